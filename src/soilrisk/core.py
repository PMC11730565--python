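"""Core domain types, default reference tables, and delimited-text I/O.

The package assesses heavy-metal contamination of soils from per-site
concentration tables (mg kg⁻¹) measured either in the field or extracted
from interpolated concentration rasters.  Everything downstream (indices,
classification, concordance) consumes the types defined here.

Conventions
-----------
* Concentrations are mg kg⁻¹ throughout; there is no unit-conversion layer.
* Coordinates are projected metres in a single CRS identified by a string
  tag (the study areas this package was designed around are georeferenced
  in UTM zone 29N).  CRS tags are compared for equality only; no
  reprojection is performed.
* A missing concentration is an explicit ``NaN``, never a zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("soilrisk")

#: The nine elements analysed by default, alphabetically.
STUDY_ELEMENTS: tuple[str, ...] = ("As", "Cd", "Co", "Cr", "Cu", "Mn", "Ni", "Pb", "Sb")

#: Closed registry of element symbols a sample table may carry.  Extending it
#: is deliberate (edit here), not accidental (a typo'd column name fails fast).
ELEMENT_REGISTRY: frozenset[str] = frozenset(
    STUDY_ELEMENTS
    + ("Zn", "Hg", "Fe", "Al", "V", "Mo", "Se", "Tl", "Ba", "Sn", "W", "U", "Ti", "Sr", "Ag", "Be")
)

#: Geochemical background (reference) values, mg kg⁻¹, after Reimann & de
#: Caritat's compilation for soils.
DEFAULT_BACKGROUND: dict[str, float] = {
    "As": 5.0, "Cd": 0.3, "Co": 10.0, "Cr": 80.0, "Cu": 25.0,
    "Ni": 20.0, "Pb": 17.0, "Sb": 0.5, "Mn": 530.0,
}

#: Hakanson-style toxicity coefficients (dimensionless weights).
DEFAULT_TOXICITY: dict[str, float] = {
    "As": 10.0, "Cd": 30.0, "Cr": 2.0, "Cu": 5.0, "Pb": 5.0,
    "Co": 5.0, "Ni": 5.0, "Mn": 1.0, "Sb": 7.0,
}

#: Label used wherever an index value could not be classified.
UNCLASSIFIED = "unclassified"


class SoilRiskError(Exception):
    """Base class for validation and configuration failures."""


@dataclass
class SampleTable:
    """Per-site coordinates plus element concentrations.

    Parameters
    ----------
    data
        DataFrame indexed by ``site_id`` with columns ``x``, ``y`` (projected
        metres) followed by one column per element symbol (mg kg⁻¹).
        Missing concentrations are NaN.
    source_tag
        Free label for provenance, e.g. ``"SOIL"`` or ``"LUCAS"``.
    crs_tag
        String identifying the shared projected CRS.
    """

    data: pd.DataFrame
    source_tag: str = ""
    crs_tag: str = ""

    def __post_init__(self) -> None:
        df = self.data
        for col in ("x", "y"):
            if col not in df.columns:
                raise SoilRiskError(f"sample table lacks coordinate column {col!r}")
        if df.index.has_duplicates:
            dups = sorted(set(df.index[df.index.duplicated()]))
            raise SoilRiskError(f"duplicate site_id values: {dups}")
        bad = [el for el in self.elements if el not in ELEMENT_REGISTRY]
        if bad:
            raise SoilRiskError(f"unknown element symbols {bad}; registry: {sorted(ELEMENT_REGISTRY)}")
        conc = df[list(self.elements)]
        if ((conc < 0).any()).any():
            neg = [el for el in self.elements if (conc[el] < 0).any()]
            raise SoilRiskError(f"negative concentrations for {neg}")
        self.data.index.name = "site_id"

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c not in ("x", "y"))

    @property
    def site_ids(self) -> pd.Index:
        return self.data.index

    def concentrations(self) -> pd.DataFrame:
        """Element columns only (sites × elements)."""
        return self.data[list(self.elements)]

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class ReferenceSet:
    """Per-element background values and toxicity coefficients.

    ``background`` holds the reference concentration Cb (mg kg⁻¹) used as the
    denominator of the contamination factor, pollution index and
    geoaccumulation index; ``toxicity`` holds the dimensionless Tr weights of
    the potential-ecological-risk index.
    """

    background: Mapping[str, float]
    toxicity: Mapping[str, float] = field(default_factory=dict)
    source_label: str = ""

    def __post_init__(self) -> None:
        for name, table in (("background", self.background), ("toxicity", self.toxicity)):
            for el, v in table.items():
                if not np.isfinite(v) or v <= 0:
                    raise SoilRiskError(f"{name}[{el}] must be finite and > 0, got {v}")

    def require(self, elements, *, toxicity: bool = False) -> None:
        """Fail fast if any requested element lacks reference data."""
        missing = [el for el in elements if el not in self.background]
        if missing:
            raise SoilRiskError(f"elements without background value: {missing}")
        if toxicity:
            missing = [el for el in elements if el not in self.toxicity]
            if missing:
                raise SoilRiskError(f"elements without toxicity coefficient: {missing}")

    def toxicity_sum(self, elements) -> float:
        self.require(elements, toxicity=True)
        return float(sum(self.toxicity[el] for el in elements))


def default_reference_set() -> ReferenceSet:
    """The built-in nine-element reference tables."""
    return ReferenceSet(
        background=dict(DEFAULT_BACKGROUND),
        toxicity=dict(DEFAULT_TOXICITY),
        source_label="built-in defaults (Reimann & de Caritat backgrounds; Hakanson-style toxicity)",
    )


@dataclass(frozen=True)
class CategoryScheme:
    """An ordered set of labelled classes with numeric cut points.

    ``labels`` run from least to most contaminated.  ``lower_bounds`` are the
    strictly increasing cut points between consecutive *interval* classes;
    the first class is unbounded below and the last unbounded above.  A value
    exactly at ``lower_bounds[i]`` belongs to the upper class unless
    ``at_bound_to_lower[i]`` is true (used where a published table prints a
    closed upper bound, e.g. Pn ≤ 0.7).  ``point_labels`` maps exact values to
    their own single-point class (used for PLI = 1, the baseline class).
    """

    name: str
    labels: tuple[str, ...]
    lower_bounds: tuple[float, ...]
    at_bound_to_lower: tuple[bool, ...] = ()
    point_labels: Mapping[float, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(b2 <= b1 for b1, b2 in zip(self.lower_bounds, self.lower_bounds[1:])):
            raise SoilRiskError(f"scheme {self.name}: lower_bounds must be strictly increasing")
        if len(self.interval_labels) != len(self.lower_bounds) + 1:
            raise SoilRiskError(
                f"scheme {self.name}: {len(self.lower_bounds)} cut points require "
                f"{len(self.lower_bounds) + 1} interval labels, got {len(self.interval_labels)}"
            )
        if self.at_bound_to_lower and len(self.at_bound_to_lower) != len(self.lower_bounds):
            raise SoilRiskError(f"scheme {self.name}: at_bound_to_lower length mismatch")
        for label in self.point_labels.values():
            if label not in self.labels:
                raise SoilRiskError(f"scheme {self.name}: point label {label!r} not in labels")

    @property
    def interval_labels(self) -> tuple[str, ...]:
        pts = set(self.point_labels.values())
        return tuple(l for l in self.labels if l not in pts)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "labels": list(self.labels),
            "lower_bounds": list(self.lower_bounds),
            "at_bound_to_lower": list(self.at_bound_to_lower),
            "point_labels": {float(k): v for k, v in self.point_labels.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CategoryScheme":
        return cls(
            name=d["name"],
            labels=tuple(d["labels"]),
            lower_bounds=tuple(float(b) for b in d["lower_bounds"]),
            at_bound_to_lower=tuple(bool(b) for b in d.get("at_bound_to_lower", ())),
            point_labels={float(k): v for k, v in d.get("point_labels", {}).items()},
        )


@dataclass
class ConfusionMatrix:
    """Counts of (reference class, test class) pairs for one index.

    Rows are the reference (field-sample) class, columns the test
    (raster-derived) class, both in the scheme's least- to most-contaminated
    order.  The diagonal holds the well-classified sites.
    """

    scheme_name: str
    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise SoilRiskError("confusion matrix shape does not match labels")
        if (self.counts < 0).any():
            raise SoilRiskError("confusion matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def read_sample_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    source_tag: str = "",
    crs_tag: str = "",
) -> SampleTable:
    """Read a sample table from CSV.

    Expected columns: ``site_id, x, y, <El1>, <El2>, ...`` (comma separator,
    ``.`` decimal, UTF-8).  ``column_map`` maps file headers to those
    canonical names.  Unparseable numeric cells and the literal ``NA`` become
    explicit missing values; affected rows are retained and the read is
    logged as kept/dropped counts.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in ("site_id", "x", "y"):
        if col not in df.columns:
            raise SoilRiskError(f"{path}: missing required column {col!r}")
    n_raw = len(df)
    for col in df.columns:
        if col == "site_id":
            continue
        df[col] = pd.to_numeric(df[col].replace({"": np.nan, "NA": np.nan}), errors="coerce")
    df = df.set_index("site_id")
    keep = df["x"].notna() & df["y"].notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("%s: dropped %d row(s) without valid coordinates", path, dropped)
    logger.info("%s: read %d rows, kept %d, dropped %d", path, n_raw, n_raw - dropped, dropped)
    return SampleTable(df[keep], source_tag=source_tag, crs_tag=crs_tag)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    """Write a sample table as CSV (missing values as empty cells)."""
    table.data.to_csv(path, na_rep="")


def read_reference_set(path: str | Path) -> ReferenceSet:
    """Read a reference table from CSV with columns ``element,background,toxicity``.

    The toxicity column is optional.
    """
    df = pd.read_csv(path)
    if "element" not in df.columns or "background" not in df.columns:
        raise SoilRiskError(f"{path}: reference CSV needs columns element,background[,toxicity]")
    background = dict(zip(df["element"], df["background"].astype(float)))
    toxicity: dict[str, float] = {}
    if "toxicity" in df.columns:
        sub = df[df["toxicity"].notna()]
        toxicity = dict(zip(sub["element"], sub["toxicity"].astype(float)))
    return ReferenceSet(background=background, toxicity=toxicity, source_label=str(path))


def write_reference_set(refs: ReferenceSet, path: str | Path) -> None:
    rows = []
    for el in sorted(refs.background):
        rows.append({"element": el, "background": refs.background[el],
                     "toxicity": refs.toxicity.get(el, np.nan)})
    pd.DataFrame(rows).to_csv(path, index=False)
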