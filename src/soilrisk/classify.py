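"""Ordinal classification of index values.

Houses the published interpretation schemes for each index (Cf, mCd, Pn,
Igeo, PLI, Eir) and the recalibration of the aggregate potential-ecological-
risk (RI) class thresholds for an arbitrary element set.

Boundary conventions follow the published tables exactly: intervals are
lower-closed (a value at a cut point belongs to the more-contaminated class)
except where the table prints a closed upper bound (Pn ≤ 0.7, Pn ≤ 1, …, and
Igeo ≤ 0), which is honoured; where two printed rows share a boundary the
less-contaminated class wins.  PLI's baseline class is the exact value 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import UNCLASSIFIED, CategoryScheme, ReferenceSet, SoilRiskError

__all__ = [
    "builtin_scheme",
    "classify_value",
    "RecalibrationRule",
    "recalibrate_ri_thresholds",
    "default_schemes",
    "classify_index_table",
]

_BUILTIN: dict[str, CategoryScheme] = {
    "Cf": CategoryScheme(
        name="Cf",
        labels=("Low", "Moderate", "High", "Very high"),
        lower_bounds=(1.0, 3.0, 6.0),
    ),
    "mCd": CategoryScheme(
        name="mCd",
        labels=(
            "Nil to very low degree of contamination",
            "Low degree of contamination",
            "Moderate degree of contamination",
            "High degree of contamination",
            "Very high degree of contamination",
            "Extremely high degree of contamination",
            "Ultra-high degree of contamination",
        ),
        lower_bounds=(1.5, 2.0, 4.0, 8.0, 16.0, 32.0),
    ),
    "Pn": CategoryScheme(
        name="Pn",
        labels=(
            "Safety domain",
            "Precaution domain",
            "Slightly polluted domain",
            "Moderately polluted domain",
            "Seriously polluted domain",
        ),
        lower_bounds=(0.7, 1.0, 2.0, 3.0),
        at_bound_to_lower=(True, True, True, True),
    ),
    "Igeo": CategoryScheme(
        name="Igeo",
        labels=(
            "Unpolluted",
            "Unpolluted to moderately polluted",
            "Moderately polluted",
            "Moderately to heavily polluted",
            "Heavily polluted",
            "Heavily to extremely polluted",
            "Extremely polluted",
        ),
        lower_bounds=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
        # the published rows overlap at 0; an exact 0 stays "Unpolluted"
        at_bound_to_lower=(True, False, False, False, False, False),
    ),
    "PLI": CategoryScheme(
        name="PLI",
        labels=("Not polluted", "Baseline levels of pollution", "Polluted"),
        lower_bounds=(1.0,),
        point_labels={1.0: "Baseline levels of pollution"},
    ),
    "Eir": CategoryScheme(
        name="Eir",
        labels=("low risk", "moderate risk", "considerable risk", "high risk",
                "significantly high risk"),
        lower_bounds=(30.0, 60.0, 120.0, 240.0),
    ),
}


def builtin_scheme(name: str) -> CategoryScheme:
    """Return the published interpretation scheme for one of
    ``{Cf, mCd, Pn, Igeo, PLI, Eir}``."""
    try:
        return _BUILTIN[name]
    except KeyError:
        raise SoilRiskError(f"no built-in scheme named {name!r}; known: {sorted(_BUILTIN)}") from None


def classify_value(value: float, scheme: CategoryScheme) -> str:
    """Map a finite index value to exactly one class label."""
    if not np.isfinite(value):
        raise SoilRiskError(f"cannot classify non-finite value {value!r} under scheme {scheme.name}")
    for pt, label in scheme.point_labels.items():
        if value == pt:
            return label
    to_lower = scheme.at_bound_to_lower or (False,) * len(scheme.lower_bounds)
    k = 0
    for i, bound in enumerate(scheme.lower_bounds):
        if value > bound or (value == bound and not to_lower[i]):
            k = i + 1
    return scheme.interval_labels[k]


@dataclass(frozen=True)
class RecalibrationRule:
    """Rule rescaling Hakanson's original RI grades to a new element set.

    Hakanson's first grade boundary (150) was set for a pollutant suite whose
    toxicity coefficients sum to 133; the boundary therefore scales as
    ΣTr × 150/133, rounded to the nearest multiple of 10 (ties up), and each
    subsequent grade boundary doubles the previous one.
    """

    hakanson_first_limit: float = 150.0
    hakanson_toxicity_sum: float = 133.0
    n_levels: int = 4
    rounding: float = 10.0

    @property
    def unit_factor(self) -> float:
        return self.hakanson_first_limit / self.hakanson_toxicity_sum

    def first_bound(self, toxicity_sum: float) -> float:
        raw = toxicity_sum * self.unit_factor
        rounded = math.floor(raw / self.rounding + 0.5) * self.rounding
        # a toxicity sum small enough to round to zero keeps the raw bound
        return rounded if rounded > 0 else raw


def recalibrate_ri_thresholds(
    toxicity: Mapping[str, float] | ReferenceSet,
    rule: RecalibrationRule = RecalibrationRule(),
    elements: Sequence[str] | None = None,
) -> CategoryScheme:
    """RI classification scheme scaled to the summed toxicity of the element
    set analysed.

    For the nine-element default suite (ΣTr = 70) the bounds are
    (80, 160, 320); a suite summing to 133 recovers Hakanson's original
    (150, 300, 600).
    """
    if isinstance(toxicity, ReferenceSet):
        tox = dict(toxicity.toxicity)
    else:
        tox = dict(toxicity)
    if elements is not None:
        missing = [el for el in elements if el not in tox]
        if missing:
            raise SoilRiskError(f"elements without toxicity coefficient: {missing}")
        tox = {el: tox[el] for el in elements}
    if not tox:
        raise SoilRiskError("empty toxicity map; cannot recalibrate RI thresholds")
    bad = {el: v for el, v in tox.items() if not v > 0}
    if bad:
        raise SoilRiskError(f"non-positive toxicity coefficients: {bad}")
    first = rule.first_bound(sum(tox.values()))
    bounds = tuple(first * 2**k for k in range(rule.n_levels - 1))
    return CategoryScheme(
        name="RI",
        labels=("low risk", "moderate risk", "considerable risk", "high risk")[: rule.n_levels],
        lower_bounds=bounds,
    )


def default_schemes(
    refs: ReferenceSet | None = None,
    elements: Sequence[str] | None = None,
) -> dict[str, CategoryScheme]:
    """Built-in schemes for every index, with RI recalibrated to the element
    set (default reference tables if none given)."""
    from .core import default_reference_set

    refs = refs or default_reference_set()
    schemes = dict(_BUILTIN)
    tox = dict(refs.toxicity)
    if elements is not None:
        tox = {el: tox[el] for el in elements if el in tox}
    schemes["RI"] = recalibrate_ri_thresholds(tox)
    return schemes


def _base_index(column: str) -> str:
    """'Cf_As' → 'Cf'; 'mCd' → 'mCd'."""
    return column.split("_", 1)[0]


def classify_index_table(
    idx: pd.DataFrame,
    schemes: Mapping[str, CategoryScheme],
) -> pd.DataFrame:
    """Classify every index column of an index table.

    Returns a long-format DataFrame with columns ``site_id, index, value,
    label, scheme_version``.  Missing index values receive the explicit label
    ``"unclassified"``.  Every index column present must be covered by a
    scheme (keyed by base index name: Cf, Igeo, Eir, mCd, Pn, RI, PLI).
    """
    value_cols = [c for c in idx.columns if c != "n_elements"]
    uncovered = sorted({_base_index(c) for c in value_cols} - set(schemes))
    if uncovered:
        raise SoilRiskError(f"no scheme supplied for indices: {uncovered}")
    records = []
    for col in value_cols:
        scheme = schemes[_base_index(col)]
        for site_id, value in idx[col].items():
            if pd.isna(value):
                label = UNCLASSIFIED
            else:
                label = classify_value(float(value), scheme)
            records.append((site_id, col, value, label, scheme.name))
    out = pd.DataFrame.from_records(
        records, columns=["site_id", "index", "value", "label", "scheme_version"]
    )
    return out
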