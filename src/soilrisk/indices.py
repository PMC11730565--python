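"""Contamination and ecological-risk indices.

Seven per-site quantities are computed from element concentrations Ci
(mg kg⁻¹) against geochemical backgrounds Cb and toxicity weights Tr:

===========  ==================================================  =========
quantity     definition                                          scope
===========  ==================================================  =========
Cf           Ci / Cb                                             element
PI           Ci / Si (identical to Cf for a shared reference)    element
Igeo         log₂(Ci / (1.5·Cb))                                 element
Eir          Tr · Cf                                             element
mCd          mean of Cf over the n analysed elements             composite
Pn           √((mean(PI)² + max(PI)²) / 2)   (Nemerow)           composite
RI           Σ Eir                                               composite
PLI          (∏ Cf)^(1/n)  (geometric mean)                      composite
===========  ==================================================  =========

The 1.5 factor in Igeo corrects the background for lithogenic variability;
the Nemerow index up-weights the single worst contaminant through its max
term.  All indices are computed per site: field studies report per-sample
class distributions, so site-level values are the primitive and any spatial
averaging is left to the caller.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ReferenceSet, SampleTable, SoilRiskError

logger = logging.getLogger("soilrisk")

__all__ = [
    "contamination_factor",
    "pollution_index",
    "modified_contamination_degree",
    "nemerow_index",
    "geoaccumulation_index",
    "single_element_risk",
    "aggregate_risk",
    "pollution_load_index",
    "compute_index_table",
    "index_columns",
]


def contamination_factor(ci: float, cb: float, element: str = "?") -> float:
    """Contamination factor Cf = Ci / Cb."""
    if not (cb > 0):
        raise SoilRiskError(f"background for {element} must be > 0, got {cb}")
    if ci < 0:
        raise SoilRiskError(f"concentration for {element} must be >= 0, got {ci}")
    return ci / cb


def pollution_index(ci: float, si: float, element: str = "?") -> float:
    """Pollution index PI = Ci / Si; same contract as :func:`contamination_factor`."""
    return contamination_factor(ci, si, element)


def modified_contamination_degree(cf_values: Sequence[float]) -> float:
    """Arithmetic mean of contamination factors (Abrahim's generalised mCd)."""
    cf = np.asarray(list(cf_values), dtype=float)
    if cf.size == 0:
        raise SoilRiskError("no elements for mCd")
    if not np.isfinite(cf).all() or (cf < 0).any():
        raise SoilRiskError("mCd requires finite, non-negative Cf values")
    return float(cf.mean())


def nemerow_index(pi_values: Sequence[float]) -> float:
    """Nemerow composite index Pn = √((mean(PI)² + max(PI)²) / 2)."""
    pi = np.asarray(list(pi_values), dtype=float)
    if pi.size == 0:
        raise SoilRiskError("no elements for Pn")
    if not np.isfinite(pi).all() or (pi < 0).any():
        raise SoilRiskError("Pn requires finite, non-negative PI values")
    return float(math.sqrt((pi.mean() ** 2 + pi.max() ** 2) / 2.0))


def geoaccumulation_index(cn: float, bn: float, element: str = "?") -> float:
    """Geoaccumulation index Igeo = log₂(Cn / (1.5·Bn)).

    A zero or censored concentration has no Igeo; the caller flags the site
    rather than fabricating a value.
    """
    if not (bn > 0):
        raise SoilRiskError(f"background for {element} must be > 0, got {bn}")
    if not (cn > 0):
        raise SoilRiskError(f"Igeo undefined for non-positive concentration ({element}: {cn})")
    return float(math.log2(cn / (1.5 * bn)))


def single_element_risk(tr: float, cf: float, element: str = "?") -> float:
    """Single-element potential ecological risk Eir = Tr · Cf."""
    if not (tr > 0):
        raise SoilRiskError(f"toxicity coefficient for {element} must be > 0, got {tr}")
    if cf < 0:
        raise SoilRiskError(f"Cf for {element} must be >= 0, got {cf}")
    return tr * cf


def aggregate_risk(eir_values: Sequence[float]) -> float:
    """Aggregate potential ecological risk RI = Σ Eir."""
    eir = np.asarray(list(eir_values), dtype=float)
    if eir.size == 0:
        raise SoilRiskError("no elements for RI")
    return float(eir.sum())


def pollution_load_index(cf_values: Sequence[float]) -> float:
    """Pollution load index: geometric mean of Cf, computed in log space."""
    cf = np.asarray(list(cf_values), dtype=float)
    if cf.size == 0:
        raise SoilRiskError("no elements for PLI")
    if (cf <= 0).any() or not np.isfinite(cf).all():
        bad = np.flatnonzero(~(cf > 0)).tolist()
        raise SoilRiskError(f"PLI undefined for non-positive Cf at positions {bad}")
    return float(np.exp(np.log(cf).mean()))


def index_columns(elements: Iterable[str]) -> list[str]:
    """Column order of an index table for a given element set."""
    elements = list(elements)
    return (
        [f"Cf_{el}" for el in elements]
        + [f"Igeo_{el}" for el in elements]
        + [f"Eir_{el}" for el in elements]
        + ["mCd", "Pn", "RI", "PLI", "n_elements"]
    )


def compute_index_table(
    samples: SampleTable,
    refs: ReferenceSet,
    elements: Sequence[str] | None = None,
    detection_limits: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Compute all indices per site.

    Parameters
    ----------
    samples, refs
        Concentration table and reference tables.  Every requested element
        must have a background value and a toxicity coefficient; this is
        checked before any computation.
    elements
        Element subset to use; defaults to the intersection of the table's
        elements with the reference backgrounds, in table order.
    detection_limits
        Optional per-element detection limit; concentrations below the limit
        are replaced by DL/2 before computing indices (off by default).

    Returns
    -------
    DataFrame indexed by site_id with columns ``Cf_<El>…, Igeo_<El>…,
    Eir_<El>…, mCd, Pn, RI, PLI, n_elements``.  Composites (mCd, Pn, RI, PLI)
    are taken over the per-site *available* subset of the requested elements,
    with ``n_elements`` recording that count.  Igeo is NaN for non-positive
    concentrations; PLI is NaN when any available Cf is zero.
    """
    if elements is None:
        elements = [el for el in samples.elements if el in refs.background]
        orphans = [el for el in samples.elements if el not in refs.background]
        if orphans:
            raise SoilRiskError(f"elements in sample table without reference background: {orphans}")
    elements = list(elements)
    missing_cols = [el for el in elements if el not in samples.elements]
    if missing_cols:
        raise SoilRiskError(f"requested elements absent from sample table: {missing_cols}")
    refs.require(elements, toxicity=True)

    if len(samples) == 0:
        logger.warning("empty sample table; returning empty index table")
        out = pd.DataFrame(columns=index_columns(elements))
        out.index.name = "site_id"
        return out

    conc = samples.concentrations()[elements].astype(float).copy()
    if detection_limits:
        for el, dl in detection_limits.items():
            if el in conc.columns:
                below = conc[el].notna() & (conc[el] < dl)
                conc.loc[below, el] = dl / 2.0

    cb = pd.Series({el: refs.background[el] for el in elements}, dtype=float)
    tr = pd.Series({el: refs.toxicity[el] for el in elements}, dtype=float)

    cf = conc / cb
    with np.errstate(divide="ignore", invalid="ignore"):
        igeo = np.log2(conc.where(conc > 0) / (1.5 * cb))
    eir = cf * tr

    n_el = cf.notna().sum(axis=1)
    incomplete = int((n_el < len(elements)).sum())
    if incomplete:
        logger.info("%d site(s) with incomplete element coverage; composites use the available subset", incomplete)

    mcd = cf.mean(axis=1)
    pn = np.sqrt((cf.mean(axis=1) ** 2 + cf.max(axis=1) ** 2) / 2.0)
    ri = eir.sum(axis=1, min_count=1)
    # geometric mean over available Cf; NaN where any available Cf is zero
    log_cf = np.log(cf.where(cf > 0))
    pli = np.exp(log_cf.mean(axis=1)).where(~(cf == 0).any(axis=1))
    pli = pli.where(n_el > 0)

    out = pd.concat(
        [
            cf.add_prefix("Cf_"),
            igeo.add_prefix("Igeo_"),
            eir.add_prefix("Eir_"),
            mcd.rename("mCd"),
            pn.rename("Pn"),
            ri.rename("RI"),
            pli.rename("PLI"),
            n_el.rename("n_elements"),
        ],
        axis=1,
    )
    out.index.name = "site_id"
    return out
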