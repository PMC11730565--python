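"""Agreement between two classified tables (field reference vs raster test).

Given per-site ordinal labels from two data sources, builds per-index
confusion matrices (rows: reference class, columns: test class), class
distributions, and the diagonal success rate — the percentage of sites
receiving the same class from both sources, with the field samples as
reference.  Cohen's kappa is reported as a supplementary chance-corrected
statistic.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .core import UNCLASSIFIED, CategoryScheme, ConfusionMatrix, SoilRiskError

logger = logging.getLogger("soilrisk")

__all__ = [
    "category_distribution",
    "confusion_matrix",
    "success_rate",
    "concordance_report",
    "report_summary_frame",
    "write_report",
]


def _index_labels(classified: pd.DataFrame, index: str) -> pd.Series:
    sub = classified[classified["index"] == index]
    if sub.empty:
        raise SoilRiskError(f"no classified rows for index {index!r}")
    return sub.set_index("site_id")["label"]


def category_distribution(classified: pd.DataFrame, index: str) -> dict[str, float]:
    """Percentage of sites per class for one index, over classified sites.

    Sites labelled ``"unclassified"`` are excluded; the returned percentages
    sum to 100.
    """
    labels = _index_labels(classified, index)
    labels = labels[labels != UNCLASSIFIED]
    if labels.empty:
        raise SoilRiskError(f"no classified (non-'{UNCLASSIFIED}') sites for index {index!r}")
    counts = labels.value_counts()
    return {label: 100.0 * n / len(labels) for label, n in counts.items()}


def confusion_matrix(
    reference: pd.DataFrame,
    test: pd.DataFrame,
    index: str,
    scheme: CategoryScheme,
) -> ConfusionMatrix:
    """Confusion matrix for one index between two classified tables.

    Both tables must cover the same site set; sites unclassified in either
    table are excluded (and logged).  Label order follows the scheme.
    """
    ref = _index_labels(reference, index)
    tst = _index_labels(test, index)
    if set(ref.index) != set(tst.index):
        diff = sorted(set(ref.index).symmetric_difference(tst.index))
        raise SoilRiskError(f"site_id mismatch for index {index!r}: {diff[:20]}")
    tst = tst.reindex(ref.index)
    keep = (ref != UNCLASSIFIED) & (tst != UNCLASSIFIED)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("index %s: excluded %d unclassified site(s) from confusion matrix", index, n_excluded)
    ref, tst = ref[keep], tst[keep]
    labels = list(scheme.labels)
    unknown = (set(ref) | set(tst)) - set(labels)
    if unknown:
        raise SoilRiskError(f"labels outside scheme {scheme.name!r}: {sorted(unknown)}")
    counts = (
        pd.crosstab(ref, tst)
        .reindex(index=labels, columns=labels, fill_value=0)
        .to_numpy()
    )
    return ConfusionMatrix(scheme_name=scheme.name, labels=tuple(labels), counts=counts)


def success_rate(cm: ConfusionMatrix) -> float:
    """Percentage of co-classified sites on the diagonal."""
    if cm.total == 0:
        raise SoilRiskError("empty confusion matrix")
    return 100.0 * cm.trace / cm.total


def _kappa(cm: ConfusionMatrix) -> float:
    ref_labels, test_labels = [], []
    for i, r in enumerate(cm.labels):
        for j, c in enumerate(cm.labels):
            ref_labels += [r] * cm.counts[i, j]
            test_labels += [c] * cm.counts[i, j]
    if len(set(ref_labels) | set(test_labels)) < 2:
        return float("nan")
    return float(cohen_kappa_score(ref_labels, test_labels, labels=list(cm.labels)))


def concordance_report(
    reference: pd.DataFrame,
    test: pd.DataFrame,
    schemes: Mapping[str, CategoryScheme],
    indices: Sequence[str] | None = None,
) -> dict:
    """Per-index agreement between a reference and a test classification.

    Returns ``{index: {n, success_pct, misclassification_pct, kappa,
    matrix}}`` for every index present in both tables (or the subset
    requested).  Per-element indices (``Cf_As``, …) and composites (``mCd``,
    …) are treated alike; percentages are rounded to 2 decimals in the
    serialised summary but kept at full precision here.
    """
    if indices is None:
        indices = [i for i in reference["index"].unique() if i in set(test["index"])]
    report: dict = {}
    for index in indices:
        scheme = schemes.get(index.split("_", 1)[0])
        if scheme is None:
            raise SoilRiskError(f"no scheme for index {index!r}")
        cm = confusion_matrix(reference, test, index, scheme)
        if cm.total == 0:
            logger.warning("index %s: no co-classified sites; skipped", index)
            continue
        succ = success_rate(cm)
        report[index] = {
            "n": cm.total,
            "success_pct": succ,
            "misclassification_pct": 100.0 - succ,
            "kappa": _kappa(cm),
            "matrix": cm,
        }
    return report


def report_summary_frame(report: dict) -> pd.DataFrame:
    """Flatten a concordance report to a tidy summary table (2-decimal %)."""
    rows = [
        {
            "index": index,
            "n": entry["n"],
            "success_pct": round(entry["success_pct"], 2),
            "misclassification_pct": round(entry["misclassification_pct"], 2),
            "kappa": round(entry["kappa"], 4) if np.isfinite(entry["kappa"]) else np.nan,
        }
        for index, entry in report.items()
    ]
    return pd.DataFrame(rows)


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write summary JSON/CSV and one confusion-matrix CSV per index."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = report_summary_frame(report)
    summary.to_csv(out_dir / "concordance_summary.csv", index=False)
    payload = {
        index: {
            "n": entry["n"],
            "success_pct": round(entry["success_pct"], 2),
            "misclassification_pct": round(entry["misclassification_pct"], 2),
            "kappa": None if not np.isfinite(entry["kappa"]) else round(entry["kappa"], 4),
        }
        for index, entry in report.items()
    }
    (out_dir / "concordance_summary.json").write_text(json.dumps(payload, indent=2))
    for index, entry in report.items():
        entry["matrix"].to_frame().to_csv(out_dir / f"confusion_{index}.csv")
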