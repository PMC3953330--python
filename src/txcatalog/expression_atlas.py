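"""Detection, tissue specificity (tau), and per-category expression summaries.

Tissue specificity uses the tau index: for an aggregated per-tissue
profile x with maximum x_max over n >= 2 tissues,

    tau = sum_i (1 - x_i / x_max) / (n - 1)

so tau = 1 iff expression is confined to exactly one tissue and tau = 0
for a uniform positive profile. Aggregation from samples to one value per
tissue defaults to the maximum over that tissue's samples (both library
methods and all replicates), switchable to the mean. No log transformation
is applied before tau. An all-zero profile leaves tau undefined
(reported as missing and excluded from category means).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .feature_io import ExpressionMatrix

__all__ = [
    "TauResult",
    "CategorySummary",
    "is_detected",
    "tau_index",
    "compute_tau",
    "category_summary",
    "single_tissue_fraction",
    "detected_tissue_counts",
]


def is_detected(values: Sequence[float], threshold: float = 0.1) -> bool:
    """True iff any value is strictly greater than *threshold*."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return False
    if (arr < 0).any():
        raise ValueError("FPKM values must be non-negative")
    return bool(arr.max() > threshold)


@dataclass(frozen=True)
class TauResult:
    feature_id: Optional[str]
    tau: Optional[float]  # None when undefined (all-zero profile)
    peak_tissue: Optional[str]


def tau_index(
    values: Sequence[float],
    tissues: Optional[Sequence[str]] = None,
    feature_id: Optional[str] = None,
) -> TauResult:
    """Tau tissue-specificity index of one per-tissue profile.

    Requires >=2 tissues; an all-zero profile yields ``tau=None``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("tau requires at least 2 tissues")
    if (x < 0).any():
        raise ValueError("FPKM values must be non-negative")
    xmax = x.max()
    if xmax == 0:
        return TauResult(feature_id, None, None)
    tau = float(np.sum(1.0 - x / xmax) / (x.size - 1))
    peak = int(np.argmax(x))
    peak_tissue = tissues[peak] if tissues is not None else None
    return TauResult(feature_id, tau, peak_tissue)


def compute_tau(expr: ExpressionMatrix, agg: str = "max") -> pd.DataFrame:
    """Tau and peak tissue for every feature of an expression matrix."""
    prof = expr.by_tissue(agg=agg)
    tissues = list(prof.columns)
    rows = []
    for fid, row in prof.iterrows():
        r = tau_index(row.values, tissues=tissues, feature_id=fid)
        rows.append((fid, r.tau, r.peak_tissue))
    return pd.DataFrame(rows, columns=["feature_id", "tau", "peak_tissue"]).set_index(
        "feature_id"
    )


@dataclass(frozen=True)
class CategorySummary:
    label: str
    n_loci: int
    detected_fraction: Optional[float]
    percentile_fpkm: Dict[float, float]
    mean_tau: Optional[float]


def category_summary(
    labels: Mapping[str, str],
    expr: ExpressionMatrix,
    percentiles: Sequence[float] = (95,),
    detection_threshold: float = 0.1,
    agg: str = "max",
) -> Dict[str, CategorySummary]:
    """Per-category expression summaries.

    *labels* maps feature (locus) id -> category. The per-locus summary
    expression is the maximum FPKM over all samples; percentiles are the
    empirical quantiles with linear interpolation. ``mean_tau`` averages
    tau over the detected loci of the category, skipping undefined values.
    """
    summary_expr = expr.values.max(axis=1)
    taus = compute_tau(expr, agg=agg)["tau"]
    by_label: Dict[str, list] = {}
    for fid, label in labels.items():
        by_label.setdefault(label, []).append(fid)
    out: Dict[str, CategorySummary] = {}
    for label, fids in sorted(by_label.items()):
        if not fids:
            out[label] = CategorySummary(label, 0, None, {}, None)
            continue
        vals = summary_expr.loc[fids]
        detected = vals > detection_threshold
        det_taus = [
            taus.loc[f]
            for f in vals.index[detected]
            if not (taus.loc[f] is None or (isinstance(taus.loc[f], float) and math.isnan(taus.loc[f])))
        ]
        out[label] = CategorySummary(
            label=label,
            n_loci=len(fids),
            detected_fraction=float(detected.mean()),
            percentile_fpkm={
                float(p): float(np.percentile(vals.values, p)) for p in percentiles
            },
            mean_tau=float(np.mean(det_taus)) if det_taus else None,
        )
    return out


def detected_tissue_counts(
    expr: ExpressionMatrix, threshold: float = 0.1
) -> pd.Series:
    """Number of tissues in which each feature is detected.

    Per-tissue detection takes the max over that tissue's samples (all
    methods and replicates) against the strict threshold.
    """
    prof = expr.by_tissue(agg="max")
    return (prof > threshold).sum(axis=1)


def single_tissue_fraction(
    labels: Mapping[str, str],
    expr: ExpressionMatrix,
    threshold: float = 0.1,
) -> Dict[str, Optional[float]]:
    """Per-category fraction of detected loci confined to one tissue.

    Loci detected in no tissue are excluded from the denominator.
    """
    counts = detected_tissue_counts(expr, threshold=threshold)
    by_label: Dict[str, list] = {}
    for fid, label in labels.items():
        by_label.setdefault(label, []).append(fid)
    out: Dict[str, Optional[float]] = {}
    for label, fids in sorted(by_label.items()):
        c = counts.loc[fids]
        detected = c[c > 0]
        out[label] = float((detected == 1).mean()) if len(detected) else None
    return out
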