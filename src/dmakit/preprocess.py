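"""Quantile normalization and background/variance probe filtering.

Filtering follows the all-samples-fail retention rule: a probe is removed
only when *every* sample fails the criterion, so transcripts detected in a
subset of samples are never discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionDataset

__all__ = [
    "FilterReport",
    "quantile_normalize",
    "filter_by_detection",
    "filter_by_intensity",
    "filter_low_variance",
]


@dataclass
class FilterReport:
    """Audit trail for a filter call."""

    rule: str
    threshold: float
    probes_before: int
    probes_after: int
    removed: list[str]

    def __post_init__(self) -> None:
        if self.probes_before - self.probes_after != len(self.removed):
            raise ValueError("filter report arithmetic does not add up")

    def as_record(self) -> dict:
        return {
            "rule": self.rule,
            "threshold": self.threshold,
            "probes_before": self.probes_before,
            "probes_after": self.probes_after,
            "n_removed": len(self.removed),
        }


def quantile_normalize(data: ExpressionDataset) -> ExpressionDataset:
    """Force every sample to share one intensity distribution.

    Each sample's values are replaced by the rank-wise mean across sorted
    samples; after the transform the multiset of values is identical in
    every sample while the within-sample rank order of probes is preserved.
    Ties within a sample receive the mean of the reference values at the
    ranks the tie occupies.
    """
    if data.n_samples < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    if data.has_missing():
        raise ValueError(
            "intensity table contains missing values; impute or subset "
            "before quantile normalization"
        )
    x = data.intensities.to_numpy(dtype=float)
    n, m = x.shape
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(m):
        order = np.argsort(x[:, j], kind="mergesort")
        col_sorted = x[order, j]
        assigned = np.empty(n)
        start = 0
        for i in range(1, n + 1):
            if i == n or col_sorted[i] != col_sorted[start]:
                assigned[start:i] = reference[start:i].mean()
                start = i
        out[order, j] = assigned
    inten = pd.DataFrame(out, index=data.intensities.index,
                         columns=data.intensities.columns)
    return ExpressionDataset(inten, data.detection_pvalues, data.annotation)


def _apply_removal(data: ExpressionDataset, remove_mask: np.ndarray,
                   rule: str, threshold: float):
    probes = np.asarray(data.probe_ids, dtype=object)
    removed = [str(p) for p in probes[remove_mask]]
    survivors = [str(p) for p in probes[~remove_mask]]
    report = FilterReport(rule, threshold, len(probes), len(survivors), removed)
    return data.subset_probes(survivors), report


def filter_by_detection(data: ExpressionDataset, alpha: float):
    """Remove probes whose detection p-value exceeds ``alpha`` in EVERY
    sample (i.e. never reliably detected anywhere)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if data.detection_pvalues is None:
        raise ValueError(
            "no detection p-value table present; use filter_by_intensity "
            "with an intensity floor instead"
        )
    det = data.detection_pvalues.to_numpy(dtype=float)
    remove = (det > alpha).all(axis=1)
    return _apply_removal(data, remove, "detection", alpha)


def filter_by_intensity(data: ExpressionDataset, floor: float):
    """Remove probes with intensity below ``floor`` in EVERY sample."""
    if floor < 0:
        raise ValueError("intensity floor must be non-negative")
    x = data.intensities.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("intensity filter does not accept missing values")
    remove = (x < floor).all(axis=1)
    return _apply_removal(data, remove, "intensity", floor)


def filter_low_variance(data: ExpressionDataset, fraction: float):
    """Remove the ``floor(fraction * n_probes)`` probes with the smallest
    across-sample variance (unbiased, n-1 denominator).

    Ties at the removal boundary are broken by stable input order, so the
    earlier probe is removed first.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    if data.n_samples < 2:
        raise ValueError("variance filter needs >=2 samples")
    x = data.intensities.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("variance filter does not accept missing values")
    n_remove = int(fraction * data.n_probes)
    variances = x.var(axis=1, ddof=1)
    order = np.argsort(variances, kind="mergesort")  # stable: input order on ties
    remove = np.zeros(data.n_probes, dtype=bool)
    remove[order[:n_remove]] = True
    return _apply_removal(data, remove, "low_variance", fraction)
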