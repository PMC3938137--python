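"""Differential expression: two-group volcano statistics and the
time-series trend-correlation criterion with rank ordering.

Two-group calls combine a fold-change cutoff with a t-test p-value cutoff
(the volcano double criterion).  Fold changes are ratios of linear-scale
group means; p-values come from a two-sided t-test on log2 intensities
(Welch by default).  For multi-condition (time-series) data, each probe's
intensity vector B is correlated with the sample-order ramp
A = (1, 2, ..., n); probes passing an |r| threshold are ranked by a
between-group over within-group variance score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .io import ExpressionDataset, GroupAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "DEResult",
    "TrendResult",
    "two_group_stats",
    "select_volcano",
    "timeseries_r",
    "select_and_rank_trends",
    "bh_adjust",
]


@dataclass
class DEResult:
    probe_id: str
    mean_test: float
    mean_control: float
    fold_change: float          # test / control, linear scale
    log2_fold_change: float
    p_value: float
    significant: bool = False
    adjusted_p: float | None = None


@dataclass
class TrendResult:
    probe_id: str
    r: float                    # Pearson r against the sample-order ramp
    rank_score: float | None = None
    rank: int | None = None


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _ordered_samples(groups: GroupAssignment, sample_ids) -> list[str]:
    """Samples sorted by group-level order, ties broken by input order."""
    level_rank = {lvl: i for i, lvl in enumerate(groups.levels)}
    return sorted(sample_ids, key=lambda s: level_rank[groups.mapping[s]])


def two_group_stats(data: ExpressionDataset, groups: GroupAssignment,
                    test_level: str, control_level: str,
                    equal_var: bool = False, fdr_bh: bool = False) -> list[DEResult]:
    """Per-probe fold change and two-sided t-test between two groups.

    fold_change = mean(test) / mean(control) on the linear intensity scale;
    the p-value is computed on log2 intensities (Welch's unequal-variance
    test unless ``equal_var``).  Intensities must be strictly positive.
    With ``fdr_bh``, Benjamini-Hochberg adjusted p-values are attached.
    """
    groups.check_covers(data.sample_ids)
    for level in (test_level, control_level):
        if level not in groups.levels:
            raise ValueError(f"unknown group level {level!r}")
    test_samples = [s for s in data.sample_ids if groups.mapping[s] == test_level]
    ctrl_samples = [s for s in data.sample_ids if groups.mapping[s] == control_level]
    if len(test_samples) < 2 or len(ctrl_samples) < 2:
        raise ValueError("each group needs >=2 samples for a variance estimate")

    x_test = data.intensities[test_samples].to_numpy(dtype=float)
    x_ctrl = data.intensities[ctrl_samples].to_numpy(dtype=float)
    for name, x in (("test", x_test), ("control", x_ctrl)):
        bad = np.where(~(x > 0))[0]
        if bad.size:
            raise ValueError(
                f"non-positive intensity in {name} group for probe "
                f"{data.probe_ids[bad[0]]!r}; fold changes need positive values"
            )

    mean_test = x_test.mean(axis=1)
    mean_ctrl = x_ctrl.mean(axis=1)
    fc = mean_test / mean_ctrl
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(np.log2(x_test), np.log2(x_ctrl),
                               axis=1, equal_var=equal_var)
    p = np.asarray(p, dtype=float)
    # zero variance in both groups: t is 0/0; identical means are a null
    # result (p=1), distinct means are an exact separation (p=0)
    nan_mask = np.isnan(p)
    if nan_mask.any():
        same = np.isclose(np.log2(mean_test), np.log2(mean_ctrl))
        p[nan_mask & same] = 1.0
        p[nan_mask & ~same] = 0.0

    results = [
        DEResult(pid, float(mt), float(mc), float(f), float(np.log2(f)), float(pv))
        for pid, mt, mc, f, pv in zip(data.probe_ids, mean_test, mean_ctrl, fc, p)
    ]
    if fdr_bh:
        adj = bh_adjust([r.p_value for r in results])
        results = [replace(r, adjusted_p=float(a)) for r, a in zip(results, adj)]
    return results


def select_volcano(results: list[DEResult], fc_cutoff: float,
                   p_cutoff: float) -> list[DEResult]:
    """Volcano double cutoff: keep probes changed at least ``fc_cutoff``-fold
    in either direction AND with p_value < ``p_cutoff``."""
    if fc_cutoff < 1:
        raise ValueError("fold-change cutoff must be >= 1")
    if not 0 < p_cutoff <= 1:
        raise ValueError("p-value cutoff must lie in (0, 1]")
    if not results:
        raise ValueError("no results to select from")
    kept = []
    for r in results:
        magnitude = max(r.fold_change, 1.0 / r.fold_change)
        if magnitude >= fc_cutoff and r.p_value < p_cutoff:
            kept.append(replace(r, significant=True))
    return kept


def timeseries_r(data: ExpressionDataset, groups: GroupAssignment) -> list[TrendResult]:
    """Correlate each probe's intensities with the sample-order ramp.

    Samples are sorted by the (time-ordered) group levels, ties broken by
    input order; A = (1, ..., n).  r is the Pearson correlation of the
    probe's intensity vector with A.  Probes with zero variance have no
    defined r and are excluded with a warning.
    """
    groups.check_covers(data.sample_ids)
    ordered = _ordered_samples(groups, data.sample_ids)
    if len(ordered) < 3:
        raise ValueError("time-series correlation needs >=3 samples")
    x = data.intensities[ordered].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("time-series correlation does not accept missing values")
    n = x.shape[1]
    a = np.arange(1, n + 1, dtype=float)
    ac = a - a.mean()
    bc = x - x.mean(axis=1, keepdims=True)
    denom_b = np.sqrt((bc ** 2).sum(axis=1))
    denom_a = np.sqrt((ac ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (bc @ ac) / (denom_a * denom_b)
    flat = denom_b == 0
    if flat.any():
        logger.warning("excluding %d zero-variance probe(s) from trend analysis",
                       int(flat.sum()))
    return [TrendResult(pid, float(ri))
            for pid, ri, is_flat in zip(data.probe_ids, r, flat) if not is_flat]


def select_and_rank_trends(results: list[TrendResult], data: ExpressionDataset,
                           groups: GroupAssignment,
                           r_threshold: float) -> list[TrendResult]:
    """Keep probes with |r| >= threshold and rank them.

    rank_score = variance of group (timepoint) means divided by the pooled
    within-group variance plus a small epsilon (1e-9 times the global data
    variance), so probes that separate the groups strongly and quietly rank
    first.  Output is sorted by descending rank_score with ranks 1..k.
    """
    if not 0 < r_threshold < 1:
        raise ValueError("r threshold must lie in (0, 1)")
    if len(groups.levels) < 2:
        raise ValueError("trend ranking needs >=2 group levels")
    selected = [r for r in results if abs(r.r) >= r_threshold]
    if not selected:
        return []
    level_samples = {lvl: [s for s in data.sample_ids if groups.mapping[s] == lvl]
                     for lvl in groups.levels}
    for lvl, ss in level_samples.items():
        if not ss:
            raise ValueError(f"group level {lvl!r} has no samples")
    x = data.intensities
    eps = 1e-9 * float(np.var(x.to_numpy(dtype=float)))
    scored = []
    for res in selected:
        row = x.loc[res.probe_id]
        group_means = []
        within_ss = 0.0
        n_total = 0
        for lvl in groups.levels:
            vals = row[level_samples[lvl]].to_numpy(dtype=float)
            group_means.append(vals.mean())
            within_ss += float(((vals - vals.mean()) ** 2).sum())
            n_total += vals.size
        dof = max(n_total - len(groups.levels), 1)
        between = float(np.var(group_means, ddof=1))
        score = between / (within_ss / dof + eps)
        scored.append(replace(res, rank_score=score))
    scored.sort(key=lambda t: (-t.rank_score, t.probe_id))
    return [replace(t, rank=i + 1) for i, t in enumerate(scored)]
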