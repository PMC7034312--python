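"""Group-level inference for behavioral, activation and network measures.

Two-sample comparisons use the independent-samples t-test (Welch by
default, pooled-variance optionally), Cohen's d as the effect size, and
false-discovery-rate control across each measure family — Benjamini-
Hochberg step-up by default, Storey's q-value (lambda = 0.5) as an
alternative.  Brain-behavior coupling is assessed by within-group Pearson
correlation between a channel's activation scalar and task accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparisonResult",
    "t_from_summary",
    "independent_t",
    "cohens_d",
    "fdr_adjust",
    "channel_group_test",
    "metric_sweep_test",
    "brain_behavior_correlation",
    "significant_ranges",
]


@dataclass(frozen=True)
class GroupComparisonResult:
    """One two-group comparison: statistic, effect size and FDR-adjusted p."""

    label: str
    t: float
    p: float
    d: float
    q: float
    mean1: float
    sem1: float
    mean2: float
    sem2: float
    n1: int
    n2: int

    @property
    def significant(self) -> bool:
        return self.q < 0.05


def t_from_summary(m1: float, se1: float, m2: float, se2: float) -> float:
    """Welch t statistic from group means and standard errors.

    ``t = (m1 - m2) / sqrt(se1**2 + se2**2)`` — reproduces a two-sample
    t computed from printed summary statistics.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    return (m1 - m2) / float(np.hypot(se1, se2))


def independent_t(
    x: np.ndarray, y: np.ndarray, variant: str = "welch"
) -> tuple[float, float, float]:
    """Two-tailed independent-samples t-test.

    Returns ``(t, p, df)``; ``variant`` selects Welch (unequal variances,
    default) or the pooled-variance test.  Two constant samples with equal
    means give (0, 1, df).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        df = len(x) + len(y) - 2
        if x.mean() == y.mean():
            return 0.0, 1.0, float(df)
        return float("inf") * np.sign(x.mean() - y.mean()), 0.0, float(df)
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue), float(res.df)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with the pooled standard deviation.

    ``d = (mean(x) - mean(y)) / s_pooled`` where the pooled variance
    weights by (n1 - 1, n2 - 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled_var = (
        (n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)
    ) / (n1 + n2 - 2)
    if pooled_var <= 0:
        raise ValueError("pooled standard deviation is zero")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def _storey_q(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    m = len(p)
    pi0 = min(1.0, np.mean(p > lam) / (1.0 - lam))
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        val = min(prev, pi0 * m * p[idx] / rank)
        q[idx] = val
        prev = val
    return q


def fdr_adjust(pvals: np.ndarray, method: str = "bh") -> np.ndarray:
    """False-discovery-rate adjusted q-values for a family of p-values.

    ``method="bh"`` (default) is the Benjamini-Hochberg step-up;
    ``method="storey"`` computes Storey q-values with lambda = 0.5.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        return _storey_q(p)
    raise ValueError(f"unknown FDR method {method!r}")


def _compare_family(
    labels: list[str],
    group1: list[np.ndarray],
    group2: list[np.ndarray],
    variant: str,
    fdr_method: str,
) -> list[GroupComparisonResult]:
    ts, ps, ds, summaries = [], [], [], []
    for x, y in zip(group1, group2):
        t, p, _ = independent_t(x, y, variant)
        ts.append(t)
        ps.append(p)
        ds.append(cohens_d(x, y))
        summaries.append(
            (
                x.mean(), x.std(ddof=1) / np.sqrt(len(x)),
                y.mean(), y.std(ddof=1) / np.sqrt(len(y)),
                len(x), len(y),
            )
        )
    qs = fdr_adjust(np.asarray(ps), method=fdr_method)
    return [
        GroupComparisonResult(
            label=lab, t=t, p=p, d=d, q=float(q),
            mean1=s[0], sem1=s[1], mean2=s[2], sem2=s[3], n1=s[4], n2=s[5],
        )
        for lab, t, p, d, q, s in zip(labels, ts, ps, ds, qs, summaries)
    ]


def channel_group_test(
    activations: dict[str, np.ndarray],
    group1: str,
    group2: str,
    channels: list[str] | None = None,
    variant: str = "welch",
    fdr_method: str = "bh",
) -> list[GroupComparisonResult]:
    """Channel-wise group comparison of activation scalars.

    ``activations`` maps group label -> array (n_subjects, n_channels).
    Tests every channel with an independent t-test; q-values are FDR-
    adjusted across the channel family.  Rows with NaN in a channel are
    excluded for that channel.
    """
    a1 = np.asarray(activations[group1], dtype=float)
    a2 = np.asarray(activations[group2], dtype=float)
    if a1.ndim != 2 or a2.ndim != 2 or a1.shape[1] != a2.shape[1]:
        raise ValueError("activation arrays must be (n_subjects, n_channels)")
    n_ch = a1.shape[1]
    if channels is None:
        channels = [f"CH{i:02d}" for i in range(1, n_ch + 1)]
    g1 = [a1[~np.isnan(a1[:, c]), c] for c in range(n_ch)]
    g2 = [a2[~np.isnan(a2[:, c]), c] for c in range(n_ch)]
    for c in range(n_ch):
        if len(g1[c]) < 2 or len(g2[c]) < 2:
            raise ValueError(f"fewer than 2 usable subjects for {channels[c]}")
    return _compare_family(list(channels), g1, g2, variant, fdr_method)


def metric_sweep_test(
    metrics: dict[str, dict[str, np.ndarray]],
    group1: str,
    group2: str,
    thresholds: np.ndarray,
    variant: str = "welch",
    fdr_method: str = "bh",
) -> dict[str, list[GroupComparisonResult]]:
    """Per-threshold group comparison of each network metric.

    ``metrics`` maps group label -> {metric name -> array (n_subjects,
    n_thresholds)}.  For each metric the tests across the threshold grid
    form one FDR family.  Grid points with fewer than 2 finite values in
    either group are skipped.
    """
    out: dict[str, list[GroupComparisonResult]] = {}
    names = sorted(set(metrics[group1]) & set(metrics[group2]))
    for name in names:
        m1 = np.asarray(metrics[group1][name], dtype=float)
        m2 = np.asarray(metrics[group2][name], dtype=float)
        labels, g1, g2 = [], [], []
        for j, t in enumerate(thresholds):
            x = m1[np.isfinite(m1[:, j]), j]
            y = m2[np.isfinite(m2[:, j]), j]
            if len(x) < 2 or len(y) < 2 or (x.var() == 0 and y.var() == 0):
                continue
            labels.append(f"{name}@{t:g}")
            g1.append(x)
            g2.append(y)
        out[name] = _compare_family(labels, g1, g2, variant, fdr_method) if labels else []
    return out


def significant_ranges(
    results: list[GroupComparisonResult],
    thresholds: list[float] | None = None,
    alpha: float = 0.05,
    corrected: bool = False,
) -> list[tuple[float, float]]:
    """Contiguous threshold ranges where a sweep comparison is significant.

    Uses uncorrected p by default (``corrected=True`` switches to q).
    """
    if thresholds is None:
        thresholds = [float(r.label.rsplit("@", 1)[1]) for r in results]
    flags = [
        (r.q if corrected else r.p) < alpha for r in results
    ]
    ranges: list[tuple[float, float]] = []
    start = None
    for t, f in zip(thresholds, flags):
        if f and start is None:
            start = t
        elif not f and start is not None:
            ranges.append((start, prev))
            start = None
        prev = t
    if start is not None:
        ranges.append((start, thresholds[-1]))
    return ranges


def brain_behavior_correlation(
    activation: np.ndarray, behavior: np.ndarray
) -> tuple[float, float]:
    """Within-group Pearson correlation between a channel's activation
    scalar and a behavioral measure; returns (r, two-tailed p)."""
    x = np.asarray(activation, dtype=float)
    y = np.asarray(behavior, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
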