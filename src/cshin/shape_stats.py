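"""Nonparametric comparison of cell-shape-index populations.

CShin distributions are skewed, so medians are compared rank-based
throughout: Mann-Whitney for two groups; Kruskal-Wallis followed by the
Conover-Iman post hoc with Benjamini-Hochberg false-discovery-rate
adjustment when there are more.  All tests are two-sided.

The Mann-Whitney p is exact (full null enumeration) when ``n_a * n_b <= 400``
and the pooled data carry no ties, and a tie- and continuity-corrected
normal approximation otherwise.  The Conover-Iman statistics are computed
from the pooled Kruskal-Wallis ranks with tie-corrected variance and
referred to Student's t with ``N - k`` degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSamples",
    "TestResult",
    "PairwiseComparison",
    "mann_whitney",
    "kruskal_wallis",
    "conover_posthoc",
    "bh_adjust",
]

# below this product of group sizes (and with no ties) the Mann-Whitney null
# is enumerated exactly rather than normal-approximated
EXACT_MW_LIMIT = 400


@dataclass(frozen=True)
class GroupSamples:
    """Labelled groups of (positive, dimensionless) shape-index values."""

    groups: Mapping[str, np.ndarray]

    def __init__(self, groups: Mapping[str, Sequence[float]]):
        cleaned = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
        if len(cleaned) < 2:
            raise ValueError("need at least 2 groups")
        for name, values in cleaned.items():
            if values.ndim != 1 or len(values) < 2:
                raise ValueError(f"group {name!r} needs >= 2 observations")
        object.__setattr__(self, "groups", cleaned)

    @property
    def labels(self) -> list[str]:
        return list(self.groups)


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float
    raw_p: float
    adjusted_p: float


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test; U reported as min(U_a, U_b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1", stacklevel=2)
        return TestResult(method="mann_whitney", statistic=len(a) * len(b) / 2.0, p_value=1.0)
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(a) * len(b) <= EXACT_MW_LIMIT) and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    u_a = float(res.statistic)
    u_b = len(a) * len(b) - u_a
    return TestResult(
        method="mann_whitney",
        statistic=min(u_a, u_b),
        p_value=min(1.0, float(res.pvalue)),
    )


def kruskal_wallis(samples: GroupSamples) -> TestResult:
    """Kruskal-Wallis H (tie-corrected) with chi-square p on k-1 df."""
    values = list(samples.groups.values())
    pooled = np.concatenate(values)
    if np.all(pooled == pooled[0]):
        return TestResult(method="kruskal_wallis", statistic=0.0, p_value=1.0)
    h, p = stats.kruskal(*values)
    return TestResult(method="kruskal_wallis", statistic=float(h), p_value=float(p))


def _pooled_ranks(samples: GroupSamples) -> tuple[dict[str, np.ndarray], np.ndarray]:
    labels = samples.labels
    values = [samples.groups[lab] for lab in labels]
    pooled = np.concatenate(values)
    ranks = stats.rankdata(pooled)
    out, offset = {}, 0
    for lab, v in zip(labels, values):
        out[lab] = ranks[offset : offset + len(v)]
        offset += len(v)
    return out, ranks


def conover_posthoc(samples: GroupSamples, adjust: str = "bh") -> TestResult:
    """All-pairs Conover-Iman test on the pooled Kruskal-Wallis ranks.

    The pairwise statistic is
    ``t_ij = (Rbar_i - Rbar_j) / sqrt(S^2 * (N-1-H)/(N-k) * (1/n_i + 1/n_j))``
    with ``S^2`` the tie-corrected variance of the pooled ranks; two-sided p
    from Student's t with ``N - k`` df, optionally BH-adjusted over the one
    family of all pairs.  With only two groups the comparison falls back to
    :func:`mann_whitney`.
    """
    if adjust not in {"bh", "none"}:
        raise ValueError("adjust must be 'bh' or 'none'")
    labels = samples.labels
    if len(labels) < 3:
        warnings.warn("fewer than 3 groups: falling back to Mann-Whitney", stacklevel=2)
        a, b = (samples.groups[lab] for lab in labels)
        mw = mann_whitney(a, b)
        pair = PairwiseComparison(labels[0], labels[1], mw.statistic, mw.p_value, mw.p_value)
        return TestResult(mw.method, mw.statistic, mw.p_value, pairwise=[pair])

    kw = kruskal_wallis(samples)
    rank_groups, pooled_ranks = _pooled_ranks(samples)
    n_total = len(pooled_ranks)
    k = len(labels)
    # tie-corrected variance of the pooled ranks
    s2 = (np.sum(pooled_ranks**2) - n_total * (n_total + 1) ** 2 / 4.0) / (n_total - 1)
    scale = s2 * (n_total - 1 - kw.statistic) / (n_total - k)
    scale = max(scale, np.finfo(float).tiny)
    df = n_total - k
    rows: list[tuple[str, str, float, float]] = []
    for lab_i, lab_j in combinations(labels, 2):
        ri, rj = rank_groups[lab_i], rank_groups[lab_j]
        se = np.sqrt(scale * (1.0 / len(ri) + 1.0 / len(rj)))
        t = (ri.mean() - rj.mean()) / se
        p = 2.0 * stats.t.sf(abs(t), df)
        rows.append((lab_i, lab_j, float(t), min(1.0, float(p))))
    raw = np.array([r[3] for r in rows])
    adjusted = bh_adjust(raw) if adjust == "bh" else raw
    pairwise = [
        PairwiseComparison(i, j, t, p, float(ap))
        for (i, j, t, p), ap in zip(rows, adjusted)
    ]
    return TestResult(
        method="kruskal_wallis+conover",
        statistic=kw.statistic,
        p_value=kw.p_value,
        pairwise=pairwise,
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
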