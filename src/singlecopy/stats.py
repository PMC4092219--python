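"""Statistical comparisons used throughout the analysis.

Spearman rank correlation (mid-rank ties, two-sided t approximation),
Mann–Whitney U (exact enumeration for small samples, tie-corrected normal
approximation otherwise), one-way ANOVA with Tukey HSD, and the binning of
genes by family size used for alternative-splicing comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

AS_BINS = ("single_copy", "family_1_10", "family_gt10")


# ---------------------------------------------------------------------------
# Spearman


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho with average-rank ties; two-sided p via the
    t-approximation t = rho·sqrt((n−2)/(1−rho²))."""
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("constant series: rho undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return (math.copysign(1.0, rho), 0.0)
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = 2 * sps.t.sf(abs(t), n - 2)
    return rho, float(p)


def spearman_exact(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact permutation p-value (n ≤ 10)."""
    n = len(x)
    if n > 10:
        raise ValueError("exact permutation only for n <= 10")
    from itertools import permutations

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = float(np.corrcoef(rx, ry)[0, 1])
    count = total = 0
    for perm in permutations(range(n)):
        r = float(np.corrcoef(rx, ry[list(perm)])[0, 1])
        total += 1
        if abs(r) >= abs(obs) - 1e-12:
            count += 1
    return obs, count / total


# ---------------------------------------------------------------------------
# Mann–Whitney U

EXACT_LIMIT = 12


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """U of sample x: number of (x_i, y_j) pairs with x_i > y_j, ties 1/2."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact: bool | None = None
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact p by enumeration of all label assignments when n₁+n₂ ≤ 12 (or
    ``exact=True``); otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    if not len(x) or not len(y):
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    if exact is None:
        exact = n1 + n2 <= EXACT_LIMIT
    if exact:
        pooled = list(x) + list(y)
        idx = range(n1 + n2)
        count = total = 0
        for chosen in combinations(idx, n1):
            chosen_set = set(chosen)
            xs = [pooled[i] for i in chosen]
            ys = [pooled[i] for i in idx if i not in chosen_set]
            u_perm = _u_statistic(xs, ys)
            total += 1
            if abs(u_perm - n1 * n2 / 2) >= abs(u - n1 * n2 / 2) - 1e-9:
                count += 1
        return u, count / total
    # normal approximation with tie correction
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    mu = n1 * n2 / 2
    sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    p = 2 * sps.norm.sf(max(z, 0.0))
    return u, float(min(p, 1.0))


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD


@dataclass
class TukeyRow:
    group_a: str
    group_b: str
    diff: float
    p_adj: float

    @property
    def significant(self) -> bool:
        return self.p_adj < 0.05


def anova_tukey(
    groups: Mapping[str, Sequence[float]]
) -> tuple[float, float, list[TukeyRow]]:
    """One-way ANOVA F and p plus all-pairs Tukey HSD.

    Requires ≥ 2 groups of ≥ 2 values each and some within-group variance.
    """
    names = list(groups)
    data = [np.asarray(groups[g], float) for g in names]
    if len(data) < 2 or any(len(d) < 2 for d in data):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.var(d) == 0 for d in data):
        raise ValueError("zero within-group variance in all groups")
    f, p = sps.f_oneway(*data)
    hsd = sps.tukey_hsd(*data)
    rows = []
    for i, j in combinations(range(len(names)), 2):
        rows.append(
            TukeyRow(
                group_a=names[i],
                group_b=names[j],
                diff=float(np.mean(data[i]) - np.mean(data[j])),
                p_adj=float(hsd.pvalue[i, j]),
            )
        )
    return float(f), float(p), rows


# ---------------------------------------------------------------------------
# AS binning by family size


@dataclass
class ASBinSummary:
    """Per-bin distribution of alternative-splicing event counts.

    ``proportions[bin][k]`` is the fraction of the bin's genes showing k AS
    events (k capped at ``k_max`` with the last entry meaning ≥ k_max).
    """

    proportions: dict[str, list[float]]
    n_genes: dict[str, int]
    k_max: int

    def prop_with_as(self, bin_name: str) -> float:
        return 1.0 - self.proportions[bin_name][0]


def family_size_bin(
    family_size: int, low_edge: int = 2, high_edge: int = 10
) -> str:
    """Bin by in-paralog count: size 1 → single_copy; ``low_edge``..``high_edge``
    → family_1_10; above → family_gt10.  (A single-copy gene has 0
    in-paralogs; "at least 10 in-paralogs" means family size ≥ 11.)"""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if family_size == 1:
        return "single_copy"
    if family_size <= high_edge:
        return "family_1_10"
    return "family_gt10"


def as_bins(
    family_sizes: Mapping[str, int],
    as_counts: Mapping[str, int],
    k_max: int = 8,
) -> ASBinSummary:
    """Summarize AS-event-count distributions per family-size bin."""
    tallies: dict[str, list[int]] = {b: [0] * (k_max + 1) for b in AS_BINS}
    totals: dict[str, int] = {b: 0 for b in AS_BINS}
    for gene, size in family_sizes.items():
        k = as_counts.get(gene, 0)
        if k < 0:
            raise ValueError(f"negative AS count for {gene}")
        b = family_size_bin(size)
        tallies[b][min(k, k_max)] += 1
        totals[b] += 1
    props = {
        b: [c / totals[b] if totals[b] else 0.0 for c in tallies[b]] for b in AS_BINS
    }
    return ASBinSummary(proportions=props, n_genes=totals, k_max=k_max)


def as_group_counts(
    family_sizes: Mapping[str, int], as_counts: Mapping[str, int]
) -> dict[str, list[int]]:
    """Per-bin lists of per-gene AS event counts (ANOVA/Tukey input)."""
    groups: dict[str, list[int]] = {b: [] for b in AS_BINS}
    for gene, size in family_sizes.items():
        groups[family_size_bin(size)].append(as_counts.get(gene, 0))
    return groups
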