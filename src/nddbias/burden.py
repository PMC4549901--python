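"""CNV burden: largest-CNV survivor functions and group comparisons.

Burden for a subject is the size of their largest QC-passing autosomal CNV.
For a group of carriers the burden summary is the survivor function

    S(t) = #{subjects with largest CNV >= t} / n,

estimated on a size grid and compared between groups at fixed thresholds
(>=1 Mbp, >=1.5 Mbp, >=2 Mbp by convention) with Fisher's exact test on the
group x exceeds-threshold table. The replication analysis on total de novo
base pairs per subject uses the Mann–Whitney rank-sum test.

The survivor denominator is the rare-CNV *carrier* cohort (subjects with at
least one passing call); callers wanting full-cohort normalization can
include non-carriers with size 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .cnv_filter import CnvCall
from .stats import Table2x2, TestResult, fisher_exact


@dataclass(frozen=True)
class BurdenSample:
    subject_id: str
    sex: str
    group: str
    largest_cnv_bp: int
    total_denovo_bp: Optional[int] = None

    def __post_init__(self):
        if self.largest_cnv_bp <= 0:
            raise ValueError("burden samples are carriers: largest_cnv_bp must be > 0")


@dataclass(frozen=True)
class SurvivorCurve:
    grid: tuple
    freq: tuple
    n_exceed: tuple
    n: int

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("grid must be strictly increasing")
        if any(f2 > f1 for f1, f2 in zip(self.freq, self.freq[1:])):
            raise ValueError("survivor frequencies must be non-increasing")


@dataclass(frozen=True)
class BurdenComparison:
    threshold_bp: int
    n_exceed_a: int
    n_a: int
    n_exceed_b: int
    n_b: int
    p_one_tailed: float
    p_two_tailed: float
    direction: str


def default_grid(
    lo: int = 50_000, hi: int = 10_000_000, n_points: int = 100
) -> list[int]:
    """Log-spaced size grid, 50 kbp to 10 Mbp by default."""
    grid = np.unique(np.geomspace(lo, hi, n_points).astype(np.int64))
    return [int(g) for g in grid]


def survivor_curve(
    largest_sizes: Sequence[int], grid: Sequence[int]
) -> SurvivorCurve:
    """Survivor function of per-subject largest CNV sizes on a threshold grid."""
    sizes = np.asarray(list(largest_sizes), dtype=np.int64)
    if sizes.size == 0:
        raise ValueError("empty burden sample")
    grid = [int(g) for g in grid]
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")
    sizes.sort()
    # count of sizes >= t
    n_exceed = [int(sizes.size - np.searchsorted(sizes, t, side="left")) for t in grid]
    n = int(sizes.size)
    return SurvivorCurve(
        grid=tuple(grid),
        freq=tuple(k / n for k in n_exceed),
        n_exceed=tuple(n_exceed),
        n=n,
    )


def burden_threshold_test(
    group_a_sizes: Sequence[int],
    group_b_sizes: Sequence[int],
    threshold_bp: int,
    alternative: str = "greater",
) -> BurdenComparison:
    """Fisher's exact test of group x (largest CNV >= threshold).

    ``alternative='greater'`` tests whether group A (conventionally girls)
    exceeds the threshold more often than group B.
    """
    a_sizes = list(group_a_sizes)
    b_sizes = list(group_b_sizes)
    if not a_sizes or not b_sizes:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = len(a_sizes), len(b_sizes)
    k_a = sum(s >= threshold_bp for s in a_sizes)
    k_b = sum(s >= threshold_bp for s in b_sizes)
    res = fisher_exact(
        Table2x2(k_a, n_a - k_a, k_b, n_b - k_b), alternative=alternative
    )
    return BurdenComparison(
        threshold_bp=int(threshold_bp),
        n_exceed_a=k_a,
        n_a=n_a,
        n_exceed_b=k_b,
        n_b=n_b,
        p_one_tailed=res.p_one_tailed,
        p_two_tailed=res.p_two_tailed,
        direction=alternative,
    )


def total_denovo_bp(calls: Iterable[CnvCall], origin: str = "de_novo") -> int:
    """Sum of sizes of one subject's calls with the given origin (0 when none)."""
    return sum(c.size for c in calls if c.origin == origin)


def rank_sum_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "greater",
    exact_max_n: int = 40,
) -> TestResult:
    """Mann–Whitney rank-sum test (midranks for ties).

    Exact enumeration when the combined sample size is at most
    ``exact_max_n`` and there are no ties; otherwise the normal
    approximation with continuity correction. ``alternative`` refers to the
    first sample ('greater' = A stochastically larger). Constant pooled data
    yield p = 1 with a degeneracy flag.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError("alternative must be greater, less or two_sided")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult(
            test_name="mann_whitney",
            p_one_tailed=1.0,
            p_two_tailed=1.0,
            direction=alternative,
            degenerate=True,
        )
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact" if (a.size + b.size) <= exact_max_n and not has_ties else "asymptotic"
    )
    if alternative == "two_sided":
        one_alt = "greater"  # report the smaller tail
        p_g = sps.mannwhitneyu(a, b, alternative="greater", method=method).pvalue
        p_l = sps.mannwhitneyu(a, b, alternative="less", method=method).pvalue
        p_one = min(p_g, p_l)
    else:
        p_one = sps.mannwhitneyu(a, b, alternative=alternative, method=method).pvalue
    p_two = sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    return TestResult(
        test_name="mann_whitney",
        p_one_tailed=float(min(1.0, p_one)),
        p_two_tailed=float(min(1.0, p_two)),
        direction=alternative,
    )


def u_statistics(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """(U_a, U_b) with midrank tie handling; U_a + U_b = n_a * n_b."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    ranks = sps.rankdata(np.concatenate([a, b]))
    r_a = ranks[: a.size].sum()
    u_a = r_a - a.size * (a.size + 1) / 2
    return float(u_a), float(a.size * b.size - u_a)
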