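"""Sex-stratified contingency statistics.

The analyses here all reduce to 2x2 tables with fixed semantics — rows are
{female, male}, columns are {feature present, feature absent}:

========  ==============  =============
          present         absent
female    a               b
male      c               d
========  ==============  =============

* odds ratio OR = (a d)/(b c), Woolf (log-scale normal) confidence interval
  ``exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``, Haldane–Anscombe +0.5
  applied to all four cells when any is zero;
* Fisher's exact test by hypergeometric enumeration (one-tailed values are
  the primary inferential quantity; the two-tailed value uses the
  method-of-small-p convention, summing all tables with point probability
  at most that of the observed table);
* Bonferroni correction with an explicit family size;
* male:female sex ratios with the sample-size >= 10 reporting rule;
* per-genomic-disorder-region comorbidity-frequency profiles by sex.

One-tailed directions are declared a priori by the caller (e.g. "female
comorbidity odds greater"); both tails are always computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import pandas as pd
from scipy import stats as sps

from .cnv_filter import CnvCall
from .keywords import Individual, in_cohort

ALTERNATIVES = ("greater", "less", "two_sided")


@dataclass(frozen=True)
class Table2x2:
    """female/male x present/absent counts (a=F+, b=F-, c=M+, d=M-)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        """True when a row or column margin is zero (no testable contrast)."""
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    alpha: float
    correction_applied: bool


@dataclass(frozen=True)
class TestResult:
    test_name: str
    p_one_tailed: float
    p_two_tailed: float
    direction: str
    degenerate: bool = False


@dataclass(frozen=True)
class SexRatioResult:
    n_male: int
    n_female: int
    ratio: Optional[float]
    meets_min_n: bool

    @property
    def ratio_rounded(self) -> Optional[float]:
        """Reporting value, one decimal ('1.6:1' style)."""
        return None if self.ratio is None else round(self.ratio, 1)


@dataclass(frozen=True)
class GenomicDisorderRegion:
    name: str
    chrom: str
    start: int
    end: int
    dosage: str
    region_class: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"region {self.name}: end must exceed start")
        if self.dosage not in ("del", "dup"):
            raise ValueError(f"region {self.name}: dosage must be del or dup")
        if self.region_class not in ("syndromic", "variable_expressivity"):
            raise ValueError(
                f"region {self.name}: class must be syndromic or "
                f"variable_expressivity, got {self.region_class!r}"
            )

    @property
    def size(self) -> int:
        return self.end - self.start


def comorbidity_table(
    individuals: Iterable[Individual],
    cohort: str,
    feature: Callable[[Individual], bool] | None = None,
) -> Table2x2:
    """Female/male x feature-present/absent table over one analysis cohort.

    The default feature predicate is "any comorbid feature beyond the
    primary diagnosis". Individuals labelled ``both`` count in both the
    autism and ID/DD cohorts.
    """
    if feature is None:
        feature = lambda ind: ind.profile.has_comorbidity
    a = b = c = d = 0
    for ind in individuals:
        if not in_cohort(ind, cohort):
            continue
        present = feature(ind)
        if ind.sex == "F":
            a += present
            b += not present
        else:
            c += present
            d += not present
    table = Table2x2(a, b, c, d)
    if table.total == 0:
        raise ValueError(f"cohort {cohort!r} is empty; no testable table")
    return table


_Z_CACHE: dict[float, float] = {}


def odds_ratio_woolf(table: Table2x2, alpha: float = 0.05) -> OddsRatioResult:
    """Odds ratio with Woolf (log) confidence interval.

    Any zero cell triggers the Haldane–Anscombe +0.5 correction on all four
    cells (flagged in the result). An all-zero table is an error.
    """
    if table.total == 0:
        raise ValueError("all-zero table has no odds ratio")
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if alpha not in _Z_CACHE:
        _Z_CACHE[alpha] = float(sps.norm.ppf(1 - alpha / 2))
    z = _Z_CACHE[alpha]
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        alpha=alpha,
        correction_applied=corrected,
    )


# growing log-factorial table shared by all fisher_exact calls
_LOGFACT = [0.0]


def _logfact(n: int) -> float:
    table = _LOGFACT
    while len(table) <= n:
        table.append(table[-1] + math.log(len(table)))
    return table[n]


def _hypergeom_pmf_support(r1: int, r2: int, c1: int) -> tuple[int, list[float]]:
    """Support start and point probabilities of the a-cell under fixed margins."""
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    base = _logfact(c1) + _logfact(n - c1) - _logfact(n) + _logfact(r1) + _logfact(r2)
    probs = [
        math.exp(
            base
            - _logfact(k)
            - _logfact(r1 - k)
            - _logfact(c1 - k)
            - _logfact(r2 - c1 + k)
        )
        for k in range(lo, hi + 1)
    ]
    return lo, probs


def fisher_exact(table: Table2x2, alternative: str = "greater") -> TestResult:
    """Fisher's exact test on a female/male x present/absent table.

    ``alternative='greater'`` tests whether females are enriched for the
    feature (a-cell larger than expected under fixed margins), ``'less'``
    the opposite tail. ``'two_sided'`` reports the smaller tail as the
    one-tailed value. The two-tailed value (method of small p) is always
    computed. Degenerate margins yield p = 1 with a flag.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    if table.degenerate:
        return TestResult(
            test_name="fisher_exact",
            p_one_tailed=1.0,
            p_two_tailed=1.0,
            direction=alternative,
            degenerate=True,
        )
    r1, r2, c1 = table.a + table.b, table.c + table.d, table.a + table.c
    lo, probs = _hypergeom_pmf_support(r1, r2, c1)
    i = table.a - lo
    p_obs = probs[i]
    p_greater = min(1.0, math.fsum(probs[i:]))
    p_less = min(1.0, math.fsum(probs[: i + 1]))
    cutoff = p_obs * (1 + 1e-7)
    p_two = min(1.0, math.fsum(p for p in probs if p <= cutoff))
    if alternative == "greater":
        p_one = p_greater
    elif alternative == "less":
        p_one = p_less
    else:
        p_one = min(p_greater, p_less)
    return TestResult(
        test_name="fisher_exact",
        p_one_tailed=p_one,
        p_two_tailed=p_two,
        direction=alternative,
    )


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> list[float]:
    """Bonferroni adjustment min(1, p*m); m defaults to the family length."""
    ps = list(p_values)
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p value out of [0, 1]: {p}")
    if m is None:
        m = len(ps)
    if m < len(ps):
        raise ValueError(f"family size m={m} smaller than number of tests {len(ps)}")
    return [min(1.0, p * m) for p in ps]


def sex_ratio(n_male: int, n_female: int, min_n: int = 10) -> SexRatioResult:
    """Male:female ratio with the minimum-total-sample reporting rule."""
    if n_male < 0 or n_female < 0:
        raise ValueError("counts must be non-negative")
    return SexRatioResult(
        n_male=n_male,
        n_female=n_female,
        ratio=(n_male / n_female) if n_female > 0 else None,
        meets_min_n=(n_male + n_female) >= min_n,
    )


def assign_regions(
    calls: Iterable[CnvCall],
    regions: Sequence[GenomicDisorderRegion],
    min_region_coverage: float = 0.5,
) -> dict[str, set[str]]:
    """region name -> set of subject ids carrying it.

    A call carries a region when dosage types match and the call covers at
    least ``min_region_coverage`` of the region.
    """
    carriers: dict[str, set[str]] = {r.name: set() for r in regions}
    calls = list(calls)
    for r in regions:
        need = min_region_coverage * r.size
        for c in calls:
            if c.chrom != r.chrom or c.dosage != r.dosage:
                continue
            ov = min(c.end, r.end) - max(c.start, r.start)
            if ov >= need:
                carriers[r.name].add(c.subject_id)
    return carriers


def per_cnv_comorbidity(
    individuals: Iterable[Individual],
    calls: Iterable[CnvCall],
    regions: Sequence[GenomicDisorderRegion],
    cohort: str,
    min_n: int = 10,
    min_region_coverage: float = 0.5,
) -> pd.DataFrame:
    """Per-region comorbidity frequency by sex, for one analysis cohort.

    Regions with fewer than ``min_n`` cohort carriers are suppressed
    (reported with ``reported=False`` and a reason, no frequencies).
    """
    inds = [i for i in individuals if in_cohort(i, cohort)]
    by_id = {i.subject_id: i for i in inds}
    carriers = assign_regions(calls, regions, min_region_coverage)
    rows = []
    for r in regions:
        members = [by_id[s] for s in carriers[r.name] if s in by_id]
        males = [i for i in members if i.sex == "M"]
        females = [i for i in members if i.sex == "F"]
        n = len(males) + len(females)
        row: dict = {
            "region": r.name,
            "class": r.region_class,
            "cohort": cohort,
            "n_male": len(males),
            "n_female": len(females),
        }
        if n < min_n:
            row.update(
                freq_male=math.nan,
                freq_female=math.nan,
                abs_diff=math.nan,
                reported=False,
                suppress_reason=f"n={n} below minimum {min_n}",
            )
        else:
            fm = (
                sum(i.profile.has_comorbidity for i in males) / len(males)
                if males
                else math.nan
            )
            ff = (
                sum(i.profile.has_comorbidity for i in females) / len(females)
                if females
                else math.nan
            )
            row.update(
                freq_male=fm,
                freq_female=ff,
                abs_diff=abs(fm - ff),
                reported=True,
                suppress_reason="",
            )
        rows.append(row)
    return pd.DataFrame(rows)
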