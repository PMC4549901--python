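"""Family-history frequency matrices and sex comparisons.

A subset of clinically ascertained probands comes with free-text family
history ("brother with autism; maternal epilepsy"). Both family histories
and proband indications are projected onto a fixed 12-category phenotype
vocabulary, and a per-sex frequency matrix is built:

    cell (f, i) = #{probands with indication i, any positive family
                    history, and family history f}
                  / #{probands with indication i and any positive family
                      history}

(rows = family-history category, columns = proband indication category).
An individual with several family-history categories contributes to several
numerators but counts once in each column denominator.

The 12 categories partition into two broad age-prevalence groups:

* ID/DD–MCA (early-manifesting): ID/DD, dysmorphic features, other
  congenital malformations, growth abnormalities, cardiac malformations;
* neuropsychiatric/behavioral (later-manifesting): epilepsy, other CNS
  malformations, autism, psychiatric disorders, attention deficit
  disorders, speech and language impairments, specific learning
  disabilities.

Row-wise male-vs-female comparisons use a paired t-test across indication
columns; broad-group comparisons pool the in-group cells of both matrices
and use the rank-sum test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import keywords as kw
from .burden import rank_sum_test
from .keywords import Individual, PhraseMatcher
from .stats import TestResult

FH_CATEGORIES = (
    "ID/DD",
    "dysmorphic features",
    "other congenital malformations",
    "growth abnormalities",
    "cardiac malformations",
    "epilepsy",
    "other CNS malformations",
    "autism",
    "psychiatric disorders",
    "attention deficit disorders",
    "speech and language impairments",
    "specific learning disabilities",
)

IDDD_MCA = "iddd_mca"
NEUROPSYCHIATRIC = "neuropsychiatric_behavioral"

BROAD_GROUPS: dict[str, frozenset] = {
    IDDD_MCA: frozenset(FH_CATEGORIES[:5]),
    NEUROPSYCHIATRIC: frozenset(FH_CATEGORIES[5:]),
}

# projection of the 7-category + OHI-subfeature indication space onto the
# 12-category family-history vocabulary; the behavioral bin has no separate
# slot and is folded into psychiatric disorders
_OHI_SUB_TO_FH = {
    "epilepsy": "epilepsy",
    "cardiac": "cardiac malformations",
    "growth": "growth abnormalities",
    "dysmorphic": "dysmorphic features",
    "attention_deficit": "attention deficit disorders",
    "cns_malformation": "other CNS malformations",
    "other_congenital": "other congenital malformations",
}
_CATEGORY_TO_FH = {
    kw.AUTISM: "autism",
    kw.IDDD: "ID/DD",
    kw.PSYCHIATRIC: "psychiatric disorders",
    kw.BEHAVIORAL: "psychiatric disorders",
    kw.SPEECH_LANGUAGE: "speech and language impairments",
    kw.SPECIFIC_LEARNING: "specific learning disabilities",
}


class FhKeywordMap:
    """keyword -> one of the 12 family-history categories."""

    def __init__(self, mapping: Mapping[str, str]):
        if not mapping:
            raise ValueError("family-history keyword map is empty")
        bad = {c for c in mapping.values() if c not in FH_CATEGORIES}
        if bad:
            raise ValueError(f"unknown family-history categories: {sorted(bad)}")
        self.mapping = dict(mapping)
        self.matcher = PhraseMatcher(self.mapping)

    def categories_in(self, text: str) -> frozenset:
        if not text:
            return frozenset()
        return frozenset(self.mapping[k] for k in self.matcher.find(text))


_DEFAULT_FH_PAIRS = {
    "developmental delay": "ID/DD",
    "mental retardation": "ID/DD",
    "intellectual disability": "ID/DD",
    "dysmorphic features": "dysmorphic features",
    "cleft palate": "other congenital malformations",
    "congenital malformation": "other congenital malformations",
    "growth abnormality": "growth abnormalities",
    "short stature": "growth abnormalities",
    "heart defect": "cardiac malformations",
    "cardiac malformation": "cardiac malformations",
    "epilepsy": "epilepsy",
    "seizures": "epilepsy",
    "hydrocephalus": "other CNS malformations",
    "brain malformation": "other CNS malformations",
    "autism": "autism",
    "schizophrenia": "psychiatric disorders",
    "bipolar disorder": "psychiatric disorders",
    "depression": "psychiatric disorders",
    "adhd": "attention deficit disorders",
    "attention deficit": "attention deficit disorders",
    "speech delay": "speech and language impairments",
    "language impairment": "speech and language impairments",
    "learning disability": "specific learning disabilities",
    "dyslexia": "specific learning disabilities",
}


def default_fh_map() -> FhKeywordMap:
    return FhKeywordMap(_DEFAULT_FH_PAIRS)


def bin_family_history(text: Optional[str], fh_map: FhKeywordMap) -> frozenset:
    """Family-history categories mentioned in *text* (empty set = none)."""
    return fh_map.categories_in(text or "")


def profile_to_fh_categories(profile: kw.CategoryProfile) -> frozenset:
    """Project a proband's binned indication onto the 12-category space."""
    out: set[str] = set()
    for cat in profile.categories:
        if cat == kw.OHI:
            out.update(_OHI_SUB_TO_FH[s] for s in profile.ohi_subfeatures)
        else:
            out.add(_CATEGORY_TO_FH[cat])
    return frozenset(out)


@dataclass
class FhMatrix:
    """Per-sex family-history x indication frequency matrix (12 x 12)."""

    sex: Optional[str]
    numerators: pd.DataFrame  # rows FH, cols indication
    denominators: pd.Series  # per indication column
    frequencies: pd.DataFrame  # NaN where denominator is zero

    @property
    def valid_columns(self) -> pd.Series:
        return self.denominators > 0


def fh_matrix_from_records(
    records: Iterable[tuple[frozenset, frozenset]], sex: Optional[str] = None
) -> FhMatrix:
    """Build the matrix from (indication categories, FH categories) records.

    Records with an empty family-history set do not enter (the denominator
    population is "any positive family history"). An individual with several
    FH categories contributes to several numerators but counts once in each
    column denominator.
    """
    cats = list(FH_CATEGORIES)
    num = pd.DataFrame(0, index=cats, columns=cats, dtype=int)
    den = pd.Series(0, index=cats, dtype=int)
    for indications, fh_cats in records:
        if not fh_cats or not indications:
            continue
        for col in indications:
            den[col] += 1
            for row in fh_cats:
                num.loc[row, col] += 1
    freq = num.astype(float).div(den.where(den > 0), axis=1)
    return FhMatrix(sex=sex, numerators=num, denominators=den, frequencies=freq)


def build_fh_matrix(
    individuals: Iterable[Individual], sex: Optional[str] = None
) -> FhMatrix:
    """Build the frequency matrix from binned individuals with FH categories.

    Only individuals with at least one indication category (in the
    12-category projection) *and* at least one family-history category
    enter. Columns with zero denominator carry NaN frequencies and are
    excluded from comparisons.
    """
    records = (
        (profile_to_fh_categories(ind.profile), ind.fh_categories)
        for ind in individuals
        if sex is None or ind.sex == sex
    )
    return fh_matrix_from_records(records, sex=sex)


def compare_fh_row(
    male_row: Sequence[float],
    female_row: Sequence[float],
    alternative: str = "greater",
) -> TestResult:
    """Paired t-test across indication columns on male - female frequencies.

    NaN pairs (invalid columns) are dropped; fewer than two valid pairs is
    an error. ``alternative='greater'`` tests male > female. Degenerate
    cases: all-zero differences give p = 0.5 (zero t under a symmetric
    null); constant nonzero differences give p = 0 in the favoured
    direction (1 against it), flagged.
    """
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError("alternative must be greater, less or two_sided")
    m = np.asarray(list(male_row), dtype=float)
    f = np.asarray(list(female_row), dtype=float)
    if m.size != f.size:
        raise ValueError("rows must have equal length")
    ok = ~(np.isnan(m) | np.isnan(f))
    d = m[ok] - f[ok]
    if d.size < 2:
        raise ValueError(f"need >=2 valid column pairs, got {d.size}")
    if np.ptp(d) < 1e-12:  # constant differences (up to fp rounding)
        if abs(d[0]) < 1e-12:
            return TestResult("paired_t", 0.5, 1.0, alternative, degenerate=True)
        # constant nonzero difference: direction unambiguous
        sign = math.copysign(1.0, d[0])
        if alternative == "two_sided":
            p_one = 0.0
        else:
            favoured = (alternative == "greater" and sign > 0) or (
                alternative == "less" and sign < 0
            )
            p_one = 0.0 if favoured else 1.0
        return TestResult("paired_t", p_one, 0.0, alternative, degenerate=True)
    t = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
    df = d.size - 1
    p_greater = float(sps.t.sf(t, df))
    p_less = float(sps.t.cdf(t, df))
    p_two = float(2 * sps.t.sf(abs(t), df))
    if alternative == "greater":
        p_one = p_greater
    elif alternative == "less":
        p_one = p_less
    else:
        p_one = min(p_greater, p_less)
    return TestResult("paired_t", p_one, min(1.0, p_two), alternative)


def compare_broad_groups(
    male_matrix: FhMatrix,
    female_matrix: FhMatrix,
    group: str,
    alternative: str = "greater",
) -> TestResult:
    """Rank-sum comparison of pooled in-group cell frequencies, male vs female.

    Pools cells whose family-history row and indication column both belong
    to the broad group; only columns valid in both matrices contribute.
    """
    if group not in BROAD_GROUPS:
        raise ValueError(f"group must be one of {sorted(BROAD_GROUPS)}")
    members = BROAD_GROUPS[group]
    cols = [
        c
        for c in FH_CATEGORIES
        if c in members
        and male_matrix.valid_columns[c]
        and female_matrix.valid_columns[c]
    ]
    rows = [r for r in FH_CATEGORIES if r in members]
    male_vals = male_matrix.frequencies.loc[rows, cols].to_numpy().ravel()
    female_vals = female_matrix.frequencies.loc[rows, cols].to_numpy().ravel()
    male_vals = male_vals[~np.isnan(male_vals)]
    female_vals = female_vals[~np.isnan(female_vals)]
    if male_vals.size == 0 or female_vals.size == 0:
        raise ValueError(f"broad group {group!r} has no valid cells to compare")
    res = rank_sum_test(male_vals, female_vals, alternative=alternative)
    return TestResult(
        test_name="mann_whitney_broad_group",
        p_one_tailed=res.p_one_tailed,
        p_two_tailed=res.p_two_tailed,
        direction=alternative,
        degenerate=res.degenerate,
    )
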