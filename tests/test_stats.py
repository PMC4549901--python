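"""2x2 statistics: odds ratios, Fisher tests, Bonferroni, sex ratios."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nddbias.cnv_filter import CnvCall
from nddbias.keywords import bin_individual, default_keyword_map
from nddbias.stats import (
    GenomicDisorderRegion,
    Table2x2,
    bonferroni,
    comorbidity_table,
    fisher_exact,
    odds_ratio_woolf,
    per_cnv_comorbidity,
    sex_ratio,
)
from _oracles import enum_fisher


def test_odds_ratio_woolf_closed_form():
    res = odds_ratio_woolf(Table2x2(20, 10, 10, 20))
    assert res.odds_ratio == pytest.approx(4.0)
    z = sps.norm.ppf(0.975)
    se = math.sqrt(0.05 + 0.1 + 0.1 + 0.05)
    assert res.ci_low == pytest.approx(math.exp(math.log(4) - z * se))
    assert res.ci_high == pytest.approx(math.exp(math.log(4) + z * se))
    assert not res.correction_applied


def test_odds_ratio_balanced_and_zero_cell():
    res = odds_ratio_woolf(Table2x2(10, 10, 10, 10))
    assert res.odds_ratio == pytest.approx(1.0)
    # CI symmetric about 1 on the log scale
    assert res.ci_low * res.ci_high == pytest.approx(1.0)

    res = odds_ratio_woolf(Table2x2(0, 10, 5, 10))
    assert res.correction_applied
    assert res.odds_ratio == pytest.approx((0.5 * 10.5) / (10.5 * 5.5))

    with pytest.raises(ValueError):
        odds_ratio_woolf(Table2x2(0, 0, 0, 0))


@settings(deadline=None, max_examples=80, derandomize=True)
@given(st.tuples(*(st.integers(1, 40),) * 4))
def test_odds_ratio_symmetries(cells):
    a, b, c, d = cells
    orig = odds_ratio_woolf(Table2x2(a, b, c, d)).odds_ratio
    both = odds_ratio_woolf(Table2x2(d, c, b, a)).odds_ratio
    rows = odds_ratio_woolf(Table2x2(c, d, a, b)).odds_ratio
    assert both == pytest.approx(orig, rel=1e-12)
    assert rows == pytest.approx(1.0 / orig, rel=1e-12)


def test_fisher_exact_derived_examples():
    g, l, two = enum_fisher(5, 5, 5, 5)
    res = fisher_exact(Table2x2(5, 5, 5, 5), "greater")
    assert res.p_one_tailed == pytest.approx(g, abs=1e-14)
    assert res.p_two_tailed == pytest.approx(two, abs=1e-14)
    assert res.p_one_tailed >= 0.5  # balanced table

    g, l, two = enum_fisher(1, 9, 11, 3)
    res = fisher_exact(Table2x2(1, 9, 11, 3), "less")
    assert res.p_one_tailed == pytest.approx(l, abs=1e-14)


def test_fisher_degenerate_margins():
    res = fisher_exact(Table2x2(0, 0, 5, 5), "greater")
    assert res.p_one_tailed == 1.0 and res.p_two_tailed == 1.0 and res.degenerate


@settings(deadline=None, max_examples=150, derandomize=True)
@given(st.tuples(*(st.integers(0, 15),) * 4))
def test_fisher_matches_enumeration(cells):
    a, b, c, d = cells
    t = Table2x2(a, b, c, d)
    if t.degenerate:
        return
    g, l, two = enum_fisher(a, b, c, d)
    assert fisher_exact(t, "greater").p_one_tailed == pytest.approx(g, abs=1e-12)
    assert fisher_exact(t, "less").p_one_tailed == pytest.approx(l, abs=1e-12)
    assert fisher_exact(t, "greater").p_two_tailed == pytest.approx(two, abs=1e-12)


def test_fisher_matches_scipy_cross_check():
    import numpy as np

    rng = np.random.default_rng(3)
    for _ in range(100):
        a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
        t = Table2x2(a, b, c, d)
        if t.degenerate:
            continue
        sp_g = sps.fisher_exact([[a, b], [c, d]], alternative="greater").pvalue
        sp_t = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue
        assert fisher_exact(t, "greater").p_one_tailed == pytest.approx(sp_g, abs=1e-10)
        assert fisher_exact(t, "greater").p_two_tailed == pytest.approx(sp_t, abs=1e-9)


def test_bonferroni():
    assert bonferroni([0.01, 0.2], m=2) == [0.02, 0.4]
    assert bonferroni([0.9], m=5) == [1.0]
    assert bonferroni([]) == []
    with pytest.raises(ValueError):
        bonferroni([0.1, 0.2], m=1)
    with pytest.raises(ValueError):
        bonferroni([1.5])
    ps = [0.001, 0.04, 0.7]
    adj = bonferroni(ps)
    assert all(q >= p for p, q in zip(ps, adj)) and all(q <= 1 for q in adj)


@pytest.mark.parametrize(
    "n_male, n_female, rounded",
    [(45, 29, 1.6), (11, 34, 0.3), (42, 10, 4.2)],
)
def test_sex_ratio_reporting(n_male, n_female, rounded):
    res = sex_ratio(n_male, n_female)
    assert res.ratio_rounded == rounded
    assert res.meets_min_n


def test_sex_ratio_undefined_and_reciprocal():
    res = sex_ratio(5, 0)
    assert res.ratio is None and not res.meets_min_n
    assert sex_ratio(7, 3).ratio * sex_ratio(3, 7).ratio == pytest.approx(1.0)


def test_comorbidity_table_counts():
    kmap = default_keyword_map()
    inds = []
    for i, (sex, text) in enumerate(
        [("F", "autism; seizures")] * 2
        + [("F", "autism")] * 2
        + [("M", "autism; seizures")] * 2
        + [("M", "autism")] * 2
    ):
        inds.append(bin_individual(f"s{i}", sex, text, kmap))
    t = comorbidity_table(inds, "autism")
    assert (t.a, t.b, t.c, t.d) == (2, 2, 2, 2)

    girls = [bin_individual("g", "F", "autism", kmap)]
    assert comorbidity_table(girls, "autism").degenerate
    with pytest.raises(ValueError, match="empty"):
        comorbidity_table(girls, "ID/DD")


def test_autism_cohort_reconstruction_from_printed_margins():
    """The printed margins (4,588 boys / 1,284 girls with autism, 3,004
    comorbid overall) admit an integer sex-split whose odds ratio falls in
    the printed interval [1.18, 1.52] and whose non-comorbid male:female
    ratio rounds to 4.2:1; the best split reproduces OR ~ 1.34."""
    n_f, n_m, comorbid = 1_284, 4_588, 3_004
    feasible = []
    for a in range(0, n_f + 1):
        c = comorbid - a
        if not 0 <= c <= n_m:
            continue
        b, d = n_f - a, n_m - c
        if min(b, d) == 0:
            continue
        res = odds_ratio_woolf(Table2x2(a, b, c, d))
        if 1.18 <= res.odds_ratio <= 1.52 and sex_ratio(d, b).ratio_rounded == 4.2:
            feasible.append((abs(res.odds_ratio - 1.34), res.odds_ratio))
    assert feasible
    best_gap, best_or = min(feasible)
    assert best_or == pytest.approx(1.34, abs=0.01)


def _region_carrier(sid, sex, comorbid, region, kmap):
    text = "developmental delay; seizures" if comorbid else "developmental delay"
    ind = bin_individual(sid, sex, text, kmap)
    call = CnvCall(sid, region.chrom, region.start, region.end, region.dosage)
    return ind, call


def test_per_cnv_comorbidity_planted_profiles():
    kmap = default_keyword_map()
    syndromic = GenomicDisorderRegion("synd", "chr1", 0, 1_000_000, "del", "syndromic")
    variable = GenomicDisorderRegion(
        "var", "chr2", 0, 1_000_000, "del", "variable_expressivity"
    )
    tiny = GenomicDisorderRegion("tiny", "chr3", 0, 1_000_000, "dup", "syndromic")
    inds, calls = [], []
    # syndromic: equal comorbidity 5/10 in both sexes -> difference 0
    for i in range(10):
        for sex in "MF":
            ind, call = _region_carrier(f"synd_{sex}{i}", sex, i < 5, syndromic, kmap)
            inds.append(ind)
            calls.append(call)
    # variable expressivity: girls 8/10, boys 5/10 -> difference 0.3
    for i in range(10):
        ind, call = _region_carrier(f"var_M{i}", "M", i < 5, variable, kmap)
        inds.append(ind)
        calls.append(call)
        ind, call = _region_carrier(f"var_F{i}", "F", i < 8, variable, kmap)
        inds.append(ind)
        calls.append(call)
    # below the minimum sample size -> suppressed
    for i in range(9):
        ind, call = _region_carrier(f"tiny_{i}", "M", True, tiny, kmap)
        inds.append(ind)
        calls.append(call)
    df = per_cnv_comorbidity(
        inds, calls, [syndromic, variable, tiny], cohort="ID/DD"
    ).set_index("region")
    assert not df.loc["tiny", "reported"]
    assert "below minimum" in df.loc["tiny", "suppress_reason"]
    assert df.loc["synd", "abs_diff"] == pytest.approx(0.0)
    assert df.loc["var", "abs_diff"] == pytest.approx(0.3)
    by_class = df[df["reported"]].groupby("class")["abs_diff"].mean()
    assert by_class["variable_expressivity"] > by_class["syndromic"]


def test_per_cnv_comorbidity_extreme_difference():
    kmap = default_keyword_map()
    region = GenomicDisorderRegion("r", "chr4", 0, 500_000, "del", "syndromic")
    inds, calls = [], []
    for i in range(6):
        ind, call = _region_carrier(f"f{i}", "F", True, region, kmap)
        inds.append(ind)
        calls.append(call)
        ind, call = _region_carrier(f"m{i}", "M", False, region, kmap)
        inds.append(ind)
        calls.append(call)
    df = per_cnv_comorbidity(inds, calls, [region], cohort="ID/DD")
    assert df.loc[0, "abs_diff"] == pytest.approx(1.0)
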