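"""Synthetic-cohort generator: determinism, round trips, ground truth."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nddbias.cnv_filter import apply_qc
from nddbias.pipeline import bin_dataframe
from nddbias.simulate import (
    SimulationConfig,
    expected_statistics,
    female_comorbidity_rate,
    largest_size_tail,
    simulate_cohort,
)
from nddbias.stats import comorbidity_table, odds_ratio_woolf


def test_seed_determinism():
    config = SimulationConfig(n_individuals=1_500, seed=42)
    p1, c1, _ = simulate_cohort(config)
    p2, c2, _ = simulate_cohort(config)
    pd.testing.assert_frame_equal(p1, p2)
    pd.testing.assert_frame_equal(c1, c2)
    p3, _, _ = simulate_cohort(config, seed=43)
    assert not p1["indication"].equals(p3["indication"])


def test_invalid_config_names_field():
    with pytest.raises(ValueError, match="male_fraction"):
        SimulationConfig(male_fraction=1.5).validate()
    with pytest.raises(ValueError, match="p_autism"):
        SimulationConfig(p_autism=0.9, p_iddd=0.3).validate()
    with pytest.raises(ValueError, match="n_cnv_per_carrier_mean"):
        SimulationConfig(n_cnv_per_carrier_mean=0.5).validate()


def test_indications_rebin_to_generating_categories(small_cohort):
    """Keyword binning recovers the generating category sets exactly."""
    _, pheno, _, _ = small_cohort
    inds = {i.subject_id: i for i in bin_dataframe(pheno)}
    for sid, cats, subs, group, comorbid in zip(
        pheno["subject_id"],
        pheno["truth_categories"],
        pheno["truth_subfeatures"],
        pheno["truth_group"],
        pheno["truth_comorbid"],
    ):
        ind = inds[sid]
        want_cats = frozenset(cats.split("|")) if cats else frozenset()
        want_subs = frozenset(subs.split("|")) if subs else frozenset()
        assert ind.profile.categories == want_cats
        assert ind.profile.ohi_subfeatures == want_subs
        assert ind.cohort.value == group or (
            group == "neither" and ind.cohort.value == "neither"
        )
        if group != "neither":
            assert ind.profile.has_comorbidity == comorbid


def test_expected_statistics_closed_forms():
    config = SimulationConfig()
    truth = expected_statistics(config)
    assert truth.comorbidity_rate_female == pytest.approx(
        female_comorbidity_rate(config.comorbidity_rate_male, 1.34)
    )
    # null OR leaves the female rate unchanged
    assert female_comorbidity_rate(0.5, 1.0) == pytest.approx(0.5)

    single = SimulationConfig(
        cnv_size_logmean_male=math.log(500_000),
        cnv_size_logmean_female=math.log(500_000),
        cnv_size_logsd=1.0,
        n_cnv_per_carrier_mean=1.0,
    )
    want = 1.0 - sps.norm.cdf((math.log(1e6) - math.log(5e5)) / 1.0)
    assert largest_size_tail(single, "M", 1e6) == pytest.approx(float(want))

    # equal sexes and an 8:1 male:female carrier-rate ratio -> ratio exactly 8
    config = SimulationConfig(male_fraction=0.5)
    config.regions = [
        type(config.regions[0])(config.regions[0].region, 0.01, 8.0)
    ]
    truth = expected_statistics(config)
    (ratio,) = truth.region_expected_sex_ratio.values()
    assert ratio == pytest.approx(8.0)


def test_planted_filter_outcomes_match_apply_qc(planted_scenario):
    sc = planted_scenario
    for planted in sc.planted:
        got = apply_qc(planted.call, sc.config, sc.segdups, sc.artifacts, sc.controls)
        assert got == planted.expected, planted.call.subject_id


def _estimate_or(pheno: pd.DataFrame):
    """Woolf OR of sex x comorbidity among diagnosed individuals, via the
    full binning + contingency path."""
    inds = bin_dataframe(pheno)
    return odds_ratio_woolf(comorbidity_table(inds, "union"))


def test_null_or_recovery_large_n():
    config = SimulationConfig(
        n_individuals=50_000, comorbidity_or_female=1.0, seed=5
    )
    pheno, _, _ = simulate_cohort(config)
    res = _estimate_or(pheno)
    # log-OR within 3 SEs of zero
    se = math.log(res.ci_high / res.odds_ratio) / sps.norm.ppf(0.975)
    assert abs(math.log(res.odds_ratio)) < 3 * se


def test_or_error_shrinks_with_sample_size():
    """Estimated OR converges to the generating value: the absolute log-OR
    error at n=50,000 beats n=2,000 in nearly all paired seeds."""
    wins = 0
    n_pairs = 20
    for seed in range(n_pairs):
        errors = {}
        for n in (2_000, 50_000):
            config = SimulationConfig(
                n_individuals=n, comorbidity_or_female=1.34, seed=100 + seed
            )
            pheno, _, _ = simulate_cohort(config)
            sub = pheno[pheno["truth_group"] != "neither"]
            a = int(((sub["sex"] == "F") & sub["truth_comorbid"]).sum())
            b = int(((sub["sex"] == "F") & ~sub["truth_comorbid"]).sum())
            c = int(((sub["sex"] == "M") & sub["truth_comorbid"]).sum())
            d = int(((sub["sex"] == "M") & ~sub["truth_comorbid"]).sum())
            est = odds_ratio_woolf(
                comorbidity_table_from_counts(a, b, c, d)
            ).odds_ratio
            errors[n] = abs(math.log(est / 1.34))
        wins += errors[50_000] < errors[2_000]
    assert wins >= int(0.75 * n_pairs)


def comorbidity_table_from_counts(a, b, c, d):
    from nddbias.stats import Table2x2

    return Table2x2(a, b, c, d)


def test_cnv_sizes_follow_per_sex_lognormal(small_cohort):
    config, pheno, cnv, truth = small_cohort
    background = cnv[cnv["truth_region"] == ""]
    sex = dict(zip(pheno["subject_id"], pheno["sex"]))
    sizes_m = np.log(
        (background["end"] - background["start"])[
            background["subject_id"].map(sex) == "M"
        ].to_numpy(dtype=float)
    )
    assert sizes_m.mean() == pytest.approx(
        config.cnv_size_logmean_male, abs=4 * sizes_m.std() / math.sqrt(len(sizes_m))
    )


def test_planted_scenario_has_decoys_and_boundary_cases(planted_scenario):
    sc = planted_scenario
    ids = {p.call.subject_id for p in sc.planted}
    assert {"case_clean", "case_ctrl_nine", "case_ctrl_eight"} <= ids
    assert sc.controls.n_controls == 8329
    assert sc.segdups.n_intervals > 2  # decoys present
    statuses = {p.call.subject_id: p.expected.passed for p in sc.planted}
    assert statuses["case_ctrl_eight"] and not statuses["case_ctrl_nine"]
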