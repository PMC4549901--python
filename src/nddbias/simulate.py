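"""Synthetic clinical-cohort generator with closed-form ground truth.

Real clinical testing cohorts of this kind are not redistributable, so every
pipeline stage here is exercised on synthetic data whose generating
parameters are known. The generator emulates the *statistical structure* of
a referral cohort:

* a male-skewed population with four diagnostic strata (autism alone, ID/DD
  alone, both, neither);
* comorbidity assigned per sex through an odds multiplier for girls
  (``comorbidity_or_female``), so the female:male comorbidity odds ratio is
  a known constant;
* indications rendered as keyword strings drawn from the default keyword
  map, so keyword binning round-trips them exactly;
* per-sex lognormal CNV sizes (heavy right tail; tail probabilities are
  closed-form), ``1 + Poisson`` calls per carrier, placed on a toy genome;
* genomic-disorder region carriers with per-region male:female carrier-rate
  ratios (planted sex ratios);
* sparse free-text family histories with per-sex category weights.

``expected_statistics`` derives the implied ground truth (rates, OR,
survivor tails, region sex ratios) from a config without sampling;
``simulate_interval_tracks`` plants CNV calls with exactly known filter
outcomes, including the >8-control-carriers boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import keywords as kw
from .cnv_filter import (
    CnvCall,
    ControlCnvSet,
    FilterConfig,
    FilterMetrics,
    FilterOutcome,
    IntervalTrack,
    merge_track,
)
from .family_history import (
    FH_CATEGORIES,
    FhMatrix,
    _DEFAULT_FH_PAIRS,
    fh_matrix_from_records,
)
from .stats import GenomicDisorderRegion

TOY_CHROM_LENGTH = 200_000_000
BURDEN_THRESHOLDS = (1_000_000, 1_500_000, 2_000_000)

_COMORBID_TYPES = (kw.OHI, kw.PSYCHIATRIC, kw.BEHAVIORAL, kw.SPEECH_LANGUAGE,
                   kw.SPECIFIC_LEARNING)
_OHI_SUBS = ("epilepsy", "cardiac", "growth", "dysmorphic", "attention_deficit",
             "cns_malformation", "other_congenital")


@dataclass(frozen=True)
class RegionSpec:
    """A genomic-disorder region plus its planted carrier model.

    ``male_female_rate_ratio`` multiplies the female carrier rate to give the
    male rate, so with equal sex counts the expected carrier sex ratio equals
    the rate ratio exactly.
    """

    region: GenomicDisorderRegion
    carrier_rate_female: float
    male_female_rate_ratio: float

    @property
    def carrier_rate_male(self) -> float:
        return min(1.0, self.carrier_rate_female * self.male_female_rate_ratio)


def default_region_specs() -> list[RegionSpec]:
    mk = GenomicDisorderRegion
    return [
        RegionSpec(mk("16p11.2_del", "chr16", 29_500_000, 30_100_000, "del",
                      "variable_expressivity"), 0.004, 1.6),
        RegionSpec(mk("22q13_del", "chr22", 45_000_000, 46_000_000, "del",
                      "syndromic"), 0.006, 0.3),
        RegionSpec(mk("22q11.2_dup", "chr22", 18_500_000, 21_000_000, "dup",
                      "variable_expressivity"), 0.001, 8.0),
        RegionSpec(mk("1q21.1_del", "chr1", 146_000_000, 147_800_000, "del",
                      "variable_expressivity"), 0.003, 1.4),
        RegionSpec(mk("22q11.2_del", "chr22", 18_500_000, 21_000_000, "del",
                      "syndromic"), 0.003, 1.2),
        RegionSpec(mk("17p11.2_del", "chr17", 16_700_000, 20_200_000, "del",
                      "syndromic"), 0.002, 0.8),
    ]


def _default_ohi_weights() -> dict:
    return {
        "M": {"epilepsy": 0.14, "cardiac": 0.12, "growth": 0.15,
              "dysmorphic": 0.25, "attention_deficit": 0.16,
              "cns_malformation": 0.08, "other_congenital": 0.10},
        "F": {"epilepsy": 0.21, "cardiac": 0.12, "growth": 0.15,
              "dysmorphic": 0.22, "attention_deficit": 0.10,
              "cns_malformation": 0.08, "other_congenital": 0.12},
    }


def _default_fh_weights() -> dict:
    m = (0.16, 0.07, 0.06, 0.04, 0.06, 0.10, 0.05, 0.14, 0.09, 0.07, 0.06, 0.10)
    f = (0.16, 0.07, 0.07, 0.10, 0.07, 0.10, 0.05, 0.08, 0.09, 0.06, 0.09, 0.06)
    return {
        "M": dict(zip(FH_CATEGORIES, m)),
        "F": dict(zip(FH_CATEGORIES, f)),
    }


@dataclass
class SimulationConfig:
    """Generating parameters; defaults emulate a large clinical referral cohort.

    Stratum probabilities mirror the funnel of a clinical testing population
    (a substantial fraction of referrals match no primary diagnosis keyword
    and drop out of the analysis cohorts); the female comorbidity odds
    multiplier and carrier rate are calibration-flavored, not ground truth
    about any real population.
    """

    n_individuals: int = 10_000
    male_fraction: float = 4_588 / 5_872  # autism-cohort flavored male share
    p_autism: float = 3_602 / 54_370
    p_iddd: float = 26_283 / 54_370
    p_both: float = 2_270 / 54_370
    comorbidity_rate_male: float = 0.50
    comorbidity_or_female: float = 1.34
    comorbid_category_weights: dict = field(
        default_factory=lambda: {kw.OHI: 0.55, kw.PSYCHIATRIC: 0.10,
                                 kw.BEHAVIORAL: 0.10, kw.SPEECH_LANGUAGE: 0.15,
                                 kw.SPECIFIC_LEARNING: 0.10}
    )
    p_second_feature: float = 0.30
    ohi_subfeature_weights: dict = field(default_factory=_default_ohi_weights)
    cnv_carrier_rate: float = 8_373 / 32_155
    cnv_size_logmean_male: float = math.log(200_000)
    cnv_size_logmean_female: float = math.log(200_000) + 0.30
    cnv_size_logsd: float = 1.0
    n_cnv_per_carrier_mean: float = 2.0
    regions: list = field(default_factory=default_region_specs)
    fh_rate: float = 386 / 32_155
    fh_category_weights: dict = field(default_factory=_default_fh_weights)
    seed: int = 0

    def validate(self) -> None:
        def _prob(name):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"config field {name} must lie in [0, 1], got {v}")

        if self.n_individuals <= 0:
            raise ValueError("config field n_individuals must be positive")
        for name in ("male_fraction", "p_autism", "p_iddd", "p_both",
                     "comorbidity_rate_male", "p_second_feature",
                     "cnv_carrier_rate", "fh_rate"):
            _prob(name)
        if not 0.0 < self.male_fraction < 1.0:
            raise ValueError("config field male_fraction must lie in (0, 1)")
        if self.p_autism + self.p_iddd + self.p_both > 1.0 + 1e-12:
            raise ValueError(
                "config fields p_autism + p_iddd + p_both must not exceed 1"
            )
        if self.comorbidity_or_female <= 0:
            raise ValueError("config field comorbidity_or_female must be positive")
        if self.n_cnv_per_carrier_mean < 1.0:
            raise ValueError("config field n_cnv_per_carrier_mean must be >= 1")
        if self.cnv_size_logsd <= 0:
            raise ValueError("config field cnv_size_logsd must be positive")
        for sex in ("M", "F"):
            for name, table, vocab in (
                ("ohi_subfeature_weights", self.ohi_subfeature_weights, _OHI_SUBS),
                ("fh_category_weights", self.fh_category_weights, FH_CATEGORIES),
            ):
                w = table[sex]
                if set(w) != set(vocab):
                    raise ValueError(f"config field {name}[{sex}] keys mismatch")
                if abs(sum(w.values()) - 1.0) > 1e-6:
                    raise ValueError(f"config field {name}[{sex}] must sum to 1")
        if abs(sum(self.comorbid_category_weights.values()) - 1.0) > 1e-6:
            raise ValueError("config field comorbid_category_weights must sum to 1")


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form expectations implied by a config (no sampling involved)."""

    comorbidity_rate_male: float
    comorbidity_rate_female: float
    comorbidity_or_female: float
    call_size_tails: dict  # sex -> {threshold: P(call size >= t)}
    largest_size_tails: dict  # sex -> {threshold: P(largest of carrier >= t)}
    region_expected_sex_ratio: dict  # region name -> expected M:F carrier ratio
    cohort_fractions: dict  # stratum -> probability


def female_comorbidity_rate(rate_male: float, or_female: float) -> float:
    odds_m = rate_male / (1.0 - rate_male)
    odds_f = or_female * odds_m
    return odds_f / (1.0 + odds_f)


def call_size_tail(config: SimulationConfig, sex: str, threshold: float) -> float:
    """P(single CNV call size >= threshold) under the per-sex lognormal."""
    mu = (config.cnv_size_logmean_male if sex == "M"
          else config.cnv_size_logmean_female)
    z = (math.log(threshold) - mu) / config.cnv_size_logsd
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def largest_size_tail(config: SimulationConfig, sex: str, threshold: float) -> float:
    """P(largest of a carrier's calls >= t), calls per carrier = 1 + Poisson.

    With K = 1 + Poisson(lam), F the per-call size CDF at t:
    P(max >= t) = 1 - E[F^K] = 1 - F * exp(lam * (F - 1)).
    """
    f_cdf = 1.0 - call_size_tail(config, sex, threshold)
    lam = config.n_cnv_per_carrier_mean - 1.0
    return 1.0 - f_cdf * math.exp(lam * (f_cdf - 1.0))


def expected_statistics(config: SimulationConfig) -> GroundTruth:
    config.validate()
    p_f = female_comorbidity_rate(
        config.comorbidity_rate_male, config.comorbidity_or_female
    )
    fm, ff = config.male_fraction, 1.0 - config.male_fraction
    return GroundTruth(
        comorbidity_rate_male=config.comorbidity_rate_male,
        comorbidity_rate_female=p_f,
        comorbidity_or_female=config.comorbidity_or_female,
        call_size_tails={
            s: {t: call_size_tail(config, s, t) for t in BURDEN_THRESHOLDS}
            for s in ("M", "F")
        },
        largest_size_tails={
            s: {t: largest_size_tail(config, s, t) for t in BURDEN_THRESHOLDS}
            for s in ("M", "F")
        },
        region_expected_sex_ratio={
            rs.region.name: (fm * rs.carrier_rate_male)
            / (ff * rs.carrier_rate_female)
            for rs in config.regions
        },
        cohort_fractions={
            "autism_alone": config.p_autism,
            "iddd_alone": config.p_iddd,
            "both": config.p_both,
            "neither": 1.0 - config.p_autism - config.p_iddd - config.p_both,
        },
    )


def _keyword_pools() -> dict:
    """(category, subfeature) -> list of keywords from the default map."""
    pools: dict = {}
    for e in kw.default_keyword_map().entries:
        pools.setdefault((e.category, e.ohi_subfeature), []).append(e.keyword)
    # flatten non-OHI categories
    out = {
        "autism": pools[(kw.AUTISM, None)],
        "iddd": pools[(kw.IDDD, None)],
        kw.PSYCHIATRIC: pools[(kw.PSYCHIATRIC, None)],
        kw.BEHAVIORAL: pools[(kw.BEHAVIORAL, None)],
        kw.SPEECH_LANGUAGE: pools[(kw.SPEECH_LANGUAGE, None)],
        kw.SPECIFIC_LEARNING: pools[(kw.SPECIFIC_LEARNING, None)],
    }
    for sub in _OHI_SUBS:
        out[("OHI", sub)] = pools[(kw.OHI, sub)]
    return out


_FH_KEYWORDS_BY_CATEGORY: dict = {}
for _k, _cat in _DEFAULT_FH_PAIRS.items():
    _FH_KEYWORDS_BY_CATEGORY.setdefault(_cat, []).append(_k)


def _pick(rng: np.random.Generator, pool: Sequence[str]) -> str:
    return pool[int(rng.integers(len(pool)))]


def simulate_cohort(
    config: SimulationConfig, seed: Optional[int] = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (phenotype table, CNV call table, ground truth).

    Deterministic given config + seed (``seed`` overrides ``config.seed``).
    The phenotype table carries ``truth_*`` columns (generating stratum,
    comorbidity flag, category sets) that the analysis stages ignore but the
    test harness uses for parameter recovery.
    """
    config.validate()
    truth = expected_statistics(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_individuals
    pools = _keyword_pools()

    sex = np.where(rng.random(n) < config.male_fraction, "M", "F")
    strata = rng.choice(
        np.array(["autism_alone", "iddd_alone", "both", "neither"]),
        size=n,
        p=[
            config.p_autism,
            config.p_iddd,
            config.p_both,
            1.0 - config.p_autism - config.p_iddd - config.p_both,
        ],
    )
    p_f = truth.comorbidity_rate_female
    p_comorbid = np.where(sex == "M", config.comorbidity_rate_male, p_f)
    comorbid = (rng.random(n) < p_comorbid) & (strata != "neither")
    second = rng.random(n) < config.p_second_feature
    neither_has_text = rng.random(n) < 0.5

    cat_names = list(config.comorbid_category_weights)
    cat_w = np.array([config.comorbid_category_weights[c] for c in cat_names])
    feat1 = rng.choice(np.array(cat_names, dtype=object), size=n, p=cat_w)
    feat2 = rng.choice(np.array(cat_names, dtype=object), size=n, p=cat_w)
    sub_w = {
        s: np.array([config.ohi_subfeature_weights[s][x] for x in _OHI_SUBS])
        for s in ("M", "F")
    }
    sub1 = np.empty(n, dtype=object)
    sub2 = np.empty(n, dtype=object)
    for s in ("M", "F"):
        mask = sex == s
        k = int(mask.sum())
        sub1[mask] = rng.choice(np.array(_OHI_SUBS, dtype=object), size=k, p=sub_w[s])
        sub2[mask] = rng.choice(np.array(_OHI_SUBS, dtype=object), size=k, p=sub_w[s])

    fh_mask = (rng.random(n) < config.fh_rate) & (strata != "neither")
    fh_second = rng.random(n) < 0.3
    fh_w = {
        s: np.array([config.fh_category_weights[s][c] for c in FH_CATEGORIES])
        for s in ("M", "F")
    }
    fh1 = np.empty(n, dtype=object)
    fh2 = np.empty(n, dtype=object)
    fh_cats_arr = np.array(FH_CATEGORIES, dtype=object)
    for s in ("M", "F"):
        mask = sex == s
        k = int(mask.sum())
        fh1[mask] = rng.choice(fh_cats_arr, size=k, p=fh_w[s])
        fh2[mask] = rng.choice(fh_cats_arr, size=k, p=fh_w[s])

    subject_ids = [f"S{i:06d}" for i in range(n)]
    indications: list[str] = []
    fh_texts: list[str] = []
    truth_categories: list[str] = []
    truth_subfeatures: list[str] = []
    truth_fh: list[str] = []

    for i in range(n):
        words: list[str] = []
        cats: set[str] = set()
        subs: set[str] = set()
        stratum = strata[i]
        if stratum in ("autism_alone", "both"):
            words.append(_pick(rng, pools["autism"]))
            cats.add(kw.AUTISM)
        if stratum in ("iddd_alone", "both"):
            words.append(_pick(rng, pools["iddd"]))
            cats.add(kw.IDDD)
        add_comorbid = comorbid[i] or (stratum == "neither" and neither_has_text[i])
        if add_comorbid:
            items = [(feat1[i], sub1[i])]
            if second[i]:
                items.append((feat2[i], sub2[i]))
            for cat, sub in items:
                if cat == kw.OHI:
                    words.append(_pick(rng, pools[("OHI", sub)]))
                    cats.add(kw.OHI)
                    subs.add(sub)
                else:
                    words.append(_pick(rng, pools[cat]))
                    cats.add(cat)
        if stratum == "neither" and not neither_has_text[i]:
            indications.append("routine genetic evaluation")
        else:
            indications.append("; ".join(dict.fromkeys(words)))
        truth_categories.append("|".join(sorted(cats)))
        truth_subfeatures.append("|".join(sorted(subs)))
        if fh_mask[i]:
            fh_set = {fh1[i]}
            if fh_second[i]:
                fh_set.add(fh2[i])
            fh_words = [
                f"relative with {_pick(rng, _FH_KEYWORDS_BY_CATEGORY[c])}"
                for c in sorted(fh_set)
            ]
            fh_texts.append("; ".join(fh_words))
            truth_fh.append("|".join(sorted(fh_set)))
        else:
            fh_texts.append("")
            truth_fh.append("")

    pheno = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "sex": sex,
            "indication": indications,
            "family_history": fh_texts,
            "truth_group": strata,
            "truth_comorbid": comorbid,
            "truth_categories": truth_categories,
            "truth_subfeatures": truth_subfeatures,
            "truth_fh": truth_fh,
        }
    )

    # CNV calls: background rare calls for carriers, then planted region calls
    carrier = rng.random(n) < config.cnv_carrier_rate
    rows: list[tuple] = []
    lam = config.n_cnv_per_carrier_mean - 1.0
    n_calls = np.where(carrier, 1 + rng.poisson(lam, size=n), 0)
    origins = np.array(["de_novo", "inherited", "unknown"], dtype=object)
    for i in range(n):
        mu = (config.cnv_size_logmean_male if sex[i] == "M"
              else config.cnv_size_logmean_female)
        for _ in range(int(n_calls[i])):
            size = max(1, int(round(rng.lognormal(mu, config.cnv_size_logsd))))
            size = min(size, TOY_CHROM_LENGTH - 1)
            chrom = f"chr{int(rng.integers(1, 23))}"
            start = int(rng.integers(0, TOY_CHROM_LENGTH - size))
            dosage = "del" if rng.random() < 0.5 else "dup"
            origin = str(rng.choice(origins, p=[0.25, 0.55, 0.20]))
            rows.append(
                (chrom, start, start + size, subject_ids[i], dosage, origin, "")
            )
    for rs in config.regions:
        p_region = np.where(sex == "M", rs.carrier_rate_male, rs.carrier_rate_female)
        hit = rng.random(n) < p_region
        r = rs.region
        for i in np.flatnonzero(hit):
            if r.region_class == "syndromic":
                origin = "de_novo"
            else:
                origin = "de_novo" if rng.random() < 0.3 else "inherited"
            rows.append(
                (r.chrom, r.start, r.end, subject_ids[i], r.dosage, origin, r.name)
            )
    cnv = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "subject_id", "dosage", "origin",
            "truth_region",
        ],
    )
    return pheno, cnv, truth


def simulate_fh_cohort(
    n_male: int,
    n_female: int,
    rng: np.random.Generator,
    fh_weights_male: Optional[Sequence[float]] = None,
    fh_weights_female: Optional[Sequence[float]] = None,
    p_second_fh: float = 0.3,
) -> tuple[FhMatrix, FhMatrix]:
    """Generate per-sex family-history matrices directly in category space.

    Each synthetic proband has exactly one indication category (uniform over
    the 12) and one or two family-history categories drawn from the per-sex
    weights (default: equal rates for both sexes — the null used for type-I
    calibration). Returns (male matrix, female matrix).
    """
    k = len(FH_CATEGORIES)
    uniform = np.full(k, 1.0 / k)
    w = {
        "M": np.asarray(fh_weights_male, dtype=float)
        if fh_weights_male is not None
        else uniform,
        "F": np.asarray(fh_weights_female, dtype=float)
        if fh_weights_female is not None
        else uniform,
    }
    cats = np.array(FH_CATEGORIES, dtype=object)
    matrices = {}
    for sex, n in (("M", n_male), ("F", n_female)):
        ind = rng.choice(cats, size=n)
        f1 = rng.choice(cats, size=n, p=w[sex])
        f2 = rng.choice(cats, size=n, p=w[sex])
        extra = rng.random(n) < p_second_fh
        records = [
            (
                frozenset({ind[i]}),
                frozenset({f1[i], f2[i]}) if extra[i] else frozenset({f1[i]}),
            )
            for i in range(n)
        ]
        matrices[sex] = fh_matrix_from_records(records, sex=sex)
    return matrices["M"], matrices["F"]


@dataclass(frozen=True)
class PlantedCall:
    call: CnvCall
    expected: FilterOutcome


@dataclass(frozen=True)
class PlantedFilterScenario:
    segdups: IntervalTrack
    artifacts: IntervalTrack
    controls: ControlCnvSet
    planted: tuple
    config: FilterConfig


def _outcome(call: CnvCall, failed: tuple, carriers: int,
             segdup_frac: float, artifact_frac: float) -> FilterOutcome:
    return FilterOutcome(
        call=call,
        passed=not failed,
        failed_rules=failed,
        metrics=FilterMetrics(
            size_bp=call.size,
            control_carriers=carriers,
            segdup_fraction=segdup_frac,
            artifact_fraction=artifact_frac,
        ),
    )


def simulate_interval_tracks(seed: int = 0) -> PlantedFilterScenario:
    """Plant CNV calls with exactly known QC outcomes.

    Classes planted: clean pass, size failures (both sides and inclusive
    boundaries), sex-chromosome exclusion, control-frequency failure at
    exactly 9 carriers and pass at exactly 8 (the >8/8,329 boundary),
    segmental-duplication overlap 0.6, artifact overlap 0.2, and a combined
    size+segdup failure. Decoy track intervals and non-matching control
    calls are scattered away from the planted calls.
    """
    rng = np.random.default_rng(seed)
    config = FilterConfig()

    segdup_ivs: list[tuple[str, int, int]] = [("chr5", 1_000_000, 1_300_000),
                                              ("chr7", 3_000_000, 3_040_000)]
    artifact_ivs: list[tuple[str, int, int]] = [("chr6", 2_000_000, 2_100_000)]
    for _ in range(30):  # decoys on chromosomes the planted calls avoid
        chrom = f"chr{int(rng.integers(10, 15))}"
        start = int(rng.integers(0, 150_000_000))
        segdup_ivs.append((chrom, start, start + int(rng.integers(1_000, 200_000))))
        start = int(rng.integers(0, 150_000_000))
        artifact_ivs.append((chrom, start, start + int(rng.integers(1_000, 50_000))))
    segdups = merge_track(segdup_ivs, name="segdups")
    artifacts = merge_track(artifact_ivs, name="artifacts")

    control_calls = [
        CnvCall(f"ctrl_nine_{j}", "chr4", 5_000_000, 5_500_000, "dup")
        for j in range(9)
    ] + [
        CnvCall(f"ctrl_eight_{j}", "chr4", 20_000_000, 20_500_000, "del")
        for j in range(8)
    ]
    for j in range(40):  # decoy control calls far from planted cases
        chrom = f"chr{int(rng.integers(10, 15))}"
        start = int(rng.integers(0, 150_000_000))
        control_calls.append(
            CnvCall(
                f"ctrl_decoy_{j}", chrom, start,
                start + int(rng.integers(60_000, 400_000)),
                "del" if rng.random() < 0.5 else "dup",
            )
        )
    controls = ControlCnvSet(control_calls, n_controls=8329)

    def call(sid, chrom, start, end, dosage):
        return CnvCall(sid, chrom, start, end, dosage)

    planted = (
        PlantedCall(
            c := call("case_clean", "chr3", 10_000_000, 10_200_000, "del"),
            _outcome(c, (), 0, 0.0, 0.0),
        ),
        PlantedCall(
            c := call("case_small", "chr3", 20_000_000, 20_040_000, "dup"),
            _outcome(c, ("size",), 0, 0.0, 0.0),
        ),
        PlantedCall(
            c := call("case_big", "chr3", 30_000_000, 65_000_000, "del"),
            _outcome(c, ("size",), 0, 0.0, 0.0),
        ),
        PlantedCall(
            c := call("case_min_size", "chr8", 1_000_000, 1_050_000, "del"),
            _outcome(c, (), 0, 0.0, 0.0),
        ),
        PlantedCall(
            c := call("case_max_size", "chr9", 10_000_000, 40_000_000, "dup"),
            _outcome(c, (), 0, 0.0, 0.0),
        ),
        PlantedCall(
            c := call("case_chrx", "chrX", 5_000_000, 5_200_000, "del"),
            _outcome(c, ("autosome",), 0, 0.0, 0.0),
        ),
        PlantedCall(
            c := call("case_ctrl_nine", "chr4", 5_000_000, 5_500_000, "dup"),
            _outcome(c, ("control_frequency",), 9, 0.0, 0.0),
        ),
        PlantedCall(
            c := call("case_ctrl_eight", "chr4", 20_000_000, 20_500_000, "del"),
            _outcome(c, (), 8, 0.0, 0.0),
        ),
        PlantedCall(
            c := call("case_segdup", "chr5", 1_000_000, 1_500_000, "del"),
            _outcome(c, ("segdup",), 0, 0.6, 0.0),
        ),
        PlantedCall(
            c := call("case_artifact", "chr6", 2_000_000, 2_500_000, "dup"),
            _outcome(c, ("artifact",), 0, 0.0, 0.2),
        ),
        PlantedCall(
            c := call("case_size_and_segdup", "chr7", 3_000_000, 3_040_000, "del"),
            _outcome(c, ("size", "segdup"), 0, 1.0, 0.0),
        ),
    )
    return PlantedFilterScenario(
        segdups=segdups,
        artifacts=artifacts,
        controls=controls,
        planted=planted,
        config=config,
    )
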