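"""End-to-end pipeline orchestration and report writing.

Stage order: load cohort -> keyword binning -> CNV QC filtering ->
sex-stratified comorbidity statistics -> sex ratios (overall and per
genomic-disorder region) -> largest-CNV burden -> family-history matrices.
Every stage's input/passed/failed record counts are conserved and recorded
in the run report; re-running with identical inputs, config and seed
produces identical outputs (the report embeds a config hash).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io
from .burden import burden_threshold_test, default_grid, survivor_curve
from .cnv_filter import FilterConfig, apply_qc_batch, merge_track
from .cnv_filter import ControlCnvSet
from .family_history import (
    BROAD_GROUPS,
    FH_CATEGORIES,
    FhKeywordMap,
    bin_family_history,
    build_fh_matrix,
    compare_broad_groups,
    compare_fh_row,
    default_fh_map,
)
from .keywords import (
    AUTISM,
    IDDD,
    CohortLabel,
    Individual,
    KeywordMap,
    assign_cohort,
    bin_indication,
    cohort_counts,
    default_keyword_map,
    in_cohort,
)
from .stats import (
    bonferroni,
    comorbidity_table,
    fisher_exact,
    odds_ratio_woolf,
    per_cnv_comorbidity,
    sex_ratio,
)


@dataclass
class PipelineConfig:
    cohort_path: str
    out_dir: str
    keywords_path: Optional[str] = None
    cnv_calls_path: Optional[str] = None
    segdups_path: Optional[str] = None
    artifacts_path: Optional[str] = None
    controls_path: Optional[str] = None
    regions_path: Optional[str] = None
    n_controls: int = 8329
    filter: FilterConfig = field(default_factory=FilterConfig)
    burden_thresholds: Sequence[int] = (1_000_000, 1_500_000, 2_000_000)
    # one-tailed directions, declared before any data is read
    comorbidity_direction: str = "greater"  # female comorbidity odds greater
    burden_direction: str = "greater"  # female burden greater
    fh_row_direction: str = "greater"  # male FH frequency greater
    min_n: int = 10
    run_burden: bool = True
    run_family_history: bool = True
    seed: int = 0

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["burden_thresholds"] = list(self.burden_thresholds)
        return d


@dataclass
class RunReport:
    config_hash: str
    counts: dict
    outputs: list
    skipped: list

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "counts": self.counts,
                "outputs": self.outputs,
                "skipped": self.skipped,
            },
            indent=2,
            sort_keys=True,
        )


def bin_dataframe(
    df: pd.DataFrame,
    kmap: Optional[KeywordMap] = None,
    fh_map: Optional[FhKeywordMap] = None,
) -> list[Individual]:
    """Bin a cohort table into Individuals (indications + family history).

    Unique indication strings are binned once and reused, which keeps large
    simulated cohorts fast.
    """
    kmap = kmap or default_keyword_map()
    fh_map = fh_map or default_fh_map()
    profiles = {text: bin_indication(text, kmap) for text in df["indication"].unique()}
    fh_col = (
        df["family_history"]
        if "family_history" in df.columns
        else pd.Series("", index=df.index)
    )
    fh_sets = {text: bin_family_history(text, fh_map) for text in fh_col.unique()}
    out = []
    for sid, sex, text, fh_text in zip(
        df["subject_id"], df["sex"], df["indication"], fh_col
    ):
        profile = profiles[text]
        out.append(
            Individual(
                subject_id=sid,
                sex=sex,
                indication_text=text,
                profile=profile,
                cohort=assign_cohort(profile),
                family_history_text=fh_text or None,
                fh_categories=fh_sets[fh_text],
            )
        )
    return out


def binned_table(individuals: Sequence[Individual]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": i.subject_id,
                "sex": i.sex,
                "cohort": i.cohort.value,
                "categories": "|".join(sorted(i.profile.categories)),
                "ohi_subfeatures": "|".join(sorted(i.profile.ohi_subfeatures)),
                "multiple_features": i.profile.multiple_features,
                "multiple_ohi": i.profile.multiple_ohi,
                "has_comorbidity": i.profile.has_comorbidity,
                "fh_categories": "|".join(sorted(i.fh_categories)),
            }
            for i in individuals
        ]
    )


def comorbidity_report(
    individuals: Sequence[Individual],
    direction: str = "greater",
    bonferroni_m: Optional[int] = None,
) -> pd.DataFrame:
    """Female-vs-male comorbidity tables, ORs and Fisher tests per cohort."""
    rows = []
    for cohort in (AUTISM, IDDD):
        table = comorbidity_table(individuals, cohort)
        orr = odds_ratio_woolf(table)
        test = fisher_exact(table, alternative=direction)
        rows.append(
            {
                "cohort": cohort,
                "feature": "any_comorbidity",
                "a": table.a,
                "b": table.b,
                "c": table.c,
                "d": table.d,
                "odds_ratio": orr.odds_ratio,
                "ci_low": orr.ci_low,
                "ci_high": orr.ci_high,
                "p_one_tailed": test.p_one_tailed,
                "p_two_tailed": test.p_two_tailed,
            }
        )
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = bonferroni(list(df["p_one_tailed"]), m=bonferroni_m)
    return df


def run_pipeline(config: PipelineConfig) -> RunReport:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(config.to_jsonable())
    counts: dict = {}
    outputs: list[str] = []
    skipped: list[str] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        outputs.append(name)

    cohort_df = io.load_cohort_table(config.cohort_path)
    counts["cohort_input"] = len(cohort_df)
    kmap = (
        io.load_keyword_map(config.keywords_path)
        if config.keywords_path
        else default_keyword_map()
    )
    individuals = bin_dataframe(cohort_df, kmap)
    label_counts = cohort_counts(individuals)
    counts["binned"] = int(label_counts["total"].sum())
    counts["cohort_neither"] = int(
        label_counts.loc[CohortLabel.NEITHER.value, "total"]
    )
    counts["cohort_autism"] = int(
        label_counts.loc[CohortLabel.AUTISM_ALONE.value, "total"]
        + label_counts.loc[CohortLabel.BOTH.value, "total"]
    )
    counts["cohort_iddd"] = int(
        label_counts.loc[CohortLabel.IDDD_ALONE.value, "total"]
        + label_counts.loc[CohortLabel.BOTH.value, "total"]
    )
    emit(binned_table(individuals), "binned.tsv")
    emit(label_counts.reset_index(names="cohort_label"), "cohort_counts.tsv")

    # CNV filtering
    passing_calls = []
    if config.cnv_calls_path:
        calls = io.load_cnv_calls(config.cnv_calls_path)
        segdups = merge_track(
            io.load_track_intervals(config.segdups_path)
            if config.segdups_path
            else [],
            name="segdups",
        )
        artifacts = merge_track(
            io.load_track_intervals(config.artifacts_path)
            if config.artifacts_path
            else [],
            name="artifacts",
        )
        controls = ControlCnvSet(
            io.load_cnv_calls(config.controls_path) if config.controls_path else [],
            n_controls=config.n_controls,
        )
        outcomes = apply_qc_batch(calls, config.filter, segdups, artifacts, controls)
        counts["cnv_input"] = len(outcomes)
        counts["cnv_passed"] = sum(o.passed for o in outcomes)
        counts["cnv_failed"] = counts["cnv_input"] - counts["cnv_passed"]
        passing_calls = [o.call for o in outcomes if o.passed]
        log = pd.DataFrame(
            [
                {
                    "subject_id": o.call.subject_id,
                    "chrom": o.call.chrom,
                    "start": o.call.start,
                    "end": o.call.end,
                    "dosage": o.call.dosage,
                    "size_bp": o.metrics.size_bp,
                    "control_carriers": o.metrics.control_carriers,
                    "segdup_fraction": o.metrics.segdup_fraction,
                    "artifact_fraction": o.metrics.artifact_fraction,
                    "passed": o.passed,
                    "failed_rules": ",".join(o.failed_rules),
                }
                for o in outcomes
            ]
        )
        emit(log, "filter_log.tsv")
        io.write_cnv_calls(passing_calls, out_dir / "passed.bed")
        outputs.append("passed.bed")
    else:
        skipped.append("cnv_filtering")

    # comorbidity statistics
    emit(
        comorbidity_report(individuals, direction=config.comorbidity_direction),
        "comorbidity.tsv",
    )

    # sex ratios
    ratio_rows = []
    for cohort in (AUTISM, IDDD):
        members = [i for i in individuals if in_cohort(i, cohort)]
        res = sex_ratio(
            sum(i.sex == "M" for i in members),
            sum(i.sex == "F" for i in members),
            min_n=config.min_n,
        )
        ratio_rows.append(
            {
                "cohort": cohort,
                "scope": "all",
                "n_male": res.n_male,
                "n_female": res.n_female,
                "ratio": res.ratio,
                "ratio_reported": io.format_ratio(res.ratio),
                "meets_min_n": res.meets_min_n,
            }
        )
    regions = io.load_regions(config.regions_path) if config.regions_path else []
    if regions and passing_calls:
        from .stats import assign_regions

        carriers = assign_regions(passing_calls, regions)
        by_id = {i.subject_id: i for i in individuals}
        for r in regions:
            members = [
                by_id[s]
                for s in carriers[r.name]
                if s in by_id and by_id[s].cohort != CohortLabel.NEITHER
            ]
            res = sex_ratio(
                sum(i.sex == "M" for i in members),
                sum(i.sex == "F" for i in members),
                min_n=config.min_n,
            )
            ratio_rows.append(
                {
                    "cohort": "union",
                    "scope": r.name,
                    "n_male": res.n_male,
                    "n_female": res.n_female,
                    "ratio": res.ratio,
                    "ratio_reported": io.format_ratio(res.ratio),
                    "meets_min_n": res.meets_min_n,
                }
            )
        for cohort in (AUTISM, IDDD):
            emit(
                per_cnv_comorbidity(
                    individuals, passing_calls, regions, cohort, min_n=config.min_n
                ),
                f"region_comorbidity_{'autism' if cohort == AUTISM else 'iddd'}.tsv",
            )
    emit(pd.DataFrame(ratio_rows), "sex_ratios.tsv")

    # burden
    if config.run_burden and passing_calls:
        largest: dict[str, int] = {}
        for c in passing_calls:
            if c.size > largest.get(c.subject_id, 0):
                largest[c.subject_id] = c.size
        by_id = {i.subject_id: i for i in individuals}
        curve_rows = []
        comp_rows = []
        grid = default_grid()
        for cohort in (AUTISM, IDDD):
            sizes = {
                "M": [
                    s
                    for sid, s in largest.items()
                    if sid in by_id
                    and by_id[sid].sex == "M"
                    and in_cohort(by_id[sid], cohort)
                ],
                "F": [
                    s
                    for sid, s in largest.items()
                    if sid in by_id
                    and by_id[sid].sex == "F"
                    and in_cohort(by_id[sid], cohort)
                ],
            }
            for sex, vals in sizes.items():
                if not vals:
                    continue
                curve = survivor_curve(vals, grid)
                curve_rows.extend(
                    {
                        "cohort": cohort,
                        "sex": sex,
                        "threshold_bp": t,
                        "freq": f,
                        "n_exceed": k,
                        "n": curve.n,
                    }
                    for t, f, k in zip(curve.grid, curve.freq, curve.n_exceed)
                )
            if sizes["F"] and sizes["M"]:
                ps = []
                for t in config.burden_thresholds:
                    comp = burden_threshold_test(
                        sizes["F"], sizes["M"], t,
                        alternative=config.burden_direction,
                    )
                    ps.append(comp.p_one_tailed)
                    comp_rows.append(
                        {
                            "cohort": cohort,
                            "threshold_bp": comp.threshold_bp,
                            "n_exceed_female": comp.n_exceed_a,
                            "n_female": comp.n_a,
                            "n_exceed_male": comp.n_exceed_b,
                            "n_male": comp.n_b,
                            "p_one_tailed": comp.p_one_tailed,
                            "p_two_tailed": comp.p_two_tailed,
                        }
                    )
                adj = bonferroni(ps, m=len(config.burden_thresholds))
                for row, p_adj in zip(comp_rows[-len(ps):], adj):
                    row["p_bonferroni"] = p_adj
        emit(pd.DataFrame(curve_rows), "burden_curves.tsv")
        emit(pd.DataFrame(comp_rows), "burden_tests.tsv")
        counts["burden_carriers"] = len(largest)
    elif config.run_burden:
        skipped.append("burden")

    # family history
    if config.run_family_history and any(i.fh_categories for i in individuals):
        male_m = build_fh_matrix(individuals, sex="M")
        female_m = build_fh_matrix(individuals, sex="F")
        for m, name in ((male_m, "fh_male"), (female_m, "fh_female")):
            emit(m.frequencies.reset_index(names="family_history"),
                 f"{name}_freq.tsv")
            emit(m.numerators.reset_index(names="family_history"),
                 f"{name}_num.tsv")
        fh_tests = []
        for cat in FH_CATEGORIES:
            try:
                res = compare_fh_row(
                    male_m.frequencies.loc[cat],
                    female_m.frequencies.loc[cat],
                    alternative=config.fh_row_direction,
                )
            except ValueError:
                continue
            fh_tests.append(
                {
                    "comparison": f"row:{cat}",
                    "test": res.test_name,
                    "p_one_tailed": res.p_one_tailed,
                    "p_two_tailed": res.p_two_tailed,
                    "degenerate": res.degenerate,
                }
            )
        for group in BROAD_GROUPS:
            try:
                res = compare_broad_groups(
                    male_m, female_m, group, alternative=config.fh_row_direction
                )
            except ValueError:
                continue
            fh_tests.append(
                {
                    "comparison": f"group:{group}",
                    "test": res.test_name,
                    "p_one_tailed": res.p_one_tailed,
                    "p_two_tailed": res.p_two_tailed,
                    "degenerate": res.degenerate,
                }
            )
        emit(pd.DataFrame(fh_tests), "fh_tests.tsv")
        counts["fh_individuals"] = sum(bool(i.fh_categories) for i in individuals)
    elif config.run_family_history:
        skipped.append("family_history")

    report = RunReport(
        config_hash=chash, counts=counts, outputs=outputs, skipped=skipped
    )
    (out_dir / "report.json").write_text(report.to_json())
    return report
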