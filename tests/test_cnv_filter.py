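"""Interval arithmetic and the rare-CNV QC filter."""

import dataclasses

import pytest

from nddbias.cnv_filter import (
    CnvCall,
    ControlCnvSet,
    FilterConfig,
    apply_qc,
    apply_qc_batch,
    control_carrier_count,
    covered_fraction,
    largest_autosomal_cnv,
    merge_track,
)


def brute_force_covered_fraction(call, intervals):
    """Per-base membership count (independent oracle, small calls only)."""
    covered = 0
    for pos in range(call.start, call.end):
        covered += any(
            chrom == call.chrom and s <= pos < e for chrom, s, e in intervals
        )
    return covered / call.size


def test_merge_track_examples():
    t = merge_track([("chr1", 100, 200), ("chr1", 150, 250)])
    assert t.intervals() == [("chr1", 100, 250)]
    assert merge_track([]).intervals() == []
    t = merge_track([("chr1", 100, 200), ("chr2", 100, 200)])
    assert t.intervals() == [("chr1", 100, 200), ("chr2", 100, 200)]
    # touching intervals merge; covered bases conserved
    t = merge_track([("chr1", 0, 10), ("chr1", 10, 20)])
    assert t.intervals() == [("chr1", 0, 20)] and t.total_bases() == 20


def test_merge_track_idempotent_and_validating():
    raw = [("chr1", 5, 50), ("chr1", 40, 60), ("chr1", 100, 120)]
    once = merge_track(raw)
    twice = merge_track(once.intervals())
    assert once.intervals() == twice.intervals()
    with pytest.raises(ValueError, match="interval 1"):
        merge_track([("chr1", 0, 10), ("chr1", 20, 20)])


def test_covered_fraction_examples():
    call = CnvCall("s", "chr1", 100, 200, "del")
    assert covered_fraction(call, merge_track([("chr1", 150, 250)])) == 0.5
    assert covered_fraction(call, merge_track([])) == 0.0
    call = CnvCall("s", "chr1", 0, 1000, "del")
    track = merge_track([("chr1", 100, 300), ("chr1", 250, 600)])
    assert covered_fraction(call, track) == brute_force_covered_fraction(
        call, [("chr1", 100, 300), ("chr1", 250, 600)]
    ) == 0.5


def test_covered_fraction_matches_brute_force_randomized(rng):
    for _ in range(200):
        start = int(rng.integers(0, 5_000))
        size = int(rng.integers(1, 2_000))
        call = CnvCall("s", "chr1", start, start + size, "del")
        intervals = []
        for _ in range(int(rng.integers(0, 8))):
            s = int(rng.integers(0, 8_000))
            intervals.append(("chr1", s, s + int(rng.integers(1, 1_500))))
        track = merge_track(intervals)
        expected = brute_force_covered_fraction(call, intervals)
        assert covered_fraction(call, track) == pytest.approx(expected, abs=1e-12)
        # invariance to input order and pre-splitting
        rng.shuffle(intervals)
        split = []
        for chrom, s, e in intervals:
            mid = (s + e) // 2
            if mid > s:
                split.extend([(chrom, s, mid), (chrom, mid, e)])
            else:
                split.append((chrom, s, e))
        assert covered_fraction(call, merge_track(split)) == pytest.approx(
            expected, abs=1e-12
        )


def test_control_carrier_count_reciprocal_matching():
    controls = ControlCnvSet(
        [
            CnvCall("A", "chr1", 1400, 2400, "del"),
            CnvCall("B", "chr1", 1900, 3000, "del"),
            CnvCall("C", "chr1", 1400, 2400, "dup"),
        ]
    )
    call = CnvCall("case", "chr1", 1000, 2000, "del")
    # only A matches: reciprocal overlap 600/1000 both ways; B fails
    # reciprocity (overlap 100), C fails dosage
    assert control_carrier_count(call, controls, reciprocal_overlap=0.5) == 1
    assert control_carrier_count(call, ControlCnvSet([])) == 0
    # two matching calls from one subject count once
    controls = ControlCnvSet(
        [
            CnvCall("A", "chr1", 900, 1900, "del"),
            CnvCall("A", "chr1", 1100, 2100, "del"),
        ]
    )
    assert control_carrier_count(call, controls) == 1


def brute_force_carriers(call, control_calls, r=0.5):
    subjects = set()
    for c in control_calls:
        if c.chrom != call.chrom or c.dosage != call.dosage:
            continue
        ov = min(c.end, call.end) - max(c.start, call.start)
        if ov >= r * call.size and ov >= r * c.size:
            subjects.add(c.subject_id)
    return len(subjects)


def test_control_carrier_count_matches_brute_force(rng):
    for _ in range(50):
        call = CnvCall("case", "chr2", 10_000, 10_000 + int(rng.integers(500, 5_000)),
                       "del" if rng.random() < 0.5 else "dup")
        control_calls = []
        for j in range(int(rng.integers(0, 30))):
            s = int(rng.integers(5_000, 18_000))
            control_calls.append(
                CnvCall(
                    f"c{int(rng.integers(0, 10))}", "chr2", s,
                    s + int(rng.integers(200, 6_000)),
                    "del" if rng.random() < 0.5 else "dup",
                )
            )
        controls = ControlCnvSet(control_calls)
        assert control_carrier_count(call, controls) == brute_force_carriers(
            call, control_calls
        )


EMPTY = merge_track([])
NO_CONTROLS = ControlCnvSet([])
CONFIG = FilterConfig()


@pytest.mark.parametrize(
    "call, expected_failed",
    [
        (CnvCall("s", "chr2", 0, 40_000, "del"), ("size",)),
        (CnvCall("s", "chrX", 0, 200_000, "del"), ("autosome",)),
        (CnvCall("s", "chr2", 0, 200_000, "del"), ()),
        (CnvCall("s", "chr2", 0, 50_000, "del"), ()),  # inclusive lower bound
        (CnvCall("s", "chr2", 0, 30_000_000, "del"), ()),  # inclusive upper bound
        (CnvCall("s", "chr2", 0, 30_000_001, "del"), ("size",)),
    ],
)
def test_apply_qc_rules(call, expected_failed):
    out = apply_qc(call, CONFIG, EMPTY, EMPTY, NO_CONTROLS)
    assert out.failed_rules == expected_failed
    assert out.passed == (not expected_failed)


def test_control_frequency_boundary():
    call = CnvCall("case", "chr1", 0, 100_000, "del")

    def controls(k):
        return ControlCnvSet(
            [CnvCall(f"c{j}", "chr1", 0, 100_000, "del") for j in range(k)]
        )

    ok = apply_qc(call, CONFIG, EMPTY, EMPTY, controls(8))
    assert ok.passed and ok.metrics.control_carriers == 8
    bad = apply_qc(call, CONFIG, EMPTY, EMPTY, controls(9))
    assert bad.failed_rules == ("control_frequency",)
    assert bad.metrics.control_carriers == 9


def test_all_rules_evaluated_with_complete_metrics():
    call = CnvCall("s", "chrX", 0, 40_000, "del")
    track = merge_track([("chrX", 0, 40_000)])
    out = apply_qc(call, CONFIG, track, track, NO_CONTROLS)
    assert out.failed_rules == ("autosome", "size", "segdup", "artifact")
    assert out.metrics.segdup_fraction == 1.0
    assert out.metrics.artifact_fraction == 1.0


def _random_calls(rng, n=60):
    calls = []
    for i in range(n):
        chrom = f"chr{int(rng.integers(1, 24))}"
        chrom = "chrX" if chrom == "chr23" else chrom
        start = int(rng.integers(0, 1_000_000))
        size = int(10 ** rng.uniform(3.5, 7.8))
        calls.append(CnvCall(f"s{i}", chrom, start, start + size,
                             "del" if rng.random() < 0.5 else "dup"))
    return calls


def test_filter_conservation_and_threshold_monotonicity(rng):
    calls = _random_calls(rng)
    segdups = merge_track([("chr1", 0, 500_000), ("chr5", 0, 2_000_000)])
    artifacts = merge_track([("chr2", 100_000, 400_000)])
    controls = ControlCnvSet(
        [CnvCall(f"c{j}", "chr3", 0, 300_000, "del") for j in range(12)]
    )
    outcomes = apply_qc_batch(calls, CONFIG, segdups, artifacts, controls)
    assert len(outcomes) == len(calls)
    assert all(o.passed == (len(o.failed_rules) == 0) for o in outcomes)
    passed = {o.call.subject_id for o in outcomes if o.passed}
    relaxed = dataclasses.replace(
        CONFIG,
        min_size_bp=1,
        max_size_bp=10**9,
        max_control_carriers=100,
        segdup_max_fraction=1.0,
        artifact_max_fraction=1.0,
    )
    outcomes2 = apply_qc_batch(calls, relaxed, segdups, artifacts, controls)
    passed2 = {o.call.subject_id for o in outcomes2 if o.passed}
    assert passed <= passed2


def test_largest_autosomal_cnv():
    calls = [
        CnvCall("s", "chr1", 0, 120_000, "del"),
        CnvCall("s", "chr2", 0, 950_000, "dup"),
        CnvCall("s", "chr3", 0, 2_400_000, "del"),
    ]
    assert largest_autosomal_cnv(calls) == 2_400_000
    assert largest_autosomal_cnv([]) is None
    assert largest_autosomal_cnv([CnvCall("s", "chr1", 0, 50_000, "del")]) == 50_000
    with pytest.raises(ValueError, match="multiple subjects"):
        largest_autosomal_cnv(
            [CnvCall("a", "chr1", 0, 10_000, "del"),
             CnvCall("b", "chr1", 0, 10_000, "del")]
        )
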