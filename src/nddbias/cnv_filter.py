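"""Rare-CNV quality-control filtering.

Implements the standard rare-CNV inclusion filter for clinical microarray
call sets, as interval arithmetic on BED-convention (0-based, half-open)
coordinates:

* autosomes only (chr1..chr22; sex chromosomes are excluded explicitly
  because control data there are unreliable),
* size window 50 kbp <= size <= 30 Mbp (boundaries inclusive),
* control frequency: removed when carried by more than ``max_control_carriers``
  distinct control subjects (default >8 of 8,329, i.e. >~0.1 %), where a
  control "carries" the call if it has a same-dosage call with >=50 %
  reciprocal overlap,
* segmental-duplication mask: removed when the track covers >=50 % of the call,
* artifact blacklist: removed when the track covers >=10 % of the call
  (dosage-agnostic by default; the blacklist is positional).

All rules are always evaluated (no short-circuiting) so every
:class:`FilterOutcome` carries a complete metric set, and relaxing any
threshold can only grow the pass set (monotonicity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

AUTOSOMES = frozenset(f"chr{i}" for i in range(1, 23))
DOSAGES = ("del", "dup")
ORIGINS = ("de_novo", "inherited", "unknown")

RULE_AUTOSOME = "autosome"
RULE_SIZE = "size"
RULE_CONTROL = "control_frequency"
RULE_SEGDUP = "segdup"
RULE_ARTIFACT = "artifact"
RULE_ORDER = (RULE_AUTOSOME, RULE_SIZE, RULE_CONTROL, RULE_SEGDUP, RULE_ARTIFACT)


@dataclass(frozen=True)
class CnvCall:
    """One deletion/duplication interval (0-based half-open coordinates)."""

    subject_id: str
    chrom: str
    start: int
    end: int
    dosage: str
    origin: Optional[str] = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"CNV {self.subject_id} {self.chrom}:{self.start}-{self.end}: "
                "end must exceed start"
            )
        if self.start < 0:
            raise ValueError(f"CNV start must be non-negative, got {self.start}")
        if self.dosage not in DOSAGES:
            raise ValueError(f"dosage must be one of {DOSAGES}, got {self.dosage!r}")
        if self.origin is not None and self.origin not in ORIGINS:
            raise ValueError(f"origin must be one of {ORIGINS}, got {self.origin!r}")

    @property
    def size(self) -> int:
        return self.end - self.start


class IntervalTrack:
    """Merged genomic interval set (per chromosome: sorted, disjoint, non-adjacent)."""

    def __init__(self, name: str, per_chrom: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.name = name
        self._per_chrom = per_chrom

    @property
    def n_intervals(self) -> int:
        return sum(len(s) for s, _ in self._per_chrom.values())

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._per_chrom):
            starts, ends = self._per_chrom[chrom]
            out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
        return out

    def total_bases(self) -> int:
        return sum(int((e - s).sum()) for s, e in self._per_chrom.values())

    def covered_bases(self, chrom: str, start: int, end: int) -> int:
        """Bases of [start, end) on *chrom* covered by the track union."""
        if chrom not in self._per_chrom:
            return 0
        starts, ends = self._per_chrom[chrom]
        # intervals possibly overlapping the query
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return int(np.maximum(e - s, 0).sum())


def merge_track(
    intervals: Iterable[tuple[str, int, int]], name: str = "track"
) -> IntervalTrack:
    """Union raw (chrom, start, end) intervals into a merged :class:`IntervalTrack`.

    Touching intervals are merged too; total covered bases are preserved.
    Malformed intervals (end <= start) raise with their input position.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, (chrom, start, end) in enumerate(intervals):
        if end <= start:
            raise ValueError(
                f"interval {i} ({chrom}:{start}-{end}): end must exceed start"
            )
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        per_chrom[chrom] = (
            np.array([m[0] for m in merged], dtype=np.int64),
            np.array([m[1] for m in merged], dtype=np.int64),
        )
    return IntervalTrack(name, per_chrom)


def covered_fraction(call: CnvCall, track: IntervalTrack) -> float:
    """Fraction of the call's bases covered by the track union (call-denominated)."""
    return track.covered_bases(call.chrom, call.start, call.end) / call.size


class ControlCnvSet:
    """Control-cohort CNV calls with per-subject carrier counting."""

    def __init__(self, calls: Iterable[CnvCall], n_controls: int = 8329):
        if n_controls <= 0:
            raise ValueError("n_controls must be positive")
        self.calls = list(calls)
        self.n_controls = n_controls
        self._index: dict[tuple[str, Optional[str]], tuple] = {}
        by_key: dict[tuple, list[CnvCall]] = {}
        for c in self.calls:
            by_key.setdefault((c.chrom, c.dosage), []).append(c)
            by_key.setdefault((c.chrom, None), []).append(c)
        for key, group in by_key.items():
            self._index[key] = (
                np.array([c.start for c in group], dtype=np.int64),
                np.array([c.end for c in group], dtype=np.int64),
                np.array([c.subject_id for c in group], dtype=object),
            )

    def __len__(self) -> int:
        return len(self.calls)


def control_carrier_count(
    call: CnvCall,
    controls: ControlCnvSet,
    reciprocal_overlap: float = 0.5,
    match_dosage: bool = True,
) -> int:
    """Distinct control subjects with >=1 call matching *call*.

    Match = same dosage (when ``match_dosage``) and reciprocal overlap at
    least ``reciprocal_overlap`` (each interval covers that fraction of the
    other).
    """
    key = (call.chrom, call.dosage if match_dosage else None)
    idx = controls._index.get(key)
    if idx is None:
        return 0
    starts, ends, subjects = idx
    ov = np.minimum(ends, call.end) - np.maximum(starts, call.start)
    sizes = ends - starts
    match = (ov >= reciprocal_overlap * call.size) & (ov >= reciprocal_overlap * sizes)
    return len(set(subjects[match]))


@dataclass(frozen=True)
class FilterConfig:
    min_size_bp: int = 50_000
    max_size_bp: int = 30_000_000
    max_control_carriers: int = 8
    segdup_max_fraction: float = 0.50
    artifact_max_fraction: float = 0.10
    control_reciprocal_overlap: float = 0.5
    control_match_dosage: bool = True
    artifact_match_dosage: bool = False

    def __post_init__(self):
        if self.min_size_bp >= self.max_size_bp:
            raise ValueError("min_size_bp must be below max_size_bp")
        for name in ("segdup_max_fraction", "artifact_max_fraction",
                     "control_reciprocal_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.max_control_carriers < 0:
            raise ValueError("max_control_carriers must be non-negative")


@dataclass(frozen=True)
class FilterMetrics:
    size_bp: int
    control_carriers: int
    segdup_fraction: float
    artifact_fraction: float


@dataclass(frozen=True)
class FilterOutcome:
    call: CnvCall
    passed: bool
    failed_rules: tuple
    metrics: FilterMetrics

    @property
    def first_failed_rule(self) -> Optional[str]:
        return self.failed_rules[0] if self.failed_rules else None


def apply_qc(
    call: CnvCall,
    config: FilterConfig,
    segdups: IntervalTrack,
    artifacts: IntervalTrack,
    controls: ControlCnvSet,
) -> FilterOutcome:
    """Evaluate every QC rule on one call; passed iff no rule fails."""
    size = call.size
    carriers = control_carrier_count(
        call,
        controls,
        reciprocal_overlap=config.control_reciprocal_overlap,
        match_dosage=config.control_match_dosage,
    )
    segdup_frac = covered_fraction(call, segdups)
    artifact_frac = covered_fraction(call, artifacts)
    failed = []
    if call.chrom not in AUTOSOMES:
        failed.append(RULE_AUTOSOME)
    if not (config.min_size_bp <= size <= config.max_size_bp):
        failed.append(RULE_SIZE)
    if carriers > config.max_control_carriers:
        failed.append(RULE_CONTROL)
    if segdup_frac >= config.segdup_max_fraction:
        failed.append(RULE_SEGDUP)
    if artifact_frac >= config.artifact_max_fraction:
        failed.append(RULE_ARTIFACT)
    return FilterOutcome(
        call=call,
        passed=not failed,
        failed_rules=tuple(failed),
        metrics=FilterMetrics(
            size_bp=size,
            control_carriers=carriers,
            segdup_fraction=segdup_frac,
            artifact_fraction=artifact_frac,
        ),
    )


def apply_qc_batch(
    calls: Iterable[CnvCall],
    config: FilterConfig,
    segdups: IntervalTrack,
    artifacts: IntervalTrack,
    controls: ControlCnvSet,
) -> list[FilterOutcome]:
    return [apply_qc(c, config, segdups, artifacts, controls) for c in calls]


def largest_autosomal_cnv(calls: Sequence[CnvCall]) -> Optional[int]:
    """Largest size among one subject's QC-passing calls; None when empty."""
    calls = list(calls)
    if not calls:
        return None
    subjects = {c.subject_id for c in calls}
    if len(subjects) > 1:
        raise ValueError(f"calls span multiple subjects: {sorted(subjects)}")
    return max(c.size for c in calls)


def largest_per_subject(outcomes: Iterable[FilterOutcome]) -> dict[str, int]:
    """subject_id -> largest passing CNV size; carriers only."""
    best: dict[str, int] = {}
    for o in outcomes:
        if not o.passed:
            continue
        sid = o.call.subject_id
        if o.metrics.size_bp > best.get(sid, 0):
            best[sid] = o.metrics.size_bp
    return best
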