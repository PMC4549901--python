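"""File formats and report formatting.

Tab-separated throughout; genomic intervals are BED-like (0-based,
half-open). Cohort tables have the header ``subject_id sex indication
family_history`` (family_history optional). Keyword maps load from TSV
(columns ``keyword category ohi_subfeature``) or YAML. Reported numbers
follow clinical-report conventions: odds ratios to two decimals, sex ratios
as "1.6:1", small p values as "2.9 × 10^-6".
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .cnv_filter import CnvCall
from .keywords import KeywordEntry, KeywordMap
from .stats import GenomicDisorderRegion

COHORT_COLUMNS = ("subject_id", "sex", "indication")


def load_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort phenotype table.

    Requires columns subject_id, sex, indication (family_history optional,
    filled with empty strings when absent). Invalid sex codes raise with the
    offending row numbers (1-based, excluding the header).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    if "family_history" not in df.columns:
        df["family_history"] = ""
    bad = df.index[~df["sex"].isin(["M", "F"])]
    if len(bad):
        rows = ", ".join(str(i + 1) for i in bad[:10])
        raise ValueError(
            f"{path}: invalid sex code (must be M or F) in row(s): {rows}"
        )
    return df


def load_keyword_map(path: str | Path) -> KeywordMap:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        entries = [
            KeywordEntry(
                d["keyword"], d["category"], d.get("ohi_subfeature") or None
            )
            for d in data
        ]
        return KeywordMap(entries)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("keyword", "category"):
        if col not in df.columns:
            raise ValueError(f"{path}: keyword map needs column {col!r}")
    entries = []
    for _, row in df.iterrows():
        sub = row.get("ohi_subfeature", "") or None
        entries.append(KeywordEntry(row["keyword"], row["category"], sub))
    return KeywordMap(entries)


def write_keyword_map(kmap: KeywordMap, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "keyword": e.keyword,
                "category": e.category,
                "ohi_subfeature": e.ohi_subfeature or "",
            }
            for e in kmap.entries
        ]
    ).to_csv(path, sep="\t", index=False)


def load_cnv_calls(path: str | Path) -> list[CnvCall]:
    """BED-like calls: chrom, start, end, subject_id, dosage[, origin]."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["chrom", "start", "end", "subject_id", "dosage"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing CNV column(s): {missing}")
    calls = []
    for _, row in df.iterrows():
        origin = row.get("origin", "") or None
        calls.append(
            CnvCall(
                subject_id=row["subject_id"],
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                dosage=row["dosage"],
                origin=origin,
            )
        )
    return calls


def write_cnv_calls(calls, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "subject_id": c.subject_id,
                "dosage": c.dosage,
                "origin": c.origin or "",
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def load_track_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Plain BED (chrom, start, end), no header required but tolerated."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if parts[0] == "chrom":  # header line
                continue
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    return rows


def write_track(intervals, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def load_regions(path: str | Path) -> list[GenomicDisorderRegion]:
    """BED+ region list: chrom, start, end, name, dosage, class."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["chrom", "start", "end", "name", "dosage", "class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing region column(s): {missing}")
    return [
        GenomicDisorderRegion(
            name=row["name"],
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            dosage=row["dosage"],
            region_class=row["class"],
        )
        for _, row in df.iterrows()
    ]


def write_regions(regions, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "name": r.name,
                "dosage": r.dosage,
                "class": r.region_class,
            }
            for r in regions
        ]
    ).to_csv(path, sep="\t", index=False)


def format_or(value: float) -> str:
    return f"{value:.2f}"


def format_ratio(ratio: Optional[float]) -> str:
    return "undefined" if ratio is None else f"{round(ratio, 1):.1f}:1"


def format_p(p: float) -> str:
    """Two significant digits; scientific as 'm.m × 10^-e' below 0.001."""
    if p == 0:
        return "0"
    if p >= 0.001:
        return f"{p:.2g}"
    exp = math.floor(math.log10(p))
    mant = p / 10**exp
    if round(mant, 1) >= 10:  # e.g. 9.96e-4 -> 1.0e-3
        mant /= 10
        exp += 1
    return f"{mant:.1f} × 10^{exp}"


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
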