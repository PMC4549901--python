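"""Phenotype keyword binning.

Clinical testing cohorts come with free-text diagnostic indications written
by referring physicians ("autism; seizures", "PDD and mental retardation").
This module harmonizes those strings into seven broad phenotype categories
modelled on the IDEA special-education disability taxonomy:

* ``autism``
* ``ID/DD`` (intellectual disability / developmental delay)
* ``OHI`` (other health impairments, carrying a seven-way subfeature
  vocabulary: epilepsy, cardiac, growth, dysmorphic, attention deficit,
  CNS malformation, other congenital malformation)
* ``psychiatric``
* ``behavioral``
* ``speech_language``
* ``specific_learning``

Matching is dictionary based (no NLP): case-insensitive, longest phrase
first, on whole word tokens.  Hyphenated compounds are single tokens, so
"adhd" never matches inside "adhd-like".  Every individual is then assigned
a cohort label (``autism_alone`` / ``iddd_alone`` / ``both`` / ``neither``);
individuals labelled ``both`` are members of *both* analysis cohorts
downstream, while ``neither`` individuals are retained only in logs.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

AUTISM = "autism"
IDDD = "ID/DD"
OHI = "OHI"
PSYCHIATRIC = "psychiatric"
BEHAVIORAL = "behavioral"
SPEECH_LANGUAGE = "speech_language"
SPECIFIC_LEARNING = "specific_learning"

CATEGORIES = frozenset(
    {AUTISM, IDDD, OHI, PSYCHIATRIC, BEHAVIORAL, SPEECH_LANGUAGE, SPECIFIC_LEARNING}
)
PRIMARY_CATEGORIES = frozenset({AUTISM, IDDD})

OHI_SUBFEATURES = frozenset(
    {
        "epilepsy",
        "cardiac",
        "growth",
        "dysmorphic",
        "attention_deficit",
        "cns_malformation",
        "other_congenital",
    }
)

SEXES = ("M", "F")

# word tokens; internal hyphens keep compounds like "adhd-like" atomic
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


def _tokens(text: str) -> tuple[str, ...]:
    return tuple(_TOKEN_RE.findall(text.lower()))


class UnknownKeywordError(KeyError):
    """A keyword reached the mapper that the keyword map does not know."""

    def __init__(self, keyword: str):
        super().__init__(keyword)
        self.keyword = keyword

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"keyword not present in keyword map: {self.keyword!r}"


class PhraseMatcher:
    """Longest-phrase-first whole-token matcher over a keyword vocabulary.

    Tokens consumed by a match are not re-used, so a map holding both
    "seizure" and "seizure disorder" matches only the longer phrase in
    "seizure disorder".
    """

    def __init__(self, keywords: Iterable[str]):
        self._by_first: dict[str, list[tuple[tuple[str, ...], str]]] = {}
        for kw in keywords:
            toks = _tokens(kw)
            if not toks:
                raise ValueError(f"keyword has no matchable tokens: {kw!r}")
            self._by_first.setdefault(toks[0], []).append((toks, kw))
        for cands in self._by_first.values():
            cands.sort(key=lambda it: len(it[0]), reverse=True)

    def find(self, text: str) -> list[str]:
        """Return map keywords found in *text*, in order, duplicates collapsed."""
        toks = _tokens(text)
        out: list[str] = []
        seen: set[str] = set()
        i = 0
        n = len(toks)
        while i < n:
            hit_len = 0
            hit_kw = None
            for cand, kw in self._by_first.get(toks[i], ()):
                m = len(cand)
                if i + m <= n and tuple(toks[i : i + m]) == cand:
                    hit_len, hit_kw = m, kw
                    break  # candidates sorted longest first
            if hit_kw is not None:
                if hit_kw not in seen:
                    seen.add(hit_kw)
                    out.append(hit_kw)
                i += hit_len
            else:
                i += 1
        return out


@dataclass(frozen=True)
class KeywordEntry:
    keyword: str
    category: str
    ohi_subfeature: Optional[str] = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for keyword {self.keyword!r}"
            )
        if self.ohi_subfeature is not None:
            if self.category != OHI:
                raise ValueError(
                    f"keyword {self.keyword!r}: ohi_subfeature set but category is "
                    f"{self.category!r}, not {OHI!r}"
                )
            if self.ohi_subfeature not in OHI_SUBFEATURES:
                raise ValueError(
                    f"keyword {self.keyword!r}: unknown OHI subfeature "
                    f"{self.ohi_subfeature!r}"
                )


class KeywordMap:
    """Non-redundant keyword -> category (+ optional OHI subfeature) dictionary."""

    def __init__(self, entries: Iterable[KeywordEntry]):
        self.entries: list[KeywordEntry] = list(entries)
        if not self.entries:
            raise ValueError("keyword map is empty")
        self._by_tokens: dict[tuple[str, ...], KeywordEntry] = {}
        for e in self.entries:
            key = _tokens(e.keyword)
            if not key:
                raise ValueError(f"keyword has no matchable tokens: {e.keyword!r}")
            if key in self._by_tokens:
                prev = self._by_tokens[key]
                raise ValueError(
                    f"redundant keyword {e.keyword!r}: already mapped to "
                    f"{prev.category!r} (synonym collision)"
                )
            self._by_tokens[key] = e
        self.matcher = PhraseMatcher(e.keyword for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, keyword: str) -> KeywordEntry:
        entry = self._by_tokens.get(_tokens(keyword))
        if entry is None:
            raise UnknownKeywordError(keyword)
        return entry

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str] | tuple[str, str, Optional[str]]]
    ) -> "KeywordMap":
        entries = []
        for p in pairs:
            kw, cat = p[0], p[1]
            sub = p[2] if len(p) > 2 else None
            entries.append(KeywordEntry(kw, cat, sub))
        return cls(entries)


# Default dictionary. The curated clinical keyword list is configuration:
# supply the real table via `KeywordMap` / `ndd bin --keywords` when
# available.  This built-in stand-in covers all seven categories and all
# seven OHI subfeatures with common clinical phrasings.
_DEFAULT_PAIRS: list[tuple[str, str, Optional[str]]] = [
    ("autism", AUTISM, None),
    ("autistic", AUTISM, None),
    ("autism spectrum disorder", AUTISM, None),
    ("pdd", AUTISM, None),
    ("pervasive developmental disorder", AUTISM, None),
    ("asperger", AUTISM, None),
    ("mental retardation", IDDD, None),
    ("intellectual disability", IDDD, None),
    ("developmental delay", IDDD, None),
    ("global developmental delay", IDDD, None),
    ("cognitive deficit", IDDD, None),
    ("psychomotor retardation", IDDD, None),
    ("epilepsy", OHI, "epilepsy"),
    ("seizures", OHI, "epilepsy"),
    ("seizure disorder", OHI, "epilepsy"),
    ("infantile spasms", OHI, "epilepsy"),
    ("cardiac defect", OHI, "cardiac"),
    ("congenital heart disease", OHI, "cardiac"),
    ("heart murmur", OHI, "cardiac"),
    ("cardiac", OHI, "cardiac"),
    ("short stature", OHI, "growth"),
    ("growth retardation", OHI, "growth"),
    ("failure to thrive", OHI, "growth"),
    ("macrocephaly", OHI, "growth"),
    ("microcephaly", OHI, "growth"),
    ("dysmorphic features", OHI, "dysmorphic"),
    ("dysmorphic", OHI, "dysmorphic"),
    ("facial anomalies", OHI, "dysmorphic"),
    ("adhd", OHI, "attention_deficit"),
    ("attention deficit", OHI, "attention_deficit"),
    ("hyperactivity", OHI, "attention_deficit"),
    ("hydrocephalus", OHI, "cns_malformation"),
    ("agenesis of corpus callosum", OHI, "cns_malformation"),
    ("brain malformation", OHI, "cns_malformation"),
    ("cleft palate", OHI, "other_congenital"),
    ("renal anomaly", OHI, "other_congenital"),
    ("genitourinary abnormality", OHI, "other_congenital"),
    ("skeletal anomalies", OHI, "other_congenital"),
    ("schizophrenia", PSYCHIATRIC, None),
    ("bipolar disorder", PSYCHIATRIC, None),
    ("depression", PSYCHIATRIC, None),
    ("anxiety", PSYCHIATRIC, None),
    ("psychosis", PSYCHIATRIC, None),
    ("behavior problems", BEHAVIORAL, None),
    ("aggression", BEHAVIORAL, None),
    ("self-injurious behavior", BEHAVIORAL, None),
    ("tantrums", BEHAVIORAL, None),
    ("speech delay", SPEECH_LANGUAGE, None),
    ("language delay", SPEECH_LANGUAGE, None),
    ("nonverbal", SPEECH_LANGUAGE, None),
    ("articulation disorder", SPEECH_LANGUAGE, None),
    ("learning disability", SPECIFIC_LEARNING, None),
    ("dyslexia", SPECIFIC_LEARNING, None),
    ("learning disorder", SPECIFIC_LEARNING, None),
]


def default_keyword_map() -> KeywordMap:
    """Built-in keyword map (a documented stand-in for a curated clinical list)."""
    return KeywordMap.from_pairs(_DEFAULT_PAIRS)


@dataclass(frozen=True)
class CategoryProfile:
    """Binned phenotype profile for one individual."""

    categories: frozenset
    ohi_subfeatures: frozenset
    multiple_features: bool
    multiple_ohi: bool
    matched_keywords: tuple

    @property
    def comorbid_features(self) -> frozenset:
        """Distinct comorbid items beyond a primary autism/ID-DD diagnosis.

        Non-primary categories count once each; OHI is expanded into its
        recorded subfeatures (or counts once itself if none were recorded).
        """
        items = set(self.categories) - set(PRIMARY_CATEGORIES) - {OHI}
        if OHI in self.categories:
            items |= set(self.ohi_subfeatures) or {OHI}
        return frozenset(items)

    @property
    def has_comorbidity(self) -> bool:
        return bool(self.comorbid_features)


class CohortLabel(enum.Enum):
    AUTISM_ALONE = "autism_alone"
    IDDD_ALONE = "iddd_alone"
    BOTH = "both"
    NEITHER = "neither"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class Individual:
    subject_id: str
    sex: str
    indication_text: str
    profile: CategoryProfile
    cohort: CohortLabel
    family_history_text: Optional[str] = None
    fh_categories: frozenset = frozenset()

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(
                f"subject {self.subject_id!r}: sex must be one of {SEXES}, "
                f"got {self.sex!r}"
            )


def tokenize_indication(text: str, kmap: KeywordMap) -> list[str]:
    """Return every map keyword found in *text* (order of appearance, deduped)."""
    if not text:
        return []
    return kmap.matcher.find(text)


def map_to_profile(keywords: Sequence[str], kmap: KeywordMap) -> CategoryProfile:
    """Union the categories of *keywords* into a :class:`CategoryProfile`.

    Raises :class:`UnknownKeywordError` naming the first keyword missing
    from the map (a stale map / tokenizer mismatch signal).
    """
    categories: set[str] = set()
    subfeatures: set[str] = set()
    for kw in keywords:
        entry = kmap.lookup(kw)
        categories.add(entry.category)
        if entry.ohi_subfeature is not None:
            subfeatures.add(entry.ohi_subfeature)
    profile = CategoryProfile(
        categories=frozenset(categories),
        ohi_subfeatures=frozenset(subfeatures),
        multiple_features=False,
        multiple_ohi=len(subfeatures) >= 2,
        matched_keywords=tuple(keywords),
    )
    # multiple features = >=2 distinct comorbid items beyond the primary dx
    return CategoryProfile(
        categories=profile.categories,
        ohi_subfeatures=profile.ohi_subfeatures,
        multiple_features=len(profile.comorbid_features) >= 2,
        multiple_ohi=profile.multiple_ohi,
        matched_keywords=profile.matched_keywords,
    )


def bin_indication(text: str, kmap: KeywordMap) -> CategoryProfile:
    """Tokenize then map: the one-call binning path used by the pipeline."""
    return map_to_profile(tokenize_indication(text, kmap), kmap)


def assign_cohort(profile: CategoryProfile) -> CohortLabel:
    has_autism = AUTISM in profile.categories
    has_iddd = IDDD in profile.categories
    if has_autism and has_iddd:
        return CohortLabel.BOTH
    if has_autism:
        return CohortLabel.AUTISM_ALONE
    if has_iddd:
        return CohortLabel.IDDD_ALONE
    return CohortLabel.NEITHER


def bin_individual(
    subject_id: str,
    sex: str,
    indication_text: str,
    kmap: KeywordMap,
    family_history_text: Optional[str] = None,
) -> Individual:
    profile = bin_indication(indication_text, kmap)
    return Individual(
        subject_id=subject_id,
        sex=sex,
        indication_text=indication_text,
        profile=profile,
        cohort=assign_cohort(profile),
        family_history_text=family_history_text,
    )


def in_cohort(individual: Individual, cohort: str) -> bool:
    """Membership test for an analysis cohort ('autism', 'ID/DD' or 'union').

    Individuals labelled ``both`` belong to both analysis cohorts; ``union``
    is everyone with a primary diagnosis.
    """
    if cohort == AUTISM:
        return individual.cohort in (CohortLabel.AUTISM_ALONE, CohortLabel.BOTH)
    if cohort == IDDD:
        return individual.cohort in (CohortLabel.IDDD_ALONE, CohortLabel.BOTH)
    if cohort == "union":
        return individual.cohort is not CohortLabel.NEITHER
    raise ValueError(
        f"cohort must be {AUTISM!r}, {IDDD!r} or 'union', got {cohort!r}"
    )


def cohort_counts(individuals: Iterable[Individual]) -> pd.DataFrame:
    """Counts by cohort label and sex (rows: labels; columns F, M, total)."""
    rows = {lab.value: {"F": 0, "M": 0} for lab in CohortLabel}
    for ind in individuals:
        rows[ind.cohort.value][ind.sex] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").loc[
        [lab.value for lab in CohortLabel]
    ]
    df["total"] = df["F"] + df["M"]
    return df


def cohort_sizes(autism_alone: int, iddd_alone: int, both: int) -> dict[str, int]:
    """Additive cohort bookkeeping from disjoint subgroup counts."""
    return {
        "autism": autism_alone + both,
        "ID/DD": iddd_alone + both,
        "union": autism_alone + iddd_alone + both,
    }


def cohort_sizes_from_individuals(
    individuals: Iterable[Individual],
) -> dict[str, int]:
    counts = cohort_counts(individuals)["total"]
    return cohort_sizes(
        int(counts[CohortLabel.AUTISM_ALONE.value]),
        int(counts[CohortLabel.IDDD_ALONE.value]),
        int(counts[CohortLabel.BOTH.value]),
    )
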