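# Methods

This note documents the statistical procedures, the synthetic-data model,
numerical choices, and the places where the design was genuinely open.

## Phenotype harmonization

Free-text diagnostic indications are matched against a non-redundant
keyword dictionary by case-insensitive, longest-phrase-first matching on
whole word tokens. Text and keywords are tokenized identically
(`[a-z0-9]+` with internal hyphens kept, so `adhd` does not match inside
`adhd-like`); tokens consumed by a match are not reused, so a dictionary
containing both `seizure disorder` and `seizures` matches only the longer
phrase when both could apply. Matching is purely lexical — no ontology
mapping, stemming or spelling correction — which keeps the step auditable
and exactly reproducible.

Each keyword maps to one of seven categories (autism, ID/DD, OHI,
psychiatric, behavioral, speech/language, specific learning); OHI keywords
additionally carry one of seven subfeatures (epilepsy, cardiac, growth,
dysmorphic, attention deficit, CNS malformation, other congenital). A
keyword mapping to two categories is rejected at map load. The built-in
~55-keyword dictionary is a documented stand-in covering every category and
subfeature; a curated clinical list can be supplied as TSV/YAML and is then
the source of truth.

**Comorbidity and multiplicity.** A comorbid feature is any non-primary
item: a non-primary category counts once, and OHI is expanded into its
distinct subfeatures. `multiple_features` means ≥2 distinct comorbid items
beyond the primary autism/ID-DD diagnosis, and `multiple_ohi` means ≥2
distinct OHI subfeatures — the minimal reading of "multiple". Whether the
non-OHI comorbid categories should also count toward `multiple_ohi` is
ambiguous; we restrict it to OHI subfeatures.

**Cohorts.** autism-alone / ID/DD-alone / both / neither; individuals with
both diagnoses are analysed in both cohorts, so cohort sizes satisfy
`autism = autism_alone + both`, `ID/DD = iddd_alone + both`,
`union = autism_alone + iddd_alone + both`. Individuals matching no
keyword (or only comorbidity keywords) are labelled `neither` and excluded
from analysis cohorts but retained in logs, mirroring the referral funnel
of clinical testing populations.

## Rare-CNV quality control

Coordinates are 0-based half-open (BED) everywhere. Rules, evaluated in a
fixed order on every call with no short-circuiting (so the per-call metric
set is always complete, and relaxing any threshold can only grow the pass
set):

1. **autosome** — only chr1..chr22 pass; sex-chromosome calls are excluded
   with their own named rule (control data are unreliable there), never
   silently dropped;
2. **size** — 50 kbp ≤ size ≤ 30 Mbp, boundaries inclusive;
3. **control_frequency** — fail when more than `max_control_carriers`
   (default 8, of 8,329) distinct control subjects carry the call. A
   control carries a call when it has a same-dosage call with ≥50 %
   reciprocal overlap (the field's common identity convention; the
   threshold and dosage matching are configurable). Note 8/8,329 = 0.096 %,
   so the integer ">8" rule and a "<0.1 %" frequency rule differ only in
   wording at this cohort size; we implement the explicit integer rule.
4. **segdup** — fail when the merged segmental-duplication track covers
   ≥50 % of the call;
5. **artifact** — fail when the artifact blacklist covers ≥10 % of the
   call, regardless of dosage (the blacklist is positional; a type-matched
   variant is available).

Overlap fractions are call-denominated (fraction of the *call* covered by
the track union), the standard orientation for masking calls against a
fixed annotation; the boundary is treated as "pass iff fraction <
threshold". Calls caused by reference CNVs or embedded in complex
segmental duplications are not modelled separately; both are subsumed by
the segdup/artifact coverage rules. Interval tracks are stored merged
(sorted, disjoint, non-adjacent per chromosome) as numpy arrays; coverage
queries are two binary searches plus a clipped sum, and are validated
against a per-base brute-force oracle in the tests.

## Contingency statistics

All sex contrasts are 2×2 tables with rows {female, male} and columns
{present, absent}. The odds ratio uses the Woolf log interval with
z = Φ⁻¹(0.975) ≈ 1.959964; any zero cell triggers Haldane–Anscombe +0.5 on
all four cells, flagged in the result. Fisher's exact test is computed by
hypergeometric enumeration over the a-cell support using a shared
log-factorial table; the two-tailed value follows the method-of-small-p
convention, summing all tables whose point probability is at most
(1 + 10⁻⁷)× the observed one (the same relative-epsilon rule R and scipy
use). One-tailed directions are declared in configuration before data are
read (female > male for comorbidity presence and burden; male > female for
the family-history rows) and both tails are always reported. Degenerate
margins yield p = 1 with a flag. Bonferroni correction is min(1, p·m) with
the family size m an explicit argument, because which comparisons form a
family is an analysis decision, not a property of a p-value list.

Sex ratios are reported male:female at one decimal ("1.6:1"), keeping full
precision internally, and are only reported when the total sample is ≥10.
Per-genomic-disorder profiles assign a passing call to a region when
dosages match and the call covers ≥50 % of the region (configurable);
regions below the minimum n are suppressed with a reason rather than
omitted.

## CNV burden

A subject's burden is the size of their largest QC-passing autosomal CNV.
The survivor function S(t) — the fraction of subjects whose largest CNV is
at least t — is computed over the rare-CNV *carrier* cohort (subjects with
≥1 passing call); including non-carriers at size 0 is available as a
sensitivity option. Group contrasts build the 2×2 (group × exceeds-t)
table at closed thresholds (≥1, ≥1.5, ≥2 Mbp by default) and use the same
Fisher machinery, with Bonferroni m equal to the number of thresholds on
request. The default plotting/reporting grid is 100 log-spaced points from
50 kbp to 10 Mbp.

The replication-style comparison on total de novo base pairs per subject
uses the Mann–Whitney rank-sum test with midrank tie handling: exact
enumeration when the combined sample size is ≤40 and tie-free, otherwise
the normal approximation with continuity correction (the switch point is
configurable). Constant pooled data return p = 1 with a degeneracy flag.

## Family history

Family-history text is matched with the same phrase matcher against a
12-category vocabulary: {ID/DD, dysmorphic features, other congenital
malformations, growth abnormalities, cardiac malformations} form the
early-manifesting ID/DD–MCA group, and {epilepsy, other CNS malformations,
autism, psychiatric disorders, attention deficit disorders, speech and
language impairments, specific learning disabilities} the
neuropsychiatric/behavioral group (5 + 7, a partition). Proband
indications are projected onto the same 12-category space by expanding OHI
into its subfeatures; the 7-category scheme's *behavioral* bin has no
separate slot in the 12-category vocabulary and is folded into psychiatric
disorders.

The per-sex matrix cell (f, i) is the number of probands with indication i,
any positive family history, and family history f, divided by the number
with indication i and any positive family history. Individuals without any
positive family history are excluded before the matrix is built. A
multi-category family history contributes to several numerators but once
per column denominator, so column numerator sums may exceed the
denominator while each cell stays in [0, 1].

Row-wise male-vs-female comparisons use a paired t-test across indication
columns (the two matrices share the column dimension, and pairing by
column is the natural reading of comparing the male and female matrices);
only columns with nonzero denominators in both matrices enter, and an
unpaired variant can be run on the extracted rows. Degenerate cases:
all-zero differences give p = 0.5 (zero t under a symmetric null);
constant nonzero differences (zero variance, direction unambiguous) give
p = 0 in the favoured direction with a degeneracy flag rather than an
error. Broad-group comparisons pool the cell frequencies whose row *and*
column lie in the group and apply the rank-sum test. An optional exclusion
list can mask frequently co-occurring indication/family-history pairs; the
default masks nothing.

## Synthetic cohort model

The generator emulates the statistical structure of a clinical referral
cohort; all randomness flows through one `numpy.random.default_rng(seed)`
(integer-state, platform-stable), so identical config + seed gives
byte-identical outputs.

* **Strata.** Sex is Bernoulli(male_fraction); default 4,588/5,872 ≈ 0.78,
  an autism-cohort-flavored male share. Diagnostic strata
  (autism-alone / ID/DD-alone / both / neither) default to the funnel
  proportions of a 54,370-referral population in which 32,155 carry a
  primary diagnosis (3,602 / 26,283 / 2,270, remainder neither).
* **Comorbidity.** Boys are comorbid with probability 0.50; girls' odds
  are multiplied by `comorbidity_or_female` (default 1.34), so the
  female:male odds ratio is a known constant at every cohort level.
  Comorbid individuals draw one (or, with probability 0.3, two) comorbid
  items from category weights; OHI items draw a subfeature from per-sex
  weights with a mild planted female excess of epilepsy. Indications are
  rendered as keyword strings drawn from the default dictionary, so
  keyword binning round-trips the generating categories with 100 %
  fidelity (a tested property). Half the `neither` stratum gets
  comorbidity-only text, the other half unmatched filler, exercising the
  exclusion path.
* **CNV sizes.** Carriers (rate 8,373/32,155 ≈ 0.26) receive
  K = 1 + Poisson(λ) calls (mean 2.0) with lognormal sizes: log-mean
  ln(200 kbp) for boys, +0.30 for girls (the planted female burden
  excess), log-sd 1.0. Lognormal was chosen because burden analyses are
  about heavy right tails and it makes the tails closed-form:
  P(call ≥ t) = 1 − Φ((ln t − μ)/σ) and
  P(largest ≥ t) = 1 − F(t)·exp(λ(F(t) − 1)). Positions are uniform on a
  toy genome of 22 autosomes of 200 Mbp — no attempt at realistic
  coordinates beyond keeping planted features apart.
* **Genomic-disorder regions.** Each region spec plants carriers at a
  female rate times a male:female *rate ratio* (rate, not odds, so that
  with equal sexes the expected carrier sex ratio equals the ratio
  exactly); planted calls span the region exactly and inherit its dosage.
  Defaults include regions with planted ratios from 0.3:1 to 8:1 across
  syndromic and variable-expressivity classes.
* **Family history.** A sparse rate (386/32,155) of diagnosed individuals
  gets one or two family-history categories from per-sex weights, rendered
  as text via the family-history dictionary. The direct-to-category
  generator used for calibration experiments gives each synthetic proband
  exactly one indication category so that matrix columns are independent —
  with shared multi-indication individuals, the paired t across columns
  would not be nominally calibrated.
* **Planted filter scenario.** `simulate_interval_tracks` constructs calls
  whose QC outcome is known by construction: clean passes, size failures
  on both sides with inclusive boundaries, a sex-chromosome exclusion,
  control-frequency failure at exactly 9 carriers and a pass at exactly 8,
  segdup coverage 0.6, artifact coverage 0.2, and a combined failure,
  plus decoy track intervals and control calls. The filter is
  deterministic arithmetic, so these are checked exactly.

**What the generator does not emulate.** Real indication text (misspelled,
abbreviated, multilingual), correlated comorbidity structure, realistic
CNV positional clustering, ascertainment bias, age effects, and
between-site heterogeneity. Passing tests on synthetic data therefore
demonstrate correctness of the *computational pipeline* under the stated
generative model, not clinical validity of any estimate on real cohorts.

## Problem sizes and numerical choices

The test suite validates the Fisher implementation against exhaustive
hypergeometric enumeration over all ~6.4 × 10⁵ tables with N ≤ 60, checks
Woolf-CI coverage of the generating odds ratio over 200 seeded cohorts of
n = 30,000, checks survivor tails against the closed forms at ~5,000
carriers per sex (3 Monte-Carlo SEs), and calibrates the family-history
row test's type-I error over 1,000 replicates of a 386-proband cohort —
sizes chosen to make the Monte-Carlo bands tight enough to detect real
defects while the whole suite runs in a few minutes on one CPU. Survivor
curves and coverage fractions are exact integer ratios; p-value
enumeration uses log-factorials with `math.fsum` tail sums (absolute
agreement with rational-arithmetic enumeration to better than 10⁻¹²).

## Known limitations

* The built-in keyword dictionaries are stand-ins; analyses of real data
  should supply the curated lists.
* The "same CNV in controls" identity (≥50 % reciprocal overlap, dosage
  matched) is a convention; carrier counts near the >8 boundary can be
  sensitive to it.
* The Bonferroni family, the one-tailed directions, and the survivor
  denominator (carriers vs full cohort) are configuration, and results
  should always be reported together with those choices.
* The paired t-test on matrix rows treats column frequencies as
  approximately normal; with very small column denominators its
  calibration degrades (the rank-sum broad-group comparison is the more
  robust contrast there).
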