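# Methods

## Data model

A plate run is a 96-well layout: 76 study wells, two study-pool QC (SPQC)
wells bracketing the injection sequence, three NIST reference-plasma
wells, one reference-serum well, three kit-QC levels in triplicate, a
calibrator series, and blank/zero wells. Concentrations are µM. Every
matrix cell carries a status flag: `valid`, `below_LOD`, `below_LLOQ`,
`semi_quant` or (after Level 4) `imputed`. The two kinds of missingness
are kept distinct on disk — an empty cell is missing *without*
explanation, the `<LOD` sentinel is missing *with* explanation — because
the %<LOD filter must count only the latter. `<LLOQ` cells may carry a
numeric payload (`<LLOQ|0.12`); they are treated as numeric-valid with
the flag preserved, since values between LOD and LLOQ are measured but
below the lowest calibrator.

Sample identity is plate-scoped; subjects become the analysis unit only
at Level 5, where blinded duplicate pairs (a second aliquot of the same
serum draw inserted under a different id) collapse to one row per
subject.

## Plate technical validation

A plate is accepted when: each calibrator concentration is within ±30% of
nominal and ≥ 75% of an analyte's calibrators are valid; each kit-QC
injection is within ±45% of nominal with at least two-thirds valid
overall and ≥ 50% valid at every QC level ("67%" is read as 2/3 — with
the usual 3×3 QC layout, six of nine injections must pass, and
6/9 < 0.67 as a bare float); blank signals stay below kit-defined
ceilings and internal-standard intensities inside kit-defined windows
(both are configuration, since the manufacturer does not publish them).
Tolerance comparisons are inclusive with a 1e-9 relative guard so that a
measurement at exactly the printed tolerance is never rejected by
floating-point round-off. The plate-specific LOD is 3 × the mean
zero-sample level per analyte; a zero mean gives LOD 0 and the analyte is
simply never censored.

## Curation statistics

**SPQC scaling (Level 2).** For analyte *a* on plate *p* the correction
factor is the analyte's global SPQC average divided by its within-plate
SPQC average. Multiplying a plate's cells by its factor equalizes SPQC
means across plates exactly; with noiseless SPQC wells the factors invert
a planted multiplicative batch effect to machine precision. An undefined
plate mean (zero or all-missing) falls back to factor 1 with a warning.
With the real design — two SPQC wells per plate — the factor estimate
carries the sampling error of a two-injection mean, i.e. a relative s.e.
of `cv/√2` (≈ 3.5% at 5% technical CV); users should not expect
per-analyte factors to be accurate beyond that.

**Duplicate CV (Level 3).** Per pair, `100·s/x̄` with the n = 2 sample
standard deviation; per analyte, the arithmetic mean over usable pairs.
Pairs with a missing member are skipped per analyte; non-positive pair
means are skipped with a warning; an analyte with no usable pair fails
the filter (the pipeline is deliberately stringent). Note the estimator's
small-sample bias: `E[s] = √(2/π)·σ` at n = 2, so a true technical CV of
5% yields a mean estimate near 4.0%. We keep the plain estimator because
it is what duplicate-QC practice reports; the bias is a property of the
published procedure, not of this implementation.

**Duplicate ICC (Level 3).** One-way random-effects ICC(1,1),
`(MSB − MSW)/(MSB + (k−1)·MSW)` with k = 2, allowing negative estimates —
duplicates are exchangeable technical replicates with no rater structure.
At least three complete pairs are required; fewer fails the filter.
Retention requires ICC strictly above 0.65: an analyte at exactly 0.65 is
excluded. With 20 pairs the estimator is noisy (s.d. ≈ 0.2 near zero
reproducibility), which is why the synthetic generator plants its
"low-ICC" defect at zero between-subject variance rather than at a
marginal value.

**%<LOD (Level 3).** 100 × flagged study cells / study cells, per
analyte; QC and reference wells are excluded from both counts because
missingness of controls is not a property of the cohort. Exclusion is
strict: 40.0% is retained, 40.1% is not. Verdicts record the first
failing rule in the fixed order CV → ICC → LOD.

**Imputation and flags (Level 4).** Remaining `<LOD` cells become the
plate-specific LOD/2 of the plate the sample ran on (LOD is defined per
plate, so a global LOD would be wrong), with status `imputed`. Samples
that are non-fasting, lack BMI, or lack a baseline medication record are
flagged but physically retained until Level 5, keeping the Level-4 file
consistent with the staged-artifact convention.

**Level 5.** Fixed order: (1) drop flagged samples, (2) average duplicate
pairs to one row per subject, (3) PCA outlier screen, (4) conditional
log2. Analytes are standardized before PCA because µM scales differ by
orders of magnitude across classes; the smallest K components with
cumulative explained variance strictly above 0.90 are kept, and a subject
is flagged when its Euclidean distance from the K-dimensional score
centroid exceeds mean(d) + 7·sd(d). Two properties of this rule are worth
knowing. First, it is masking-limited: one extreme subject inflates the
s.d. it is tested against, so a single outlier can *never* be flagged in
a cohort of fewer than 51 subjects (the flag condition requires
√(n−1) > 7), and standardization caps an outlier's per-analyte coordinate
near √n however extreme the raw value. Second, it is scale-free in the
component signs, so PCA sign ambiguity cannot change the flags. The log2
decision requires both a significant D'Agostino–Pearson omnibus test
(p < 0.05) and Fisher–Pearson skewness g1 > 2, evaluated on ≥ 20 values;
LOD/2 imputation guarantees positivity.

Everything in Levels 1–5 is deterministic: identical inputs and
configuration give byte-identical level files and audit, and the audit's
per-level counts always satisfy before − removed = after.

## Medication classification

Raw entries are lowercased; dose/unit/route/frequency tokens are
stripped; combination separators (`/`, `+`, `with`, commas) split entries
into multiple tokens. Tokens are matched against a lexicon of brand and
generic names by a pluggable scorer whose contract is: 1.0 on exact
match, symmetric, decreasing in edit distance. The default is normalized
Levenshtein similarity, `1 − d/max(|a|,|b|)`, computed with edlib. Scores
≥ 0.85 auto-accept; scores in [0.5, 0.85) queue for manual review;
review decisions are serialized and re-applied verbatim, and a review
file touching an auto-accepted or unknown query is rejected whole, so a
rerun is bit-identical. Accepted names resolve to ingredients and then to
drug classes; each subject gets one Boolean per class (union semantics
over entries and ingredients). The bundled lexicon is an offline,
hand-curated stand-in of ~120 names / 85 ingredients / 69 classes — a
live terminology service can be plugged in through the same matcher and
lexicon contracts but is deliberately out of scope.

## Synthetic cohorts

The generator emulates the study design it is meant to test: 11 plates ×
76 study wells, 831 study samples of 811 subjects with 20 blinded
duplicate pairs, 182 analytes, two SPQC wells per plate, and clinical
flags of 69 non-fasting + 2 missing-BMI + 1 missing-medication samples
(kept disjoint so the flag arithmetic is exact), 4 thawed samples
excluded at Level 1, and 2 planted outlier subjects. Subject truths are
lognormal per analyte (ln-median uniform on [0, 3] — roughly 1–20 µM —
and ln-s.d. uniform on [0.2, 1.0], spanning tight amino acids to skewed
lipids so that the log2 rule fires for a subset); an observation is truth
× plate effect × (1 + cv·z) truncated at zero, with plate effects
lognormal (ln-s.d. 0.10, the ±10–20% batch spread typical of multi-plate
kits) and technical CV 5%. Planted defects: technical CV 40% (high-CV),
zero between-subject variance (low-ICC), and 60% censoring (high-LOD) —
each at least twice the corresponding filter margin. Detection limits are
set per plate from the target censoring quantile of that plate's study
wells, and the simulated zero wells are written as LOD/3 so that the 3×
zero-level rule reproduces the LOD table exactly. Calibrator/QC/blank/
ISTD data are drawn to satisfy every plate-acceptance rule. Outlier
subjects are shifted by 30 linear-scale s.d. on 10 clean analytes.
Medication text is drawn from the lexicon with seeded transposition typos
(rate 0.15); a typo that would not resolve back to its intended drug —
automatically or through the emitted review file — falls back to the
clean spelling, so the expected class matrix is exact by construction.
All randomness flows from a single integer seed through one
`numpy.random.default_rng`; no hash-ordering or platform state is
involved, and identical configs produce byte-identical files.

What the generator does *not* emulate: chromatographic drift, carryover,
isobaric interference, correlated analyte blocks, non-lognormal biology,
or plate-by-analyte interaction in the batch effect. Passing tests
therefore demonstrate that the pipeline recovers *this* generative
structure exactly, not that real cohorts are free of subtler artifacts.

The packaged reference fixture is regenerated deterministically (fixed
internal seed) at 3 plates × 40 study wells, 40 analytes, 6 duplicate
pairs, 2 defects per type and 1 planted outlier; its size keeps the
cohort above the ~51-subject floor the outlier rule needs.

## Problem sizes used in the test suite

Monte-Carlo checks run at 100 simulated SPQC designs (scaling recovery),
500 replicates of 20 duplicate pairs (CV/ICC parameter recovery), 20
seeded defect-planted cohorts of 120 samples × 40 analytes
(recall/precision), and 200 replicates of 200 × 20 Gaussian cohorts
(outlier specificity); the acceptance script runs the full-size 11-plate
design. The whole suite completes in well under a minute on one CPU.

## Known limitations

* The mean-of-pair-CVs estimator is biased low by √(2/π) at n = 2 (see
  above); consumers comparing against an unbiased CV should apply the c4
  correction themselves.
* Two SPQC injections per plate bound the achievable scaling-factor
  accuracy at ≈ 3.5% relative s.e. per (plate, analyte) at 5% technical
  CV; triplicate SPQC preps would tighten this by √(3/2).
* The 7-s.d. distance rule cannot flag single outliers in cohorts under
  51 subjects and saturates under standardization (coordinates capped
  near √n).
* `<LLOQ` values pass through as numeric with their flag; no separate
  LLOQ imputation is attempted.
* The offline lexicon is intentionally small; coverage, not the matching
  algorithm, limits recall on real free text.
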