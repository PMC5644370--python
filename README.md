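# p180curate

Curation toolkit for targeted-metabolomics plate data of the Biocrates
AbsoluteIDQ-p180 style: per-plate technical validation, pooled-QC
cross-plate scaling, duplicate-based analyte filtering, detection-limit
imputation, pre-analytical sample exclusion, PCA outlier screening and
conditional log2 transformation — together with a free-text medication →
drug-class classification pipeline and a seeded synthetic-cohort generator
with known ground truth.

## Who this is for

Metabolomics cores and analysts who receive per-plate concentration
exports (µM, with `<LOD` / `<LLOQ` status flags), a well-role manifest
(study wells, pooled study QC, kit QCs, calibrators, blank/zero wells,
NIST/reference serum), plate-specific LOD tables and a clinical annotation
table, and need a reproducible, fully audited route from those raw
artifacts to a single curated subject × analyte matrix suitable for
association analyses — plus per-subject Boolean drug-class covariates for
confounder control.

## The pipeline

Data move through staged "levels", each written to disk with an audit
trail:

| Level | Operation |
|---|---|
| 1 | drop samples excluded a priori (e.g. thawed during shipment) |
| 2 | SPQC scaling: each cell × (global SPQC mean / plate SPQC mean) per analyte |
| 3 | analyte filter: duplicate CV < 20%, ICC(1,1) > 0.65 (strict), %<LOD ≤ 40% |
| 4 | impute `<LOD` cells at plate LOD/2; flag non-fasting / missing-BMI / missing-meds samples |
| 5 | drop flagged samples, average blinded duplicate pairs, remove PCA distance outliers (> mean + 7 s.d. in the component space explaining > 90% variance), log2-transform analytes with D'Agostino p < 0.05 and skewness g1 > 2 |

The statistics underneath: scaling factors `f_{p,a} = x̄_a / x̄_{p,a}`
from the study-pool QC injected twice per plate; duplicate CV per analyte
as the mean over blinded pairs of `100·s/x̄`; ICC(1,1) from the one-way
ANOVA decomposition `(MSB − MSW)/(MSB + MSW)` with k = 2 replicates;
plate-specific LOD = 3 × mean zero-sample level; plate acceptance via
calibrators within ±30% (≥ 75% valid), kit QCs within ±45% (≥ 2/3 valid
overall, ≥ 50% per level) and kit-defined blank/ISTD bounds.

Medication free text ("Aricept 10mg QD", "lisinopril/HCTZ 20-12.5") is
normalized, matched against a bundled offline brand/generic lexicon by
normalized Levenshtein similarity (auto-accept ≥ 0.85, manual review
≥ 0.5), rolled up name → ingredient → class (ATC / NDF-RT / MeSH /
DailyMed-FDA SPL sources), and emitted as a subject × class Boolean
matrix.

## Worked example

```python
import tempfile, p180

workdir = tempfile.mkdtemp()
gt = p180.simulate_cohort(p180.SimulationConfig(seed=1), workdir)   # 11 plates, 182 analytes
paths = p180.cohort_paths(workdir)

matrix, plates = p180.read_level0(paths["plates"], paths["manifest"], paths["lod"])
clinical = p180.read_clinical(paths["clinical"])
lods = p180.read_lod_table(paths["lod"])

config = p180.PipelineConfig(exclusion_list=gt.thawed_samples)
final, audit, levels = p180.run_pipeline(matrix, clinical, lods, config,
                                         outdir=workdir + "/curated")
print(len(matrix.analytes), "->", len(final.analytes), "analytes;",
      int(matrix.study_mask().sum()), "->", final.n_samples, "subjects")
```

prints

```
182 -> 138 analytes; 831 -> 733 subjects
```

i.e. of 182 panel analytes the 44 with planted quality defects (high
technical CV, no between-subject reproducibility, or > 40% censoring) are
removed at Level 3; of the 831 study samples, 4 listed exclusions leave
at Level 1, 72 pre-analytically flagged samples (69 non-fasting, 2 missing
BMI, 1 missing medication record) leave at Level 5, the 20 blinded
duplicate pairs collapse to one row per subject, and 2 planted outlier
subjects are removed by the PCA distance screen. `audit` records every
removal with its reason, and `workdir/curated/` holds the LEVEL1–5 CSVs,
`audit.json`, per-analyte `metrics.csv` and `scaling_factors.csv`.

The same flow is available from a shell:

```sh
p180 simulate --seed 1 --outdir cohort/
p180 run --plates cohort/plates --manifest cohort/manifest.csv \
     --lod cohort/lod.csv --clinical cohort/clinical.csv --outdir curated/
p180 meds --meds cohort/meds.csv --review cohort/med_review.csv --out classes.csv
```

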