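"""Level 1 -> Level 5 curation of a p180 cohort, with a full audit trail.

The staged workflow:

* **Level 1** — drop samples excluded for pre-analytical reasons known a
  priori (e.g. thawed during shipment), from an explicit exclusion list.
* **Level 2** — SPQC cross-plate scaling: every (plate, analyte) cell is
  multiplied by global-SPQC-mean / plate-SPQC-mean.
* **Level 3** — analyte retention filter on the blinded duplicates:
  keep an analyte only if duplicate CV < 20%, ICC > 0.65 (strict) and
  at most 40% of study measurements are below the detection limit.
* **Level 4** — impute remaining <LOD cells at the plate-specific LOD/2;
  flag (but do not yet drop) samples that are non-fasting, lack BMI, or
  lack a baseline medication record.
* **Level 5** — drop the flagged samples, average blinded duplicate pairs
  to one row per subject, remove PCA distance outliers (> mean + 7 sd in
  the component space explaining > 90% of variance), and log2-transform
  analytes that are both non-normal (D'Agostino p < 0.05) and strongly
  right-skewed (g1 > 2).

Everything is deterministic: identical inputs and config give bit-identical
level files and audit.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import qcstats
from .panel import (
    MeasurementMatrix,
    STATUS_BELOW_LOD,
    STATUS_IMPUTED,
    STATUS_VALID,
    write_level,
)


@dataclass
class PipelineConfig:
    cv_max: float = 20.0            # duplicate CV ceiling, percent
    icc_min: float = 0.65           # strict lower bound on duplicate ICC
    lod_pct_max: float = 40.0       # max percent of study cells below LOD
    var_cum: float = 0.90           # PCA cumulative-variance cut for K
    k_sd: float = 7.0               # distance threshold: mean + k_sd * sd
    dagostino_alpha: float = 0.05
    skew_min: float = 2.0
    min_normality_n: int = 20
    exclusion_list: list = field(default_factory=list)  # sample ids, Level 1
    exclusion_reason: str = "pre-analytical exclusion"

    def __post_init__(self):
        for name in ("cv_max", "icc_min", "lod_pct_max", "var_cum", "k_sd",
                     "dagostino_alpha", "skew_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class LevelRecord:
    level: int
    n_samples_before: int
    n_samples_after: int
    n_analytes_before: int
    n_analytes_after: int
    removed_samples: list = field(default_factory=list)   # (sample_id, reason)
    removed_analytes: list = field(default_factory=list)  # (analyte_id, reason)
    notes: dict = field(default_factory=dict)

    def check_conservation(self) -> None:
        if self.n_samples_before - len(self.removed_samples) != self.n_samples_after:
            raise AssertionError(f"level {self.level}: sample counts inconsistent")
        if self.n_analytes_before - len(self.removed_analytes) != self.n_analytes_after:
            raise AssertionError(f"level {self.level}: analyte counts inconsistent")


@dataclass
class CurationAudit:
    """Per-level record of everything removed, imputed or transformed."""

    config: dict = field(default_factory=dict)
    levels: list = field(default_factory=list)
    scaling_factors: list = field(default_factory=list)   # long records
    analyte_metrics: list = field(default_factory=list)
    imputed_count: int = 0
    flagged_samples: dict = field(default_factory=dict)   # reason -> [sample ids]
    outlier_subjects: list = field(default_factory=list)
    transformed_analytes: list = field(default_factory=list)

    def record(self, rec: LevelRecord) -> None:
        rec.check_conservation()
        self.levels.append(rec)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @property
    def removed_analytes(self) -> list:
        return [a for rec in self.levels for a, _ in rec.removed_analytes]

    @property
    def removed_samples(self) -> list:
        return [s for rec in self.levels for s, _ in rec.removed_samples]


# --------------------------------------------------------------------------
# stages

def level1_exclude(matrix: MeasurementMatrix, config: PipelineConfig, audit: CurationAudit):
    """Remove explicitly listed samples (thawed shipments and the like)."""
    removed = []
    present = set(matrix.values.index)
    for sid in config.exclusion_list:
        if sid not in present:
            warnings.warn(f"Level 1 exclusion id {sid!r} not found; ignored")
            continue
        role = matrix.samples.loc[sid, "role"]
        if role != "study":
            raise ValueError(f"refusing to exclude non-study well {sid!r} (role {role})")
        removed.append((sid, config.exclusion_reason))
    out = matrix.drop_samples([s for s, _ in removed])
    audit.record(
        LevelRecord(1, matrix.n_samples, out.n_samples, len(matrix.analytes), len(out.analytes),
                    removed_samples=removed)
    )
    return out


def level2_scale(matrix: MeasurementMatrix, audit: CurationAudit):
    """SPQC-anchored multiplicative batch correction."""
    factors = qcstats.compute_scaling_factors(matrix)
    out = qcstats.apply_scaling(matrix, factors)
    audit.scaling_factors = factors.to_frame().to_dict("records")
    audit.record(
        LevelRecord(2, matrix.n_samples, out.n_samples, len(matrix.analytes), len(out.analytes),
                    notes={"n_factors": len(audit.scaling_factors)})
    )
    return out, factors


def level3_filter(matrix: MeasurementMatrix, config: PipelineConfig, audit: CurationAudit):
    """Drop analytes failing the duplicate-precision / missingness filters."""
    cv = qcstats.duplicate_cv(matrix)
    icc = qcstats.duplicate_icc(matrix)
    pct = qcstats.pct_below_lod(matrix)
    verdicts = qcstats.analyte_verdicts(
        cv, icc, pct, cv_max=config.cv_max, icc_min=config.icc_min, lod_pct_max=config.lod_pct_max
    )
    audit.analyte_metrics = verdicts.reset_index().to_dict("records")
    dropped = verdicts[verdicts["verdict"] != qcstats.VERDICT_RETAIN]
    removed = [(a, row["verdict"]) for a, row in dropped.iterrows()]
    out = matrix.drop_analytes([a for a, _ in removed])
    audit.record(
        LevelRecord(3, matrix.n_samples, out.n_samples, len(matrix.analytes), len(out.analytes),
                    removed_analytes=removed)
    )
    return out, verdicts


def level4_impute_and_flag(
    matrix: MeasurementMatrix,
    clinical: pd.DataFrame,
    lod_tables: dict,
    audit: CurationAudit,
):
    """LOD/2 imputation plus pre-analytical sample flagging.

    Flags are recorded in the audit but flagged rows stay in the Level-4
    matrix; they are physically removed only at Level 5.
    """
    out = matrix.copy()
    vals = out.values.to_numpy()
    stats = out.status.to_numpy()
    n_imputed = 0
    plate_arr = out.samples["plate_id"].to_numpy()
    for i in range(vals.shape[0]):
        row_mask = stats[i] == STATUS_BELOW_LOD
        if not row_mask.any():
            continue
        plate_lods = lod_tables.get(plate_arr[i])
        if plate_lods is None:
            raise ValueError(f"no LOD table for plate {plate_arr[i]!r}")
        for j in np.nonzero(row_mask)[0]:
            analyte = out.values.columns[j]
            if analyte not in plate_lods:
                raise ValueError(f"no LOD for analyte {analyte!r} on plate {plate_arr[i]!r}")
            vals[i, j] = plate_lods[analyte] / 2.0
            stats[i, j] = STATUS_IMPUTED
            n_imputed += 1
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    out.status = pd.DataFrame(stats, index=out.status.index, columns=out.status.columns)

    flags: dict = {"non_fasting": [], "missing_bmi": [], "missing_med_record": []}
    study = out.study_mask()
    for sid in out.values.index[study]:
        subj = out.samples.loc[sid, "subject_id"]
        if subj not in clinical.index:
            raise ValueError(f"study sample {sid!r}: subject {subj!r} absent from clinical table")
        rec = clinical.loc[subj]
        if not bool(rec["fasting"]):
            flags["non_fasting"].append(sid)
        if not np.isfinite(rec["bmi"]):
            flags["missing_bmi"].append(sid)
        if not bool(rec["has_baseline_med_record"]):
            flags["missing_med_record"].append(sid)
    flags = {k: sorted(v) for k, v in flags.items()}
    audit.imputed_count = n_imputed
    audit.flagged_samples = flags
    audit.record(
        LevelRecord(4, matrix.n_samples, out.n_samples, len(matrix.analytes), len(out.analytes),
                    notes={"imputed_cells": n_imputed,
                           "flagged": {k: len(v) for k, v in flags.items()}})
    )
    return out, flags


def level5_finalize(
    matrix: MeasurementMatrix,
    flags: dict,
    config: PipelineConfig,
    audit: CurationAudit,
):
    """Flag removal, duplicate averaging, outlier screening, conditional log2."""
    flagged = sorted({s for ids in flags.values() for s in ids})
    reasons = {s: [] for s in flagged}
    for reason, ids in flags.items():
        for s in ids:
            reasons[s].append(reason)

    study = matrix.rows(matrix.study_mask())
    kept = study.drop_samples(flagged)
    removed_samples = [(s, "+".join(reasons[s])) for s in flagged if s in set(study.values.index)]
    # also count the QC rows that leave the table at this point
    removed_samples += [
        (s, "qc_well") for s in matrix.values.index[~matrix.study_mask()]
    ]

    # duplicate pairs with both members flagged leave no subject row
    for g, sub in study.samples.dropna(subset=["duplicate_group"]).groupby("duplicate_group"):
        if all(s in set(flagged) for s in sub.index):
            warnings.warn(f"duplicate pair {g!r}: both members flagged; subject absent from output")

    if kept.values.isna().any().any():
        raise ValueError("Level 5 requires a complete matrix; run Level 4 imputation first")

    # one row per subject: blinded duplicates are averaged, singletons pass through
    subj = kept.values.groupby(kept.samples["subject_id"]).mean()
    subj = subj.sort_index()

    report = qcstats.pca_outliers(subj, var_cum=config.var_cum, k_sd=config.k_sd)
    final = subj.drop(index=report.flagged)
    audit.outlier_subjects = list(report.flagged)

    transformed = []
    for analyte in final.columns:
        if qcstats.normality_decision(
            final[analyte].to_numpy(),
            alpha=config.dagostino_alpha,
            skew_min=config.skew_min,
            min_n=config.min_normality_n,
        ):
            transformed.append(analyte)
    out_vals = final.copy()
    if transformed:
        out_vals[transformed] = np.log2(out_vals[transformed])
    audit.transformed_analytes = transformed

    samples = pd.DataFrame(
        {
            "subject_id": out_vals.index,
            "plate_id": np.nan,
            "role": "study",
            "duplicate_group": np.nan,
        },
        index=out_vals.index,
    )
    status = pd.DataFrame(STATUS_VALID, index=out_vals.index, columns=out_vals.columns)
    for frame in (out_vals, status, samples):
        frame.index.name = "sample_id"
    final_matrix = MeasurementMatrix(out_vals, status, samples)

    rec = LevelRecord(
        5,
        matrix.n_samples,
        matrix.n_samples - len(removed_samples),
        len(matrix.analytes),
        len(final_matrix.analytes),
        removed_samples=removed_samples,
        notes={
            "n_subjects": len(final_matrix.values),
            "outlier_subjects": list(report.flagged),
            "pca_components": report.n_components,
            "pca_threshold": report.threshold,
            "log2_analytes": transformed,
        },
    )
    audit.record(rec)
    return final_matrix, report


# --------------------------------------------------------------------------

def run_pipeline(
    matrix: MeasurementMatrix,
    clinical: pd.DataFrame,
    lod_tables: dict,
    config: PipelineConfig | None = None,
    outdir=None,
):
    """Execute Levels 1..5 and (optionally) write every level artifact.

    Returns ``(level5_matrix, audit, intermediates)`` where intermediates is
    a dict level -> MeasurementMatrix for levels 1..4.
    """
    config = config or PipelineConfig()
    audit = CurationAudit(config=asdict(config))
    h = config.config_hash()

    l1 = level1_exclude(matrix, config, audit)
    l2, factors = level2_scale(l1, audit)
    l3, verdicts = level3_filter(l2, config, audit)
    l4, flags = level4_impute_and_flag(l3, clinical, lod_tables, audit)
    l5, report = level5_finalize(l4, flags, config, audit)

    intermediates = {1: l1, 2: l2, 3: l3, 4: l4}
    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        for lvl, m in intermediates.items():
            write_level(m, lvl, os.path.join(outdir, f"LEVEL{lvl}.csv"), config_hash=h)
        write_level(
            l5, 5, os.path.join(outdir, "LEVEL5.csv"), config_hash=h,
            meta={"log2_analytes": ";".join(audit.transformed_analytes)},
        )
        audit.to_json(os.path.join(outdir, "audit.json"))
        pd.DataFrame(audit.analyte_metrics).to_csv(
            os.path.join(outdir, "metrics.csv"), index=False
        )
        factors.to_frame().to_csv(os.path.join(outdir, "scaling_factors.csv"), index=False)
    return l5, audit, intermediates
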