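"""Synthetic plate-level cohorts with known ground truth.

Generates everything the curation pipeline ingests — per-plate Level-0
exports, well manifest, plate LOD tables, zero-well / calibrator / kit-QC /
blank / internal-standard validation data, a clinical annotation table and
a free-text medication file — from a seeded generative model:

* subject's true abundances are lognormal per analyte;
* an observed value is truth x multiplicative plate batch effect x
  multiplicative technical noise (Gaussian on the linear scale, truncated
  at zero) — the parameterization the CV-based filters assume;
* SPQC wells share one pooled truth per analyte, so the cross-plate
  scaling factor has an exact generative answer (mean plate effect divided
  by the plate's effect);
* detection limits are set per plate from a target censoring quantile of
  the study wells, and the simulated zero wells are made consistent
  (zero level = LOD/3, matching the 3x rule);
* planted analyte defects (inflated technical CV, zero between-subject
  variance, heavy censoring), planted score-space subject outliers, and
  clinical flags (non-fasting, missing BMI, missing medication record)
  give every downstream filter a known expected outcome;
* medication text is drawn from the bundled lexicon with seeded
  misspellings; typos that would not resolve back to the intended drug —
  automatically or through the emitted review file — fall back to the
  clean spelling so the expected class matrix stays exact.

All randomness flows from ``SimulationConfig.seed``; identical configs give
byte-identical output files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import meds as med_mod
from .panel import STATUS_BELOW_LOD
from .validation import ValidationRule

_AMINO_ACIDS = [
    "Ala", "Arg", "Asn", "Asp", "Cit", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Orn", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
]
_BIOGENIC_AMINES = [
    "Histamine", "Putrescine", "Serotonin", "Spermidine", "Spermine",
    "Taurine", "ADMA", "SDMA", "Kynurenine", "Sarcosine", "Creatinine",
    "Dopamine", "DOPA", "Carnosine", "Acetylornithine", "Methioninesulfoxide",
    "Hydroxyproline", "PEA", "alpha-AAA", "Nitrotyrosine", "Kynurenic acid",
]


def _panel_names(n: int) -> list:
    """Deterministic panel of ``n`` analyte (id, class) pairs.

    Mirrors the composition of a p180-style panel: hexose + amino acids and
    biogenic amines (UPLC) + acylcarnitines, sphingomyelins and
    glycerophospholipids (FIA).
    """
    pools = [
        ("hexose", ["H1"]),
        ("amino acid", list(_AMINO_ACIDS)),
        ("biogenic amine", list(_BIOGENIC_AMINES)),
        ("acylcarnitine", [f"C{i}" if i % 2 == 0 else f"C{i}:1" for i in range(40)]),
        ("sphingolipid", [f"SM C{14 + 2 * (i % 8)}:{i % 2}" for i in range(15)]),
        (
            "glycerophospholipid",
            [f"PC aa C{28 + 2 * (i % 13)}:{i % 7}" for i in range(45)]
            + [f"PC ae C{30 + 2 * (i % 11)}:{i % 6}" for i in range(35)]
            + [f"lysoPC a C{14 + 2 * (i % 7)}:{i % 3}" for i in range(20)],
        ),
    ]
    # de-duplicate generated lipid names
    for i, (cls, names) in enumerate(pools):
        seen, uniq = set(), []
        for j, nm in enumerate(names):
            while nm in seen:
                nm = nm + "*"
            seen.add(nm)
            uniq.append(nm)
        pools[i] = (cls, uniq)
    out = []
    idx = [0] * len(pools)
    k = 0
    while len(out) < n:
        cls, names = pools[k % len(pools)]
        if idx[k % len(pools)] < len(names):
            out.append((names[idx[k % len(pools)]], cls))
            idx[k % len(pools)] += 1
        k += 1
        if k > 10 * n + 200:
            raise ValueError(f"cannot build a panel of {n} analytes")
    return out


@dataclass
class SimulationConfig:
    """Study-design parameters of a synthetic cohort (defaults: full-size run)."""

    seed: int
    n_plates: int = 11
    study_wells_per_plate: int = 76
    n_study_samples: int = 831
    n_duplicate_pairs: int = 20
    n_analytes: int = 182
    log_mean_range: tuple = (0.0, 3.0)   # ln of the µM-scale median
    log_sd_range: tuple = (0.2, 1.0)     # between-subject lognormal spread
    plate_effect_sd: float = 0.10        # ln-scale sd of plate batch effects
    technical_cv: float = 0.05           # per-injection noise, fraction
    n_high_cv: int = 15
    high_cv_value: float = 0.40
    n_low_icc: int = 14                  # planted with zero subject variance
    n_high_censor: int = 15
    censor_frac_bad: float = 0.60
    censor_frac_clean: float = 0.05
    n_outlier_subjects: int = 2
    outlier_magnitude: float = 30.0      # linear-scale sd units
    outlier_n_analytes: int = 10
    n_thawed: int = 4
    n_nonfasting: int = 69
    n_missing_bmi: int = 2
    n_missing_meds: int = 1
    max_meds_per_subject: int = 3
    typo_rate: float = 0.15
    p_unknown_med: float = 0.02
    force_med_examples: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_study_samples > self.n_plates * self.study_wells_per_plate:
            raise ValueError("more study samples than plate capacity")
        if self.n_duplicate_pairs > self.n_study_samples // 2:
            raise ValueError("more duplicate pairs than samples allow")
        n_defect = self.n_high_cv + self.n_low_icc + self.n_high_censor
        if n_defect > self.n_analytes:
            raise ValueError("more planted analyte defects than analytes")
        special = (
            self.n_duplicate_pairs + self.n_thawed + self.n_nonfasting
            + self.n_missing_bmi + self.n_missing_meds + self.n_outlier_subjects
            + (3 if self.force_med_examples else 0)
        )
        if special > self.n_subjects:
            raise ValueError("special-subject counts exceed the cohort size")

    @property
    def n_subjects(self) -> int:
        return self.n_study_samples - self.n_duplicate_pairs


@dataclass
class GroundTruth:
    """Everything a correct pipeline run is expected to reproduce."""

    plate_effects: dict = field(default_factory=dict)
    true_scaling_factors: dict = field(default_factory=dict)  # plate -> mean(b)/b_p
    analyte_defects: dict = field(default_factory=dict)       # analyte -> label
    expected_dropped_analytes: list = field(default_factory=list)
    outlier_subjects: list = field(default_factory=list)
    thawed_samples: list = field(default_factory=list)
    flagged_samples: dict = field(default_factory=dict)       # reason -> [sample ids]
    duplicate_groups: dict = field(default_factory=dict)      # group -> [s1, s2]
    expected_final_subjects: list = field(default_factory=list)
    med_truth: dict = field(default_factory=dict)             # subject -> [classes]
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _fmt(x: float) -> str:
    return repr(float(x))


def _make_med_entries(cfg: SimulationConfig, rng, subjects, missing_meds, lexicon):
    """Seeded free-text entries + review decisions + truth classes."""
    names = lexicon.names
    unknown_pool = ["qxzlvw", "zzduplex", "xembrofil", "qorvatan"]
    unknown_pool = [
        u for u in unknown_pool
        if max(med_mod.LevenshteinMatcher().score(u, n) for n in names) < 0.5
    ]
    dose_templates = ["{}", "{} 10mg", "{} 25 mg qd", "{} 50mg bid", "{} 1 tab daily"]
    thresholds = med_mod.MatchThresholds()
    matcher = med_mod.LevenshteinMatcher()

    entries = []
    truth: dict = {}
    review_candidates: dict = {}  # review-queued token -> intended lexicon name
    for subj in subjects:
        truth[subj] = set()
        if subj in missing_meds:
            continue
        k = int(rng.integers(0, cfg.max_meds_per_subject + 1))
        chosen = list(rng.choice(names, size=k, replace=False)) if k else []
        for name in chosen:
            text_name = name
            if rng.random() < cfg.typo_rate and len(name) >= 5:
                i = int(rng.integers(0, len(name) - 1))
                if name[i] != " " and name[i + 1] != " ":
                    cand = name[:i] + name[i + 1] + name[i] + name[i + 2:]
                    tok = med_mod.normalize_med_text(cand)[0]
                    top = med_mod.match_term(tok, lexicon, matcher, thresholds)[0]
                    resolved = top.candidate == name and top.status in (
                        med_mod.STATUS_AUTO, med_mod.STATUS_REVIEW
                    )
                    if resolved and tok != name:
                        text_name = cand
                        if top.status == med_mod.STATUS_REVIEW:
                            review_candidates[tok] = name
            template = dose_templates[int(rng.integers(0, len(dose_templates)))]
            entries.append({"subject_id": subj, "visit": "bl",
                            "raw_text": template.format(text_name)})
            truth[subj].update(lexicon.classes_of(name))
        if unknown_pool and rng.random() < cfg.p_unknown_med:
            u = unknown_pool[int(rng.integers(0, len(unknown_pool)))]
            entries.append({"subject_id": subj, "visit": "bl", "raw_text": u + " 5mg"})

    if cfg.force_med_examples:
        s_exact, s_typo, s_unknown = subjects[-3], subjects[-2], subjects[-1]
        entries = [e for e in entries if e["subject_id"] not in (s_exact, s_typo, s_unknown)]
        entries.append({"subject_id": s_exact, "visit": "bl", "raw_text": "Aricept 10mg QD"})
        entries.append({"subject_id": s_typo, "visit": "bl", "raw_text": "aricpet"})
        entries.append({"subject_id": s_unknown, "visit": "bl", "raw_text": "qxzlvw 5mg"})
        truth[s_exact] = lexicon.classes_of("aricept")
        truth[s_typo] = lexicon.classes_of("aricept")
        truth[s_unknown] = set()
        review_candidates["aricpet"] = "aricept"

    # emit decisions only for tokens that still occur in the final entries
    # (overrides above may have removed the entry that queued a token)
    present: set = set()
    for e in entries:
        present.update(med_mod.normalize_med_text(e["raw_text"]))
    review_rows = [
        {"query": tok, "action": "accept_as", "target": review_candidates[tok]}
        for tok in sorted(review_candidates)
        if tok in present
    ]
    return entries, review_rows, {s: sorted(c) for s, c in truth.items()}


def simulate_cohort(cfg: SimulationConfig, outdir) -> GroundTruth:
    """Write a full synthetic Level-0 bundle to ``outdir``; return its truth."""
    rng = np.random.default_rng(cfg.seed)
    os.makedirs(os.path.join(outdir, "plates"), exist_ok=True)

    panel = _panel_names(cfg.n_analytes)
    analytes = [a for a, _ in panel]
    classes = {a: c for a, c in panel}

    # --- analyte population parameters and planted defects
    mu = rng.uniform(*cfg.log_mean_range, size=cfg.n_analytes)
    sd = rng.uniform(*cfg.log_sd_range, size=cfg.n_analytes)
    order = rng.permutation(cfg.n_analytes)
    defects = np.array(["clean"] * cfg.n_analytes, dtype=object)
    i0 = 0
    for label, count in (
        ("high_cv", cfg.n_high_cv),
        ("low_icc", cfg.n_low_icc),
        ("high_censoring", cfg.n_high_censor),
    ):
        defects[order[i0:i0 + count]] = label
        i0 += count
    sd = np.where(defects == "low_icc", 0.0, sd)
    cv = np.where(defects == "high_cv", cfg.high_cv_value, cfg.technical_cv)
    censor_q = np.where(defects == "high_censoring", cfg.censor_frac_bad, cfg.censor_frac_clean)
    clean_idx = [i for i in order[i0:] if defects[i] == "clean"]
    outlier_analytes = [analytes[i] for i in clean_idx[: cfg.outlier_n_analytes]]

    # --- subjects and their special roles (disjoint by construction)
    n_sub = cfg.n_subjects
    subjects = [f"SUBJ{i:05d}" for i in range(n_sub)]
    cursor = 0
    dup_subjects = subjects[cursor:cursor + cfg.n_duplicate_pairs]; cursor += cfg.n_duplicate_pairs
    thawed_subjects = subjects[cursor:cursor + cfg.n_thawed]; cursor += cfg.n_thawed
    nonfasting = subjects[cursor:cursor + cfg.n_nonfasting]; cursor += cfg.n_nonfasting
    missing_bmi = subjects[cursor:cursor + cfg.n_missing_bmi]; cursor += cfg.n_missing_bmi
    missing_meds = subjects[cursor:cursor + cfg.n_missing_meds]; cursor += cfg.n_missing_meds
    outlier_subjects = subjects[cursor:cursor + cfg.n_outlier_subjects]

    truths = np.exp(mu[None, :] + sd[None, :] * rng.standard_normal((n_sub, cfg.n_analytes)))
    lin_mean = np.exp(mu + sd**2 / 2.0)
    lin_sd = lin_mean * np.sqrt(np.expm1(sd**2))
    out_cols = [analytes.index(a) for a in outlier_analytes]
    for s in outlier_subjects:
        i = subjects.index(s)
        truths[i, out_cols] = lin_mean[out_cols] + cfg.outlier_magnitude * lin_sd[out_cols]

    # --- sample bookkeeping: one sample per subject plus blinded duplicates
    sample_rows = []  # (sample_id, subject_id, duplicate_group)
    sid = 0
    dup_groups: dict = {}
    for j, subj in enumerate(subjects):
        grp = f"DUP{j:03d}" if subj in dup_subjects else None
        sample_rows.append([f"LAB{sid:05d}", subj, grp]); sid += 1
        if grp is not None:
            sample_rows.append([f"LAB{sid:05d}", subj, grp]); sid += 1
            dup_groups[grp] = [sample_rows[-2][0], sample_rows[-1][0]]
    perm = rng.permutation(len(sample_rows))
    sample_rows = [sample_rows[i] for i in perm]

    b = np.exp(cfg.plate_effect_sd * rng.standard_normal(cfg.n_plates))
    plate_ids = [f"P{p + 1:02d}" for p in range(cfg.n_plates)]
    subj_index = {s: i for i, s in enumerate(subjects)}

    manifest_rows, lod_rows, zero_rows = [], [], []
    cal_rows, qc_rows, blank_rows, istd_rows = [], [], [], []
    plate_tables = {}
    thawed_samples: list = []
    pos_of = {}
    cursor = 0
    istd_names = [f"ISTD_{i:02d}" for i in range(1, 11)]
    for p, plate in enumerate(plate_ids):
        take = min(cfg.study_wells_per_plate, len(sample_rows) - cursor)
        chunk = sample_rows[cursor:cursor + take]
        cursor += take
        # measured wells: SPQC brackets, NIST triplet, reference serum, studies
        wells = [("SPQC", None), ("NIST", None)]
        wells += [("study", row) for row in chunk[: take // 2]]
        wells += [("NIST", None), ("reference_serum", None)]
        wells += [("study", row) for row in chunk[take // 2:]]
        wells += [("NIST", None), ("SPQC", None)]

        n_wells = len(wells)
        noise = np.clip(1.0 + cv[None, :] * rng.standard_normal((n_wells, cfg.n_analytes)), 0.0, None)
        values = np.empty((n_wells, cfg.n_analytes))
        spqc_truth = np.where(sd == 0, np.exp(mu), lin_mean)
        nist_truth = 0.8 * spqc_truth
        ref_truth = 1.1 * spqc_truth
        meta = []
        qc_counter = {"SPQC": 0, "NIST": 0, "reference_serum": 0}
        for w, (role, row) in enumerate(wells):
            if role == "study":
                sample_id, subj, grp = row
                base = truths[subj_index[subj]]
            else:
                qc_counter[role] += 1
                sample_id = f"{plate}_{role}_{qc_counter[role]}"
                subj, grp = "", None
                base = {"SPQC": spqc_truth, "NIST": nist_truth, "reference_serum": ref_truth}[role]
            values[w] = base * b[p] * noise[w]
            meta.append((f"W{w + 1:02d}", role, sample_id, subj, grp))
            if role == "study" and subj in thawed_subjects:
                thawed_samples.append(sample_id)

        study_mask = np.array([r == "study" for r, _ in wells])
        lod = np.array(
            [np.quantile(values[study_mask, j], censor_q[j]) for j in range(cfg.n_analytes)]
        ) if study_mask.any() else np.zeros(cfg.n_analytes)
        censored = values < lod[None, :]

        cells = np.empty(values.shape, dtype=object)
        for w in range(n_wells):
            for j in range(cfg.n_analytes):
                cells[w, j] = "<LOD" if censored[w, j] else _fmt(values[w, j])
        table = pd.DataFrame(cells, columns=analytes)
        table.insert(0, "well_id", [m[0] for m in meta])
        table.insert(0, "plate_id", plate)
        plate_tables[plate] = table

        for pos, (well_id, role, sample_id, subj, grp) in enumerate(
            [(m[0], m[1], m[2], m[3], m[4]) for m in meta], start=1
        ):
            manifest_rows.append(
                {"plate_id": plate, "well_id": well_id, "role": role,
                 "sample_id": sample_id, "subject_id": subj,
                 "duplicate_group": grp or "", "injection_position": pos}
            )
        # unmeasured control wells appear in the manifest too
        extra_pos = len(meta)
        for role in (["blank", "zero"] + [f"calibrator_{i}" for i in range(1, 8)]
                     + ["kit_QC1", "kit_QC2", "kit_QC3"]):
            extra_pos += 1
            manifest_rows.append(
                {"plate_id": plate, "well_id": f"W{extra_pos:02d}", "role": role,
                 "sample_id": "", "subject_id": "", "duplicate_group": "",
                 "injection_position": extra_pos}
            )

        for j, a in enumerate(analytes):
            lod_rows.append({"plate_id": plate, "analyte_id": a, "lod": _fmt(lod[j])})
            zero_rows.append({"plate_id": plate, "analyte_id": a, "replicate": 1,
                              "value": _fmt(lod[j] / 3.0)})
        # kit-validation data: constructed to satisfy every acceptance rule
        cal_targets = np.array([2.0 ** (lv - 4) for lv in range(1, 8)])
        for j, a in enumerate(analytes):
            for lv in range(1, 8):
                target = lin_mean[j] * cal_targets[lv - 1]
                measured = target * (1.0 + 0.05 * rng.standard_normal())
                cal_rows.append({"plate_id": plate, "analyte_id": a, "level": lv,
                                 "target": _fmt(target), "measured": _fmt(measured)})
            for qlv, mult in ((1, 0.5), (2, 1.0), (3, 2.0)):
                for rep in range(1, 4):
                    target = lin_mean[j] * mult
                    measured = target * (1.0 + 0.08 * rng.standard_normal())
                    qc_rows.append({"plate_id": plate, "analyte_id": a, "qc_level": qlv,
                                    "replicate": rep, "target": _fmt(target),
                                    "measured": _fmt(measured)})
            blank_rows.append({"plate_id": plate, "name": a,
                               "signal": _fmt(rng.uniform(1.0, 20.0))})
        for name in istd_names:
            istd_rows.append({"plate_id": plate, "name": name,
                              "intensity": _fmt(rng.uniform(3e5, 6e5))})

    # --- clinical table
    bmi = np.clip(rng.normal(27.0, 4.0, size=n_sub), 15.0, 60.0)
    clin_rows = []
    for i, subj in enumerate(subjects):
        clin_rows.append(
            {"subject_id": subj,
             "fasting": str(subj not in set(nonfasting)),
             "bmi": "" if subj in set(missing_bmi) else _fmt(bmi[i]),
             "has_baseline_med_record": str(subj not in set(missing_meds))}
        )

    # --- medications
    lexicon = med_mod.TermLexicon.default()
    entries, review_rows, med_truth = _make_med_entries(
        cfg, rng, subjects, set(missing_meds), lexicon
    )

    # --- write everything
    def _write(df_rows, name, columns):
        pd.DataFrame(df_rows, columns=columns).to_csv(os.path.join(outdir, name), index=False)

    for plate, table in plate_tables.items():
        table.to_csv(os.path.join(outdir, "plates", f"{plate}.csv"), index=False)
    _write(manifest_rows, "manifest.csv",
           ["plate_id", "well_id", "role", "sample_id", "subject_id",
            "duplicate_group", "injection_position"])
    _write(lod_rows, "lod.csv", ["plate_id", "analyte_id", "lod"])
    _write(zero_rows, "zero_wells.csv", ["plate_id", "analyte_id", "replicate", "value"])
    _write(cal_rows, "calibrators.csv", ["plate_id", "analyte_id", "level", "target", "measured"])
    _write(qc_rows, "kit_qcs.csv",
           ["plate_id", "analyte_id", "qc_level", "replicate", "target", "measured"])
    _write(blank_rows, "blanks.csv", ["plate_id", "name", "signal"])
    _write(istd_rows, "istd.csv", ["plate_id", "name", "intensity"])
    _write(clin_rows, "clinical.csv",
           ["subject_id", "fasting", "bmi", "has_baseline_med_record"])
    _write(entries, "meds.csv", ["subject_id", "visit", "raw_text"])
    _write(review_rows, "med_review.csv", ["query", "action", "target"])
    pd.DataFrame(
        [{"analyte_id": a, "analyte_class": classes[a],
          "platform": "UPLC" if classes[a] in ("amino acid", "biogenic amine") else "FIA",
          "quantitation": "fully-quantitative"
          if classes[a] in ("amino acid", "biogenic amine") else "semi-quantitative"}
         for a in analytes]
    ).to_csv(os.path.join(outdir, "panel.csv"), index=False)
    rule = ValidationRule(
        blank_max={a: 100.0 for a in analytes},
        istd_bounds={n: (2e5, 8e5) for n in istd_names},
    )
    rule.to_yaml(os.path.join(outdir, "rules.yaml"))

    # --- ground truth
    flagged = {
        "non_fasting": sorted(
            s for s, subj, _ in (tuple(r) for r in sample_rows) if subj in set(nonfasting)
        ),
        "missing_bmi": sorted(
            s for s, subj, _ in (tuple(r) for r in sample_rows) if subj in set(missing_bmi)
        ),
        "missing_med_record": sorted(
            s for s, subj, _ in (tuple(r) for r in sample_rows) if subj in set(missing_meds)
        ),
    }
    removed_subjects = set(thawed_subjects) | set(nonfasting) | set(missing_bmi) \
        | set(missing_meds) | set(outlier_subjects)
    gt = GroundTruth(
        plate_effects={plate_ids[p]: float(b[p]) for p in range(cfg.n_plates)},
        true_scaling_factors={
            plate_ids[p]: float(b.mean() / b[p]) for p in range(cfg.n_plates)
        },
        analyte_defects={analytes[j]: str(defects[j]) for j in range(cfg.n_analytes)},
        expected_dropped_analytes=sorted(
            analytes[j] for j in range(cfg.n_analytes) if defects[j] != "clean"
        ),
        outlier_subjects=list(outlier_subjects),
        thawed_samples=sorted(thawed_samples),
        flagged_samples=flagged,
        duplicate_groups=dup_groups,
        expected_final_subjects=sorted(set(subjects) - removed_subjects),
        med_truth=med_truth,
        config=asdict(cfg),
    )
    gt.to_json(os.path.join(outdir, "ground_truth.json"))
    return gt


def cohort_paths(outdir) -> dict:
    """Canonical file locations inside a simulated-cohort directory."""
    plates_dir = os.path.join(outdir, "plates")
    return {
        "plates": sorted(
            os.path.join(plates_dir, f) for f in os.listdir(plates_dir) if f.endswith(".csv")
        ),
        "manifest": os.path.join(outdir, "manifest.csv"),
        "lod": os.path.join(outdir, "lod.csv"),
        "zero_wells": os.path.join(outdir, "zero_wells.csv"),
        "calibrators": os.path.join(outdir, "calibrators.csv"),
        "kit_qcs": os.path.join(outdir, "kit_qcs.csv"),
        "blanks": os.path.join(outdir, "blanks.csv"),
        "istd": os.path.join(outdir, "istd.csv"),
        "rules": os.path.join(outdir, "rules.yaml"),
        "clinical": os.path.join(outdir, "clinical.csv"),
        "meds": os.path.join(outdir, "meds.csv"),
        "med_review": os.path.join(outdir, "med_review.csv"),
        "panel": os.path.join(outdir, "panel.csv"),
        "ground_truth": os.path.join(outdir, "ground_truth.json"),
    }


REFERENCE_FIXTURE_SEED = 104729


def reference_fixture_config() -> SimulationConfig:
    """Desk-scale deterministic fixture: 3 plates, 40 analytes, 6 duplicate
    pairs, 2 planted defects per type, 1 planted outlier subject.

    The cohort must stay comfortably above ~50 subjects: a distance rule of
    the form mean + 7 sd can never flag a single outlier among fewer than
    51 points (the outlier inflates the sd it is compared against).
    """
    return SimulationConfig(
        seed=REFERENCE_FIXTURE_SEED,
        n_plates=3,
        study_wells_per_plate=40,
        n_study_samples=120,
        n_duplicate_pairs=6,
        n_analytes=40,
        n_high_cv=2,
        n_low_icc=2,
        n_high_censor=2,
        n_outlier_subjects=1,
        outlier_n_analytes=5,
        n_thawed=2,
        n_nonfasting=3,
        n_missing_bmi=1,
        n_missing_meds=1,
        force_med_examples=True,
    )


def make_reference_fixture(outdir) -> GroundTruth:
    """Regenerate the packaged reference fixture (byte-identical every time)."""
    return simulate_cohort(reference_fixture_config(), outdir)
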