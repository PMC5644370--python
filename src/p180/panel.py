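"""Data model and file I/O for p180-style plate exports.

A Biocrates-p180 run produces, per 96-well plate, a table of analyte
concentrations (µM) for every injected well, together with a well-role
manifest (which wells are study samples, pooled study QC, NIST plasma,
reference serum, kit QCs, calibrators, blank, zero) and a plate-specific
limit-of-detection table. This module defines the in-memory containers and
the CSV dialects used throughout the curation pipeline.

Cell encoding
-------------
Measurement cells are either a plain number (status ``valid``), the
case-insensitive sentinel ``<LOD`` (value missing, explained), ``<LLOQ``
optionally carrying a numeric payload (``<LLOQ|0.12``), or one of the
tagged forms ``IMP|x`` (imputed at LOD/2) and ``SQ|x`` (semi-quantitative).
An empty cell is missing *without* explanation; the two kinds of
missingness are deliberately distinct so the %<LOD filter can tell them
apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PIPELINE_VERSION = "0.1.0"

# --------------------------------------------------------------------------
# status flags

STATUS_VALID = "valid"
STATUS_BELOW_LOD = "below_LOD"
STATUS_BELOW_LLOQ = "below_LLOQ"
STATUS_SEMI_QUANT = "semi_quant"
STATUS_IMPUTED = "imputed"

ALL_STATUSES = {
    STATUS_VALID,
    STATUS_BELOW_LOD,
    STATUS_BELOW_LLOQ,
    STATUS_SEMI_QUANT,
    STATUS_IMPUTED,
}

# analyte classes and the platform each is measured on: amino acids and
# biogenic amines are chromatographically separated (UPLC); acylcarnitines,
# lipids and hexose are flow-injection (FIA, semi-quantitative for most).
ANALYTE_CLASS_PLATFORM = {
    "acylcarnitine": "FIA",
    "amino acid": "UPLC",
    "biogenic amine": "UPLC",
    "glycerophospholipid": "FIA",
    "sphingolipid": "FIA",
    "hexose": "FIA",
}

WELL_ROLES = {
    "study",
    "SPQC",
    "kit_QC1",
    "kit_QC2",
    "kit_QC3",
    "blank",
    "zero",
    "NIST",
    "reference_serum",
}
# calibrator roles are "calibrator_1" .. "calibrator_7"
MEASURED_ROLES = {"study", "SPQC", "NIST", "reference_serum"}


def _is_valid_role(role: str) -> bool:
    return role in WELL_ROLES or role.startswith("calibrator_")


@dataclass(frozen=True)
class AnalyteDef:
    """One analyte of the panel: id, biochemical class, platform, quantitation."""

    analyte_id: str
    analyte_class: str
    platform: str
    quantitation: str  # fully-quantitative | semi-quantitative

    def __post_init__(self):
        if self.analyte_class not in ANALYTE_CLASS_PLATFORM:
            raise ValueError(f"unknown analyte class {self.analyte_class!r}")
        expected = ANALYTE_CLASS_PLATFORM[self.analyte_class]
        if self.platform != expected:
            raise ValueError(
                f"{self.analyte_id}: class {self.analyte_class!r} is measured "
                f"by {expected}, not {self.platform}"
            )


@dataclass(frozen=True)
class WellRole:
    role: str
    injection_position: int

    def __post_init__(self):
        if not _is_valid_role(self.role):
            raise ValueError(f"unknown well role {self.role!r}")


@dataclass
class PlateRun:
    """One plate: its well manifest and plate-specific LOD table (µM)."""

    plate_id: str
    wells: list  # of (well_id, WellRole, sample_id or None)
    lod: dict = field(default_factory=dict)  # analyte_id -> LOD, >= 0

    def __post_init__(self):
        for a, v in self.lod.items():
            if v < 0:
                raise ValueError(f"plate {self.plate_id}: negative LOD for {a}")


class MeasurementMatrix:
    """Samples x analytes concentrations with per-cell status flags.

    Parameters
    ----------
    values : DataFrame
        float, indexed by sample_id, one column per analyte; NaN where the
        concentration is missing (explained or not).
    status : DataFrame
        same shape/index/columns, values from ``ALL_STATUSES``.
    samples : DataFrame
        indexed by sample_id with columns ``subject_id``, ``plate_id``,
        ``role`` and ``duplicate_group`` (NaN except for blinded duplicate
        pairs, which carry a shared group label).
    """

    SAMPLE_COLS = ["subject_id", "plate_id", "role", "duplicate_group"]

    def __init__(self, values: pd.DataFrame, status: pd.DataFrame, samples: pd.DataFrame):
        if not values.index.equals(status.index) or not values.index.equals(samples.index):
            raise ValueError("values, status and samples must share one sample index")
        if list(values.columns) != list(status.columns):
            raise ValueError("values and status must share identical analyte columns")
        if values.index.has_duplicates:
            raise ValueError("duplicate sample_id in matrix")
        for col in self.SAMPLE_COLS:
            if col not in samples.columns:
                raise ValueError(f"samples table lacks column {col!r}")
        bad = set(np.unique(status.values.astype(str))) - ALL_STATUSES
        if bad:
            raise ValueError(f"unknown status flags {sorted(bad)}")
        # a below_LOD cell never carries a silently usable number
        lod_mask = status.values == STATUS_BELOW_LOD
        if np.isfinite(values.values[lod_mask]).any():
            raise ValueError("below_LOD cells must not carry numeric values")
        self._check_duplicate_groups(samples)
        self.values = values.astype(float)
        self.status = status
        self.samples = samples

    @staticmethod
    def _check_duplicate_groups(samples: pd.DataFrame) -> None:
        grp = samples.dropna(subset=["duplicate_group"])
        for g, sub in grp.groupby("duplicate_group"):
            # a pair may lose one member to sample exclusions downstream,
            # but can never gain a third or span two subjects
            if len(sub) > 2:
                raise ValueError(f"duplicate_group {g!r} has {len(sub)} samples, expected <= 2")
            if sub["subject_id"].nunique() != 1:
                raise ValueError(f"duplicate_group {g!r} spans multiple subjects")

    # -- basic accessors ----------------------------------------------------
    @property
    def analytes(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def study_mask(self) -> pd.Series:
        return self.samples["role"] == "study"

    def rows(self, mask) -> "MeasurementMatrix":
        return MeasurementMatrix(
            self.values.loc[mask].copy(), self.status.loc[mask].copy(), self.samples.loc[mask].copy()
        )

    def drop_samples(self, sample_ids) -> "MeasurementMatrix":
        keep = ~self.values.index.isin(list(sample_ids))
        return self.rows(keep)

    def drop_analytes(self, analyte_ids) -> "MeasurementMatrix":
        keep = [a for a in self.values.columns if a not in set(analyte_ids)]
        return MeasurementMatrix(
            self.values[keep].copy(), self.status[keep].copy(), self.samples.copy()
        )

    def copy(self) -> "MeasurementMatrix":
        return MeasurementMatrix(self.values.copy(), self.status.copy(), self.samples.copy())

    def equals(self, other: "MeasurementMatrix") -> bool:
        va, vb = self.values, other.values
        return (
            va.index.equals(vb.index)
            and list(va.columns) == list(vb.columns)
            and ((va.values == vb.values) | (np.isnan(va.values) & np.isnan(vb.values))).all()
            and (self.status.values == other.status.values).all()
            and self.samples[self.SAMPLE_COLS].fillna("").equals(
                other.samples[self.SAMPLE_COLS].fillna("")
            )
        )


# --------------------------------------------------------------------------
# cell codec

def encode_cell(value: float, status: str) -> str:
    if status == STATUS_BELOW_LOD:
        return "<LOD"
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "" if status == STATUS_VALID else {STATUS_BELOW_LLOQ: "<LLOQ"}.get(status, "")
    if status == STATUS_VALID:
        return repr(float(value))
    if status == STATUS_BELOW_LLOQ:
        return f"<LLOQ|{float(value)!r}"
    if status == STATUS_IMPUTED:
        return f"IMP|{float(value)!r}"
    if status == STATUS_SEMI_QUANT:
        return f"SQ|{float(value)!r}"
    raise ValueError(f"cannot encode status {status!r}")


def decode_cell(text: str) -> tuple:
    """Return (value, status) for one cell's text."""
    t = str(text).strip()
    if t == "" or t.lower() == "nan":
        return (np.nan, STATUS_VALID)
    low = t.lower()
    if low == "<lod":
        return (np.nan, STATUS_BELOW_LOD)
    if low == "<lloq":
        return (np.nan, STATUS_BELOW_LLOQ)
    if low.startswith("<lloq|"):
        return (float(t[6:]), STATUS_BELOW_LLOQ)
    if low.startswith("imp|"):
        return (float(t[4:]), STATUS_IMPUTED)
    if low.startswith("sq|"):
        return (float(t[3:]), STATUS_SEMI_QUANT)
    return (float(t), STATUS_VALID)


# --------------------------------------------------------------------------
# level-0 reading

def read_manifest(path) -> pd.DataFrame:
    man = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"plate_id", "well_id", "role", "sample_id"}
    missing = required - set(man.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    if man.duplicated(["plate_id", "well_id"]).any():
        dup = man[man.duplicated(["plate_id", "well_id"], keep=False)].iloc[0]
        raise ValueError(f"duplicate (plate, well) in manifest: {dup.plate_id}/{dup.well_id}")
    for r in man["role"]:
        if not _is_valid_role(r):
            raise ValueError(f"manifest has well without a known role: {r!r}")
    for col in ("subject_id", "duplicate_group", "injection_position"):
        if col not in man.columns:
            man[col] = ""
    return man


def read_lod_table(path) -> dict:
    """plate_id -> {analyte_id -> LOD}."""
    df = pd.read_csv(path, dtype={"plate_id": str, "analyte_id": str})
    out: dict = {}
    for row in df.itertuples(index=False):
        lod = float(row.lod)
        if lod < 0:
            raise ValueError(f"negative LOD for {row.plate_id}/{row.analyte_id}")
        out.setdefault(str(row.plate_id), {})[str(row.analyte_id)] = lod
    return out


def read_level0(plate_files, manifest_path, lod_path=None, panel=None):
    """Read per-plate Level-0 exports into one MeasurementMatrix.

    Rows are the measured wells (study, SPQC, NIST, reference serum); kit
    QCs, calibrators, blanks and zero wells live in the separate validation
    tables. Returns ``(matrix, plate_runs)``.
    """
    man = read_manifest(manifest_path)
    roles = {(r.plate_id, r.well_id): r for r in man.itertuples(index=False)}
    known = set(panel) if panel is not None else None
    lods = read_lod_table(lod_path) if lod_path else {}

    values_rows, status_rows, meta_rows, index = [], [], [], []
    analyte_cols = None
    plate_runs = []
    for path in plate_files:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        meta_cols = [c for c in ("plate_id", "well_id") if c in df.columns]
        if set(meta_cols) != {"plate_id", "well_id"}:
            raise ValueError(f"{path}: plate export needs plate_id and well_id columns")
        cols = [c for c in df.columns if c not in ("plate_id", "well_id")]
        if known is not None:
            unknown = [c for c in cols if c not in known]
            if unknown:
                raise ValueError(f"{path}: unknown analyte column {unknown[0]!r}")
        if analyte_cols is None:
            analyte_cols = cols
        elif cols != analyte_cols:
            raise ValueError(f"{path}: analyte columns differ from first plate export")

        plate_ids = df["plate_id"].unique()
        for plate_id in plate_ids:
            sub = df[df["plate_id"] == plate_id].reset_index(drop=True)
            wells = []
            for _, row in sub.iterrows():
                well_id = row["well_id"]
                key = (plate_id, well_id)
                if key not in roles:
                    raise ValueError(f"well without role in manifest: {plate_id}/{well_id}")
                m = roles[key]
                pos = int(m.injection_position) if str(m.injection_position) else 0
                wells.append((well_id, WellRole(m.role, pos), m.sample_id or None))
                if m.role not in MEASURED_ROLES:
                    continue
                values_row, status_row = zip(*(decode_cell(row[c]) for c in analyte_cols))
                sid = m.sample_id or f"{plate_id}:{well_id}"
                if sid in index:
                    raise ValueError(f"duplicate sample id {sid!r} across plate exports")
                index.append(sid)
                values_rows.append(values_row)
                status_rows.append(status_row)
                meta_rows.append(
                    {
                        "subject_id": m.subject_id or sid,
                        "plate_id": plate_id,
                        "role": m.role,
                        "duplicate_group": m.duplicate_group or np.nan,
                    }
                )
            plate_runs.append(PlateRun(plate_id, wells, lods.get(plate_id, {})))

    values = pd.DataFrame(values_rows, index=index, columns=analyte_cols, dtype=float)
    status = pd.DataFrame(status_rows, index=index, columns=analyte_cols)
    samples = pd.DataFrame(meta_rows, index=index)
    for frame in (values, status, samples):
        frame.index.name = "sample_id"
    return MeasurementMatrix(values, status, samples), plate_runs


# --------------------------------------------------------------------------
# level files (1..5)

def write_level(matrix: MeasurementMatrix, level: int, path, config_hash: str = "", meta: dict | None = None) -> None:
    """Write an intermediate/final level file (CSV with a commented header)."""
    if not 1 <= int(level) <= 5:
        raise ValueError("level must be in 1..5")
    meta = dict(meta or {})
    lines = [
        f"# p180_level={int(level)}",
        f"# pipeline_version={PIPELINE_VERSION}",
        f"# config_hash={config_hash}",
    ]
    for k in sorted(meta):
        lines.append(f"# {k}={meta[k]}")
    cols = ["sample_id"] + MeasurementMatrix.SAMPLE_COLS + matrix.analytes
    lines.append(",".join(f'"{c}"' if "," in c else c for c in cols))
    vals = matrix.values.values
    stats = matrix.status.values
    for i, sid in enumerate(matrix.values.index):
        s = matrix.samples.iloc[i]
        dg = s["duplicate_group"]
        row = [
            str(sid),
            str(s["subject_id"]),
            "" if pd.isna(s["plate_id"]) else str(s["plate_id"]),
            str(s["role"]),
            "" if pd.isna(dg) else str(dg),
        ]
        row += [encode_cell(vals[i, j], stats[i, j]) for j in range(vals.shape[1])]
        lines.append(",".join(f'"{c}"' if "," in c else c for c in row))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def _split_csv_line(line: str) -> list:
    out, cur, q = [], [], False
    for ch in line:
        if ch == '"':
            q = not q
        elif ch == "," and not q:
            out.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    out.append("".join(cur))
    return out


def read_level(path):
    """Read a level file back into ``(MeasurementMatrix, header_meta)``."""
    meta: dict = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    body = []
    for ln in lines:
        if ln.startswith("#"):
            k, _, v = ln[1:].strip().partition("=")
            meta[k.strip()] = v
        elif ln:
            body.append(ln)
    header = _split_csv_line(body[0])
    n_meta = 1 + len(MeasurementMatrix.SAMPLE_COLS)
    analytes = header[n_meta:]
    index, metas, vrows, srows = [], [], [], []
    for ln in body[1:]:
        cells = _split_csv_line(ln)
        index.append(cells[0])
        metas.append(
            {
                "subject_id": cells[1],
                "plate_id": cells[2] or np.nan,
                "role": cells[3],
                "duplicate_group": cells[4] or np.nan,
            }
        )
        vr, sr = zip(*(decode_cell(c) for c in cells[n_meta:])) if analytes else ((), ())
        vrows.append(vr)
        srows.append(sr)
    values = pd.DataFrame(vrows, index=index, columns=analytes, dtype=float)
    status = pd.DataFrame(srows, index=index, columns=analytes)
    samples = pd.DataFrame(metas, index=index) if index else pd.DataFrame(
        columns=MeasurementMatrix.SAMPLE_COLS, index=pd.Index([], name="sample_id")
    )
    for frame in (values, status, samples):
        frame.index.name = "sample_id"
    return MeasurementMatrix(values, status, samples), meta


# --------------------------------------------------------------------------
# clinical table

def read_clinical(path) -> pd.DataFrame:
    """Clinical annotations indexed by subject_id.

    Columns: ``fasting`` (bool), ``bmi`` (float, NaN if missing),
    ``has_baseline_med_record`` (bool).
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in clinical table")
    df = df.set_index("subject_id")
    for col in ("fasting", "has_baseline_med_record"):
        df[col] = df[col].map(
            lambda x: str(x).strip().lower() in ("true", "1", "yes", "t")
        )
    df["bmi"] = pd.to_numeric(df["bmi"], errors="coerce")
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.insert(0, "subject_id", out.index)
    out.to_csv(path, index=False)
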