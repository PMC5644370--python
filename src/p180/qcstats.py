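"""Statistical primitives of the curation pipeline.

Cross-plate scaling anchored on the pooled study QC (SPQC), duplicate-based
precision metrics (CV, one-way ICC), detection-limit missingness, PCA
distance-based subject outlier screening, and the skewness/normality rule
that decides which analytes get log2-transformed.

The precision metrics are computed from blinded analytical duplicates: a
second aliquot of the same serum draw inserted under a different sample id.
With only two members per pair the one-way random-effects ICC(1,1) is the
natural estimator — duplicates are exchangeable technical replicates, there
is no rater structure — and it may legitimately go negative when the
within-pair scatter exceeds the between-subject spread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .panel import MeasurementMatrix, STATUS_BELOW_LOD


# --------------------------------------------------------------------------
# SPQC cross-plate scaling

@dataclass
class ScalingFactors:
    """Multiplicative per-(plate, analyte) correction factors.

    ``table`` is indexed by plate_id with one column per analyte; the factor
    is the analyte's global SPQC average divided by its SPQC average within
    the plate, so multiplying a plate's measurements by its factor equalizes
    SPQC means across plates.
    """

    table: pd.DataFrame

    def factor(self, plate_id: str, analyte_id: str) -> float:
        return float(self.table.loc[plate_id, analyte_id])

    def to_frame(self) -> pd.DataFrame:
        long = self.table.stack().rename("factor").reset_index()
        long.columns = ["plate_id", "analyte_id", "factor"]
        return long


def compute_scaling_factors(matrix: MeasurementMatrix) -> ScalingFactors:
    """SPQC-anchored scaling factors: global mean / plate mean, per analyte."""
    spqc = matrix.samples["role"] == "SPQC"
    if not spqc.any():
        raise ValueError("matrix has no SPQC rows")
    vals = matrix.values.loc[spqc]
    plates = matrix.samples.loc[spqc, "plate_id"]
    plate_means = vals.groupby(plates).mean()  # NaN-aware
    global_mean = vals.mean()
    factors = global_mean.values[None, :] / plate_means.values
    bad = ~np.isfinite(factors) | (plate_means.values == 0)
    if bad.any():
        n = int(bad.sum())
        warnings.warn(f"{n} (plate, analyte) SPQC means undefined or zero; factor set to 1")
        factors = np.where(bad, 1.0, factors)
    table = pd.DataFrame(factors, index=plate_means.index, columns=vals.columns)
    return ScalingFactors(table)


def apply_scaling(matrix: MeasurementMatrix, factors: ScalingFactors) -> MeasurementMatrix:
    """Multiply every cell by its plate/analyte factor; flags are untouched."""
    plates = matrix.samples["plate_id"]
    missing_plates = set(plates.dropna()) - set(factors.table.index)
    if missing_plates:
        raise ValueError(f"no scaling factors for plates {sorted(missing_plates)}")
    missing_analytes = set(matrix.analytes) - set(factors.table.columns)
    if missing_analytes:
        raise ValueError(f"no scaling factors for analytes {sorted(missing_analytes)[:5]}")
    f = factors.table.loc[plates, matrix.analytes].to_numpy()
    out = matrix.copy()
    out.values = pd.DataFrame(
        matrix.values.to_numpy() * f, index=matrix.values.index, columns=matrix.values.columns
    )
    return out


# --------------------------------------------------------------------------
# duplicate-based precision

def _duplicate_arrays(matrix: MeasurementMatrix):
    """Align duplicate pairs into two (n_pairs, n_analytes) arrays."""
    dup = matrix.samples.dropna(subset=["duplicate_group"])
    groups = []
    a_rows, b_rows = [], []
    for g, sub in dup.groupby("duplicate_group"):
        if len(sub) != 2:
            warnings.warn(f"duplicate_group {g!r} has {len(sub)} members; skipped")
            continue
        sa, sb = sub.index
        groups.append(g)
        a_rows.append(matrix.values.loc[sa].to_numpy())
        b_rows.append(matrix.values.loc[sb].to_numpy())
    if not groups:
        return [], np.empty((0, len(matrix.analytes))), np.empty((0, len(matrix.analytes)))
    return groups, np.vstack(a_rows), np.vstack(b_rows)


def duplicate_cv(matrix: MeasurementMatrix) -> pd.Series:
    """Per-analyte duplicate CV (%): mean over pairs of (sample sd / mean) x 100.

    Pairs with a missing member are skipped for that analyte; pairs with a
    non-positive mean are skipped with a warning. Analytes with no usable
    pair get NaN (and, by policy, fail the retention filter downstream).
    """
    groups, a, b = _duplicate_arrays(matrix)
    n_analytes = len(matrix.analytes)
    if not groups:
        return pd.Series(np.nan, index=matrix.analytes, name="cv")
    mean = (a + b) / 2.0
    sd = np.abs(a - b) / np.sqrt(2.0)  # sample sd of two values
    usable = np.isfinite(a) & np.isfinite(b)
    nonpos = usable & (mean <= 0)
    if nonpos.any():
        warnings.warn(f"{int(nonpos.sum())} duplicate pairs with non-positive mean skipped")
    usable &= mean > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cv_pair = np.where(usable, sd / mean * 100.0, np.nan)
    out = np.full(n_analytes, np.nan)
    counts = usable.sum(axis=0)
    has = counts > 0
    out[has] = np.nanmean(cv_pair[:, has], axis=0)
    return pd.Series(out, index=matrix.analytes, name="cv")


def icc_oneway(a: np.ndarray, b: np.ndarray) -> float:
    """One-way random-effects ICC(1,1) for paired replicates (k = 2).

    (MSB - MSW) / (MSB + (k-1) MSW) from the one-way ANOVA decomposition.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(a)
    if n < 2:
        return np.nan
    m = (a + b) / 2.0
    g = m.mean()
    msb = 2.0 * np.sum((m - g) ** 2) / (n - 1)
    msw = np.sum((a - m) ** 2 + (b - m) ** 2) / n
    denom = msb + msw
    if denom == 0:
        return 1.0 if msb == msw else np.nan
    return (msb - msw) / denom


def duplicate_icc(matrix: MeasurementMatrix, min_pairs: int = 3) -> pd.Series:
    """Per-analyte ICC(1,1) over complete duplicate pairs (NaN if < min_pairs)."""
    groups, a, b = _duplicate_arrays(matrix)
    out = pd.Series(np.nan, index=matrix.analytes, name="icc")
    if not groups:
        return out
    usable = np.isfinite(a) & np.isfinite(b)
    for j, analyte in enumerate(matrix.analytes):
        mask = usable[:, j]
        if mask.sum() < min_pairs:
            continue
        out.iloc[j] = icc_oneway(a[mask, j], b[mask, j])
    return out


def pct_below_lod(matrix: MeasurementMatrix) -> pd.Series:
    """Percent of *study* measurements flagged below the detection limit.

    QC, calibrator and reference wells are excluded from numerator and
    denominator: missingness of controls is not a property of the cohort.
    """
    study = matrix.study_mask()
    if not study.any():
        raise ValueError("matrix has no study rows")
    flagged = (matrix.status.loc[study] == STATUS_BELOW_LOD).sum()
    return (100.0 * flagged / int(study.sum())).rename("pct_below_lod")


# --------------------------------------------------------------------------
# analyte verdicts

VERDICT_RETAIN = "retain"
VERDICT_DROP_CV = "drop_cv"
VERDICT_DROP_ICC = "drop_icc"
VERDICT_DROP_LOD = "drop_lod"


def analyte_verdicts(
    cv: pd.Series,
    icc: pd.Series,
    pct_lod: pd.Series,
    cv_max: float = 20.0,
    icc_min: float = 0.65,
    lod_pct_max: float = 40.0,
) -> pd.DataFrame:
    """Retention verdict per analyte.

    Retain iff CV < cv_max AND ICC > icc_min (strictly: an ICC exactly at
    the threshold is excluded) AND %<LOD <= lod_pct_max. The verdict records
    the first failing rule in the fixed order CV, ICC, LOD; an undefined
    metric fails its own rule (the pipeline is deliberately stringent).
    """
    df = pd.DataFrame({"pct_below_lod": pct_lod, "cv": cv, "icc": icc})
    verdicts = []
    for analyte, row in df.iterrows():
        if not np.isfinite(row["cv"]) or row["cv"] >= cv_max:
            verdicts.append(VERDICT_DROP_CV)
        elif not np.isfinite(row["icc"]) or row["icc"] <= icc_min:
            verdicts.append(VERDICT_DROP_ICC)
        elif row["pct_below_lod"] > lod_pct_max:
            verdicts.append(VERDICT_DROP_LOD)
        else:
            verdicts.append(VERDICT_RETAIN)
    df["verdict"] = verdicts
    df.index.name = "analyte_id"
    return df


# --------------------------------------------------------------------------
# PCA subject outliers

@dataclass
class OutlierReport:
    n_components: int
    explained: float  # cumulative variance fraction of the retained scores
    distances: pd.Series  # per-subject Euclidean distance from score centroid
    threshold: float
    flagged: list = field(default_factory=list)
    dropped_analytes: list = field(default_factory=list)


def pca_outliers(df: pd.DataFrame, var_cum: float = 0.90, k_sd: float = 7.0) -> OutlierReport:
    """Flag subjects far from the centroid in principal-component space.

    Analytes are standardized (concentrations span orders of magnitude
    across classes), PCA is run on subjects, the smallest K with cumulative
    explained variance strictly above ``var_cum`` is kept, and a subject is
    flagged when its Euclidean distance from the K-dimensional score
    centroid exceeds mean(d) + k_sd * sd(d). Sign flips of components do
    not move distances.
    """
    if df.isna().any().any():
        raise ValueError("pca_outliers requires a complete matrix (run after imputation)")
    if len(df) < 3:
        raise ValueError("pca_outliers requires at least 3 subjects")
    sd = df.std(ddof=0)
    dropped = list(df.columns[sd == 0])
    if dropped:
        warnings.warn(f"{len(dropped)} zero-variance analytes dropped from PCA")
    work = df[[c for c in df.columns if c not in dropped]]
    if work.shape[1] == 0:
        d = pd.Series(0.0, index=df.index, name="distance")
        return OutlierReport(0, 0.0, d, 0.0, [], dropped)
    z = (work - work.mean()) / work.std(ddof=0)
    pca = PCA(n_components=min(z.shape) if min(z.shape) < z.shape[1] else None, svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.argmax(cum > var_cum)) + 1 if (cum > var_cum).any() else len(cum)
    s = scores[:, :k]
    centroid = s.mean(axis=0)
    d = pd.Series(np.linalg.norm(s - centroid, axis=1), index=df.index, name="distance")
    thr = float(d.mean() + k_sd * d.std(ddof=1)) if len(d) > 1 else float(d.mean())
    flagged = list(d.index[d > thr])
    return OutlierReport(k, float(cum[k - 1]), d, thr, flagged, dropped)


# --------------------------------------------------------------------------
# conditional log2 rule

def normality_decision(
    values,
    alpha: float = 0.05,
    skew_min: float = 2.0,
    min_n: int = 20,
) -> bool:
    """True iff the analyte should be log2-transformed.

    Requires *both* a significant D'Agostino–Pearson omnibus test
    (p < alpha) and strong right skew (Fisher–Pearson g1 > skew_min).
    Below ``min_n`` usable values the tests are unreliable and the analyte
    is left untransformed with a warning.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < min_n:
        warnings.warn(f"normality decision skipped: only {len(x)} values (< {min_n})")
        return False
    if np.all(x == x[0]):
        return False
    p = sps.normaltest(x).pvalue
    g1 = sps.skew(x)
    return bool(p < alpha and g1 > skew_min)
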