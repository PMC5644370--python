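"""Per-plate technical validation of a p180 kit run.

Each plate carries its own controls: a blank, a zero sample (internal
standards only, used to establish background and hence the plate-specific
LOD = 3x the zero-sample level), a calibrator series, three levels of
kit-provided QC plasma, and internal standards in every well. A plate is
accepted only when every rule below is satisfied:

* calibrators: a standard is valid when its computed concentration is
  within +/-30% of nominal; an analyte needs >= 75% valid standards;
* kit QCs: an injection is valid within +/-45% of nominal; an analyte
  needs >= 67% valid overall and >= 50% valid at every level;
* blank signals must stay below their kit-defined ceilings, internal
  standard intensities inside their kit-defined bounds (both are
  configuration — the manufacturer does not publish the values).

Tolerance comparisons are inclusive, with a one-part-in-1e9 relative guard
so that a measurement at exactly the printed tolerance (e.g. 130 against a
target of 100) is not rejected by floating-point round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

_REL_GUARD = 1e-9


@dataclass
class ValidationRule:
    calibrator_tolerance: float = 0.30
    calibrator_min_valid: float = 0.75
    qc_tolerance: float = 0.45
    # "67%" of QC injections means two-thirds: with the usual 3x3 QC layout
    # 6 of 9 valid injections must pass, and 6/9 < 0.67 as a bare float.
    qc_min_valid_overall: float = 2.0 / 3.0
    qc_min_valid_per_level: float = 0.50
    blank_max: dict = field(default_factory=dict)  # name -> signal ceiling
    istd_bounds: dict = field(default_factory=dict)  # name -> (min, max)

    def __post_init__(self):
        for t in (self.calibrator_tolerance, self.qc_tolerance):
            if not 0 < t < 1:
                raise ValueError("tolerances must lie in (0, 1)")
        for f in (self.calibrator_min_valid, self.qc_min_valid_overall, self.qc_min_valid_per_level):
            if not 0 < f <= 1:
                raise ValueError("min-valid fractions must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "ValidationRule":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "istd_bounds" in raw:
            raw["istd_bounds"] = {k: tuple(v) for k, v in raw["istd_bounds"].items()}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "calibrator_tolerance": self.calibrator_tolerance,
            "calibrator_min_valid": self.calibrator_min_valid,
            "qc_tolerance": self.qc_tolerance,
            "qc_min_valid_overall": self.qc_min_valid_overall,
            "qc_min_valid_per_level": self.qc_min_valid_per_level,
            "blank_max": dict(self.blank_max),
            "istd_bounds": {k: list(v) for k, v in self.istd_bounds.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class PlateVerdict:
    plate_id: str
    failures: list = field(default_factory=list)  # (rule, target, observed, bound)

    @property
    def passed(self) -> bool:
        return not self.failures


def _within(measured: np.ndarray, target: np.ndarray, tol: float) -> np.ndarray:
    ratio_err = np.abs(measured / target - 1.0)
    return ratio_err <= tol * (1.0 + _REL_GUARD)


# --------------------------------------------------------------------------

def compute_plate_lod(zero_values: dict) -> dict:
    """Plate-specific LOD per analyte: 3x the mean zero-sample level.

    A zero mean yields LOD 0 — the analyte is then never censored.
    Negative zero-well levels are a data error and rejected.
    """
    out = {}
    for analyte, vals in zero_values.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"no zero-well values for {analyte}")
        if (arr < 0).any():
            raise ValueError(f"negative zero-well value for {analyte}")
        out[analyte] = 3.0 * float(arr.mean())
    return out


def validate_calibrators(df: pd.DataFrame, rule: ValidationRule) -> pd.DataFrame:
    """Per-analyte calibrator acceptance.

    ``df`` needs columns analyte_id, level, measured, target. A standard is
    valid within +/-calibrator_tolerance of its target; the analyte passes
    when the valid fraction is at least calibrator_min_valid.
    """
    if (df["target"] <= 0).any():
        bad = df.loc[df["target"] <= 0, "analyte_id"].iloc[0]
        raise ValueError(f"non-positive calibrator target for {bad}")
    valid = _within(df["measured"].to_numpy(float), df["target"].to_numpy(float), rule.calibrator_tolerance)
    work = df.assign(valid=valid)
    g = work.groupby("analyte_id")["valid"]
    res = pd.DataFrame({"n_valid": g.sum().astype(int), "n_total": g.count()})
    res["frac_valid"] = res["n_valid"] / res["n_total"]
    res["passed"] = res["frac_valid"] >= rule.calibrator_min_valid * (1 - _REL_GUARD)
    return res


def validate_kit_qcs(df: pd.DataFrame, rule: ValidationRule) -> pd.DataFrame:
    """Per-analyte kit-QC acceptance over the three QC levels.

    ``df`` needs columns analyte_id, qc_level (1..3), measured, target.
    Passing requires >= qc_min_valid_overall of all injections valid AND
    >= qc_min_valid_per_level at every level.
    """
    levels = set(df["qc_level"].unique())
    if levels != {1, 2, 3}:
        raise ValueError(f"expected QC levels {{1, 2, 3}}, got {sorted(levels)}")
    valid = _within(df["measured"].to_numpy(float), df["target"].to_numpy(float), rule.qc_tolerance)
    work = df.assign(valid=valid)
    overall = work.groupby("analyte_id")["valid"].mean()
    per_level = work.groupby(["analyte_id", "qc_level"])["valid"].mean().unstack()
    if per_level.isna().any().any():
        missing = per_level.index[per_level.isna().any(axis=1)][0]
        raise ValueError(f"analyte {missing} missing a QC level")
    res = pd.DataFrame(
        {
            "frac_valid_overall": overall,
            "min_frac_per_level": per_level.min(axis=1),
        }
    )
    res["passed"] = (res["frac_valid_overall"] >= rule.qc_min_valid_overall * (1 - _REL_GUARD)) & (
        res["min_frac_per_level"] >= rule.qc_min_valid_per_level * (1 - _REL_GUARD)
    )
    return res


def validate_blank_and_istd(
    blank_signals: dict, istd_intensities: dict, rule: ValidationRule
) -> list:
    """Violation list for blank ceilings and internal-standard windows."""
    failures = []
    for name, signal in blank_signals.items():
        if name not in rule.blank_max:
            raise ValueError(f"no blank ceiling configured for {name!r}")
        ceiling = rule.blank_max[name]
        if signal >= ceiling:
            failures.append(("blank_max", name, float(signal), float(ceiling)))
    for name, intensity in istd_intensities.items():
        if name not in rule.istd_bounds:
            raise ValueError(f"no intensity bounds configured for internal standard {name!r}")
        lo, hi = rule.istd_bounds[name]
        if not lo <= intensity <= hi:
            failures.append(("istd_bounds", name, float(intensity), (float(lo), float(hi))))
    return failures


def validate_plate(
    plate_id: str,
    calibrators: pd.DataFrame,
    kit_qcs: pd.DataFrame,
    blank_signals: dict,
    istd_intensities: dict,
    rule: ValidationRule,
) -> PlateVerdict:
    """Combine every technical-validation rule into one plate verdict."""
    verdict = PlateVerdict(plate_id)
    cal = validate_calibrators(calibrators, rule)
    for analyte, row in cal[~cal["passed"]].iterrows():
        verdict.failures.append(
            ("calibrator_min_valid", analyte, float(row["frac_valid"]), rule.calibrator_min_valid)
        )
    qc = validate_kit_qcs(kit_qcs, rule)
    for analyte, row in qc[~qc["passed"]].iterrows():
        verdict.failures.append(
            (
                "qc_min_valid",
                analyte,
                (float(row["frac_valid_overall"]), float(row["min_frac_per_level"])),
                (rule.qc_min_valid_overall, rule.qc_min_valid_per_level),
            )
        )
    verdict.failures.extend(validate_blank_and_istd(blank_signals, istd_intensities, rule))
    return verdict
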