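"""SPQC scaling, duplicate CV/ICC, %<LOD, verdicts, PCA outliers, log2 rule."""

import warnings

import numpy as np
import pandas as pd
import pytest

from p180 import (
    analyte_verdicts,
    apply_scaling,
    compute_scaling_factors,
    duplicate_cv,
    duplicate_icc,
    icc_oneway,
    normality_decision,
    pca_outliers,
    pct_below_lod,
)
from p180.qcstats import VERDICT_DROP_CV, VERDICT_DROP_ICC, VERDICT_DROP_LOD, VERDICT_RETAIN

from conftest import make_matrix


# --------------------------------------------------------------------------
# SPQC scaling

def _spqc_matrix(plate_values):
    """plate -> list of SPQC values for a single analyte 'a'."""
    samples, vals = [], []
    for plate, values in plate_values.items():
        for i, v in enumerate(values):
            samples.append({"sample_id": f"{plate}_spqc{i}", "plate_id": plate, "role": "SPQC"})
            vals.append(v)
    return make_matrix({"a": vals}, samples)


class TestScalingFactors:
    def test_single_plate_gives_unit_factors(self):
        m = _spqc_matrix({"P01": [10.0, 12.0]})
        f = compute_scaling_factors(m)
        assert f.factor("P01", "a") == pytest.approx(1.0)

    def test_hand_worked_two_plates(self):
        # plate means 11 and 19, global mean 15 -> 15/11 and 15/19
        m = _spqc_matrix({"P01": [10.0, 12.0], "P02": [18.0, 20.0]})
        f = compute_scaling_factors(m)
        assert f.factor("P01", "a") == pytest.approx(15.0 / 11.0)
        assert f.factor("P02", "a") == pytest.approx(15.0 / 19.0)

    def test_noiseless_plate_effects_recovered_exactly(self):
        """With noiseless SPQC the factors invert the planted batch effects."""
        rng = np.random.default_rng(3)
        b = np.exp(0.2 * rng.standard_normal(5))
        truth = 7.3
        m = _spqc_matrix({f"P{p:02d}": [truth * b[p]] * 2 for p in range(5)})
        f = compute_scaling_factors(m)
        expected = b.mean() / b
        for p in range(5):
            assert f.factor(f"P{p:02d}", "a") == pytest.approx(expected[p], rel=1e-12)
        # applying the factors is the exact inverse of the batch effect
        scaled = apply_scaling(m, f)
        spqc_means = scaled.values.groupby(scaled.samples["plate_id"])["a"].mean()
        assert spqc_means.std() / spqc_means.mean() < 1e-12

    def test_undefined_plate_mean_warns_and_uses_unit_factor(self):
        m = _spqc_matrix({"P01": [10.0, 10.0], "P02": [np.nan, np.nan]})
        with pytest.warns(UserWarning):
            f = compute_scaling_factors(m)
        assert f.factor("P02", "a") == 1.0


class TestApplyScaling:
    def test_unit_factor_is_identity_and_flags_survive(self):
        m = make_matrix(
            {"a": [2.0, np.nan]},
            [{"sample_id": "s1"}, {"sample_id": "s2"}],
            status={"a": ["valid", "below_LOD"]},
        )
        spqc = _spqc_matrix({"P01": [5.0, 5.0]})
        f = compute_scaling_factors(spqc)
        out = apply_scaling(m, f)
        assert out.values.loc["s1", "a"] == 2.0
        assert out.status.loc["s2", "a"] == "below_LOD"
        assert np.isnan(out.values.loc["s2", "a"])

    def test_simple_multiplication(self):
        m = make_matrix({"a": [2.0]}, [{"sample_id": "s1", "plate_id": "P01"}])
        f = compute_scaling_factors(_spqc_matrix({"P01": [10.0]}))
        f.table.loc["P01", "a"] = 1.5
        assert apply_scaling(m, f).values.loc["s1", "a"] == pytest.approx(3.0)

    def test_missing_factor_rejected(self):
        m = make_matrix({"a": [2.0]}, [{"sample_id": "s1", "plate_id": "P99"}])
        f = compute_scaling_factors(_spqc_matrix({"P01": [10.0]}))
        with pytest.raises(ValueError):
            apply_scaling(m, f)

    def test_post_scaling_spqc_means_equalized(self):
        rng = np.random.default_rng(11)
        plates = {f"P{p}": list(10.0 * np.exp(0.1 * rng.standard_normal(2))) for p in range(4)}
        m = _spqc_matrix(plates)
        out = apply_scaling(m, compute_scaling_factors(m))
        means = out.values.groupby(out.samples["plate_id"])["a"].mean()
        assert np.ptp(means.to_numpy()) / means.mean() < 1e-9


# --------------------------------------------------------------------------
# duplicate CV

def _pairs_matrix(pairs, analyte="a"):
    samples, vals = [], []
    for g, (x, y) in enumerate(pairs):
        for k, v in enumerate((x, y)):
            samples.append(
                {"sample_id": f"d{g}_{k}", "subject_id": f"subj{g}",
                 "duplicate_group": f"G{g}", "role": "study"}
            )
            vals.append(v)
    return make_matrix({analyte: vals}, samples)


class TestDuplicateCv:
    def test_hand_worked_mean_of_pair_cvs(self):
        # per-pair CVs 12.856% and 0% -> mean 6.428%
        m = _pairs_matrix([(10.0, 12.0), (20.0, 20.0)])
        assert duplicate_cv(m)["a"] == pytest.approx(6.428, abs=1e-3)

    def test_identical_pairs_give_zero(self):
        m = _pairs_matrix([(5.0, 5.0), (9.0, 9.0)])
        assert duplicate_cv(m)["a"] == 0.0

    def test_missing_member_skips_pair(self):
        m = _pairs_matrix([(10.0, 12.0), (np.nan, 20.0)])
        assert duplicate_cv(m)["a"] == pytest.approx(12.856, abs=1e-3)

    def test_no_usable_pairs_is_undefined(self):
        m = _pairs_matrix([(np.nan, 1.0)])
        assert np.isnan(duplicate_cv(m)["a"])

    def test_sampling_expectation_matches_small_sample_theory(self):
        """The mean-of-pair-CVs estimator has expectation sqrt(2/pi)*cv for
        Gaussian technical noise (the n=2 sd bias); check by Monte Carlo."""
        rng = np.random.default_rng(5)
        cv = 0.05
        n_pairs, n_rep = 20, 1000
        x = 10.0 * (1 + cv * rng.standard_normal((n_rep, n_pairs)))
        y = 10.0 * (1 + cv * rng.standard_normal((n_rep, n_pairs)))
        per_pair = np.abs(x - y) / np.sqrt(2) / ((x + y) / 2) * 100
        est = per_pair.mean(axis=1).mean()
        assert est == pytest.approx(np.sqrt(2 / np.pi) * 5.0, abs=0.15)
        # and the in-package estimator agrees with this oracle on one cohort
        m = _pairs_matrix(list(zip(x[0], y[0])))
        assert duplicate_cv(m)["a"] == pytest.approx(per_pair[0].mean(), rel=1e-12)


# --------------------------------------------------------------------------
# duplicate ICC

def brute_force_icc(pairs):
    """Plain-Python one-way ANOVA ICC(1,1): independent oracle."""
    n = len(pairs)
    k = 2
    grand = sum(x + y for x, y in pairs) / (n * k)
    means = [(x + y) / 2 for x, y in pairs]
    ssb = k * sum((m - grand) ** 2 for m in means)
    ssw = sum((x - m) ** 2 + (y - m) ** 2 for (x, y), m in zip(pairs, means))
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


class TestDuplicateIcc:
    def test_hand_worked_example(self):
        # MSB 213.5, MSW 8.5/3 -> 0.9738
        pairs = [(10.0, 12.0), (20.0, 18.0), (30.0, 33.0)]
        assert icc_oneway(*zip(*pairs)) == pytest.approx(0.9738, abs=1e-4)
        m = _pairs_matrix(pairs)
        assert duplicate_icc(m)["a"] == pytest.approx(0.9738, abs=1e-4)

    def test_equal_members_distinct_subjects_give_one(self):
        m = _pairs_matrix([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        assert duplicate_icc(m)["a"] == pytest.approx(1.0)

    def test_fewer_than_three_pairs_undefined(self):
        m = _pairs_matrix([(1.0, 2.0), (2.0, 3.0)])
        assert np.isnan(duplicate_icc(m)["a"])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            a = rng.normal(10, 3, n)
            b = a + rng.normal(0, rng.uniform(0.1, 5), n)
            pairs = list(zip(a, b))
            assert icc_oneway(a, b) == pytest.approx(brute_force_icc(pairs), abs=1e-12)

    def test_matches_pingouin_oneway_icc(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(23)
        a = rng.normal(10, 3, 12)
        b = a + rng.normal(0, 1, 12)
        long = pd.DataFrame(
            {"targets": list(range(12)) * 2, "raters": ["r1"] * 12 + ["r2"] * 12,
             "ratings": np.concatenate([a, b])}
        )
        ref = pingouin.intraclass_corr(long, targets="targets", raters="raters",
                                       ratings="ratings")
        icc1 = float(ref.loc[ref["Type"].isin(["ICC1", "ICC(1,1)"]), "ICC"].iloc[0])
        assert icc_oneway(a, b) == pytest.approx(icc1, abs=1e-9)

    def test_no_subject_effect_centers_on_zero(self):
        rng = np.random.default_rng(29)
        est = [
            icc_oneway(rng.normal(0, 1, 20), rng.normal(0, 1, 20)) for _ in range(1000)
        ]
        assert abs(np.mean(est)) < 0.03


# --------------------------------------------------------------------------
# %<LOD and verdicts

class TestPctBelowLod:
    @pytest.mark.parametrize("n_flagged, n_total, expected", [(4, 10, 40.0), (0, 10, 0.0), (41, 100, 41.0)])
    def test_study_fraction(self, n_flagged, n_total, expected):
        vals = [np.nan] * n_flagged + [1.0] * (n_total - n_flagged)
        status = ["below_LOD"] * n_flagged + ["valid"] * (n_total - n_flagged)
        samples = [{"sample_id": f"s{i}"} for i in range(n_total)]
        m = make_matrix({"a": vals}, samples, status={"a": status})
        assert pct_below_lod(m)["a"] == pytest.approx(expected)

    def test_qc_wells_excluded_from_both_counts(self):
        samples = [{"sample_id": "s1"}, {"sample_id": "q1", "role": "SPQC"}]
        m = make_matrix(
            {"a": [1.0, np.nan]}, samples, status={"a": ["valid", "below_LOD"]}
        )
        assert pct_below_lod(m)["a"] == 0.0


class TestVerdicts:
    def _one(self, cv, icc, pct, **kw):
        idx = pd.Index(["a"], name="analyte_id")
        out = analyte_verdicts(
            pd.Series([cv], index=idx), pd.Series([icc], index=idx),
            pd.Series([pct], index=idx), **kw
        )
        return out.loc["a", "verdict"]

    def test_printed_boundary_examples(self):
        # low-ICC analyte with fine CV and missingness -> excluded on ICC
        assert self._one(5.4, 0.09, 17.2) == VERDICT_DROP_ICC
        # ICC exactly at the threshold -> still excluded (strict >)
        assert self._one(8.1, 0.65, 0.0) == VERDICT_DROP_ICC

    def test_retention_and_boundaries(self):
        assert self._one(5.0, 0.9, 10.0) == VERDICT_RETAIN
        assert self._one(5.0, 0.9, 40.0) == VERDICT_RETAIN  # rule is strict > 40
        assert self._one(5.0, 0.9, 41.0) == VERDICT_DROP_LOD
        assert self._one(20.0, 0.9, 0.0) == VERDICT_DROP_CV  # strict < 20 to retain

    def test_first_failing_rule_order(self):
        assert self._one(35.0, 0.1, 80.0) == VERDICT_DROP_CV

    def test_undefined_metric_names_itself(self):
        assert self._one(np.nan, 0.9, 0.0) == VERDICT_DROP_CV
        assert self._one(5.0, np.nan, 0.0) == VERDICT_DROP_ICC

    def test_monotone_in_each_metric(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            cv, icc, pct = rng.uniform(0, 40), rng.uniform(-0.2, 1), rng.uniform(0, 100)
            if self._one(cv, icc, pct) != VERDICT_RETAIN:
                continue
            # improving any metric never turns retain into drop
            assert self._one(cv * 0.5, icc, pct) == VERDICT_RETAIN
            assert self._one(cv, min(1.0, icc + 0.1), pct) == VERDICT_RETAIN
            assert self._one(cv, icc, pct * 0.5) == VERDICT_RETAIN


# --------------------------------------------------------------------------
# PCA outliers

class TestPcaOutliers:
    def test_identical_subjects_no_flags(self):
        df = pd.DataFrame(np.ones((10, 4)), columns=list("abcd"))
        with pytest.warns(UserWarning):
            rep = pca_outliers(df)
        assert rep.flagged == []
        assert (rep.distances == 0).all()

    def test_planted_extreme_subject_is_the_only_flag(self):
        rng = np.random.default_rng(37)
        x = rng.standard_normal((200, 5))
        x[123, 0] = 50.0
        df = pd.DataFrame(x, columns=list("abcde"), index=[f"s{i}" for i in range(200)])
        rep = pca_outliers(df)
        assert rep.flagged == ["s123"]
        assert rep.explained > 0.90

    def test_flags_invariant_to_column_order(self):
        rng = np.random.default_rng(41)
        x = rng.standard_normal((80, 6))
        x[7] += 40.0
        df = pd.DataFrame(x, columns=list("abcdef"))
        rep1 = pca_outliers(df)
        rep2 = pca_outliers(df[list("fedcba")])
        assert rep1.flagged == rep2.flagged
        assert np.allclose(np.sort(rep1.distances), np.sort(rep2.distances))

    def test_requires_complete_matrix(self):
        df = pd.DataFrame([[1.0, np.nan], [2.0, 3.0], [4.0, 5.0]])
        with pytest.raises(ValueError):
            pca_outliers(df)


# --------------------------------------------------------------------------
# normality / log2 decision

class TestNormalityDecision:
    def test_symmetric_sample_never_transformed(self):
        rng = np.random.default_rng(43)
        assert normality_decision(rng.standard_normal(500)) is False

    def test_strongly_lognormal_sample_transformed(self):
        rng = np.random.default_rng(47)
        assert normality_decision(rng.lognormal(0.0, 1.5, 500)) is True

    def test_left_skew_fails_sign_condition(self):
        rng = np.random.default_rng(53)
        assert normality_decision(-rng.lognormal(0.0, 1.5, 500)) is False

    def test_small_samples_warn_and_skip(self):
        with pytest.warns(UserWarning):
            assert normality_decision([1.0, 2.0, 3.0]) is False
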