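"""Offset and rescaling bias corrections and the covariate group test:
exact arithmetic examples, oracle equivalence, orthogonality, variance
ordering, and transfer to independent test sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from agedelta.adjust import (
    OffsetModel,
    apply_cole,
    apply_proposed,
    apply_scheme,
    fit_offset_model,
    le_group_test,
)
from agedelta.errors import (
    DegenerateDataError,
    InsufficientDataError,
    SchemeMismatchError,
    UnstableAdjustmentError,
)
from agedelta.synthetic import TRAINING_BIAS_PRESET, simulate_predictions

import oracles


def pred_frame(ages, predicted, groups=None, provenance="cv_out_of_fold"):
    ages = np.asarray(ages, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    return pd.DataFrame(
        {
            "subject_id": [f"S_{i:04d}" for i in range(len(ages))],
            "age": ages,
            "group": ["CN"] * len(ages) if groups is None else list(groups),
            "predicted_raw": predicted,
            "delta": predicted - ages,
            "provenance": provenance,
        }
    )


class TestFitOffsetModel:
    def test_exact_fit_on_reference_bias_line(self):
        """Deltas lying exactly on delta = -0.7*age + 50 are recovered
        without error."""
        ages = np.array([50.0, 60.0, 70.0, 80.0])
        deltas = -0.7 * ages + 50
        m = fit_offset_model(pred_frame(ages, ages + deltas), "proposed")
        assert m.slope == pytest.approx(-0.7, abs=1e-12)
        assert m.intercept == pytest.approx(50.0, abs=1e-10)
        assert m.n_train == 4
        assert m.fit_provenance == "cv_out_of_fold"

    def test_constant_deltas_give_zero_slope(self):
        ages = np.array([50.0, 60.0, 70.0, 80.0])
        m = fit_offset_model(pred_frame(ages, ages + 3.0), "proposed")
        assert m.slope == pytest.approx(0.0, abs=1e-12)
        assert m.intercept == pytest.approx(3.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            ages = rng.uniform(40, 95, size=50)
            predicted = rng.normal(70, 10, size=50)
            frame = pred_frame(ages, predicted)
            for scheme, col in (("proposed", "delta"), ("cole", "predicted_raw")):
                m = fit_offset_model(frame, scheme)
                slope, intercept = oracles.ols_line(frame["age"], frame[col])
                assert m.slope == pytest.approx(slope, abs=1e-10)
                assert m.intercept == pytest.approx(intercept, abs=1e-10)

    def test_constant_age_is_singular(self):
        frame = pred_frame([70.0, 70.0, 70.0], [65.0, 70.0, 75.0])
        with pytest.raises(DegenerateDataError):
            fit_offset_model(frame, "proposed")

    def test_unknown_scheme_rejected(self):
        frame = pred_frame([50.0, 60.0], [55.0, 61.0])
        with pytest.raises(SchemeMismatchError):
            fit_offset_model(frame, "ridge")

    def test_json_round_trip(self, tmp_path):
        frame = pred_frame([50.0, 60.0, 70.0], [60.0, 65.0, 70.0])
        m = fit_offset_model(frame, "cole")
        path = tmp_path / "offset.json"
        m.to_json(path)
        assert OffsetModel.from_json(path) == m
        assert OffsetModel.from_json(m.to_json()) == m


class TestApplyProposed:
    def test_hand_arithmetic_with_reference_coefficients(self):
        """Raw 70 at age 60 under slope -0.7 / intercept 50: the offset is
        -0.7*60 + 50 = 8, so the adjusted prediction is 62."""
        m = OffsetModel("proposed", -0.7, 50.0, 10, "cv_out_of_fold")
        out = apply_proposed(pred_frame([60.0, 60.0], [70.0, 80.0]), m)
        assert out["predicted_adjusted"].iloc[0] == pytest.approx(62.0)
        assert out["delta_adjusted"].iloc[0] == pytest.approx(2.0)

    def test_null_offset_is_identity(self):
        m = OffsetModel("proposed", 0.0, 0.0, 10, "cv_out_of_fold")
        frame = pred_frame([50.0, 60.0, 70.0], [55.0, 66.0, 77.0])
        out = apply_proposed(frame, m)
        np.testing.assert_allclose(out["predicted_adjusted"], frame["predicted_raw"])

    def test_offset_vanishes_at_the_bias_line_root(self):
        """At age intercept/(-slope) = 50/0.7 the offset crosses zero."""
        m = OffsetModel("proposed", -0.7, 50.0, 10, "cv_out_of_fold")
        out = apply_proposed(pred_frame([71.4286, 71.4286], [70.0, 75.0]), m)
        assert out["predicted_adjusted"].iloc[0] == pytest.approx(70.0, abs=1e-3)

    def test_scheme_mismatch_rejected(self):
        m = OffsetModel("cole", 0.5, 35.0, 10, "cv_out_of_fold")
        with pytest.raises(SchemeMismatchError):
            apply_proposed(pred_frame([50.0, 60.0], [55.0, 61.0]), m)


class TestApplyCole:
    def test_fixed_point_on_the_regression_line(self):
        m = OffsetModel("cole", 0.5, 35.0, 10, "cv_out_of_fold")
        out = apply_cole(pred_frame([70.0, 70.0], [70.0, 80.0]), m)
        assert out["predicted_adjusted"].iloc[0] == pytest.approx(70.0)
        assert out["predicted_adjusted"].iloc[1] == pytest.approx(90.0)

    def test_identity_calibration(self):
        m = OffsetModel("cole", 1.0, 0.0, 10, "cv_out_of_fold")
        frame = pred_frame([50.0, 60.0, 70.0], [52.0, 63.0, 74.0])
        out = apply_cole(frame, m)
        np.testing.assert_allclose(out["predicted_adjusted"], frame["predicted_raw"])

    def test_slope_below_floor_is_unstable(self):
        m = OffsetModel("cole", 0.01, 35.0, 10, "cv_out_of_fold")
        assert not m.usable_for_adjustment()
        with pytest.raises(UnstableAdjustmentError):
            apply_cole(pred_frame([50.0, 60.0], [55.0, 61.0]), m)

    def test_scheme_mismatch_rejected(self):
        m = OffsetModel("proposed", -0.7, 50.0, 10, "cv_out_of_fold")
        with pytest.raises(SchemeMismatchError):
            apply_cole(pred_frame([50.0, 60.0], [55.0, 61.0]), m)


def _simulated_training_frame(seed, n=400, noise=5.13):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(47, 94, size=n)
    preset = TRAINING_BIAS_PRESET if noise == 5.13 else TRAINING_BIAS_PRESET.__class__(
        attenuation=TRAINING_BIAS_PRESET.attenuation,
        pivot_age=TRAINING_BIAS_PRESET.pivot_age,
        pred_noise_sd=noise,
    )
    return simulate_predictions(ages, ["CN"] * n, preset, seed=seed + 1)


class TestInvariants:
    @pytest.mark.parametrize("scheme", ["proposed", "cole"])
    def test_orthogonality_on_fitting_set(self, scheme):
        """Adjusted delta is exactly uncorrelated with age when the model
        is fitted and applied on the same predictions (OLS residual
        orthogonality; the rescaled delta is residual/slope)."""
        frame = _simulated_training_frame(seed=3)
        m = fit_offset_model(frame, scheme)
        out = apply_scheme(frame, m, scheme)
        r = stats.pearsonr(out["delta_adjusted"], out["age"]).statistic
        assert abs(r) < 1e-8

    def test_r2_invariance_under_rescaling(self):
        """The rescaling adjustment is affine, so squared Pearson
        correlation between predicted and age is unchanged."""
        frame = _simulated_training_frame(seed=5)
        m = fit_offset_model(frame, "cole")
        out = apply_cole(frame, m)
        r2_before = stats.pearsonr(frame["age"], frame["predicted_raw"]).statistic ** 2
        r2_after = stats.pearsonr(out["age"], out["predicted_adjusted"]).statistic ** 2
        assert r2_after == pytest.approx(r2_before, abs=1e-10)

    def test_variance_ordering_between_schemes(self):
        """Var(offset-adjusted) <= Var(raw) always, and the rescaling
        scheme inflates the offset-adjusted variance by 1/slope^2."""
        frame = _simulated_training_frame(seed=7)
        mp = fit_offset_model(frame, "proposed")
        mc = fit_offset_model(frame, "cole")
        dp = apply_proposed(frame, mp)["delta_adjusted"]
        dc = apply_cole(frame, mc)["delta_adjusted"]
        assert dp.var() <= frame["delta"].var()
        assert abs(mc.slope) < 1.0
        assert dc.var() >= dp.var()
        assert dc.var() == pytest.approx(dp.var() / mc.slope**2, rel=1e-9)

    @pytest.mark.parametrize("scheme", ["proposed", "cole"])
    def test_transfer_to_exchangeable_test_set(self, scheme):
        """A training-fitted model drives the *test* delta-age correlation
        to ~0 within sampling error, averaged over replicates."""
        rs = []
        for seed in range(100):
            train = _simulated_training_frame(seed=1000 + seed, n=675)
            test = _simulated_training_frame(seed=5000 + seed, n=200)
            m = fit_offset_model(train, scheme)
            out = apply_scheme(test, m, scheme)
            rs.append(stats.pearsonr(out["delta_adjusted"], out["age"]).statistic)
        assert abs(np.mean(rs)) < 0.02

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_adjusted_delta_definition_property(self, seed):
        """delta_adjusted = predicted_adjusted - age at machine precision
        for any simulated input, both schemes."""
        frame = _simulated_training_frame(seed=seed, n=60)
        for scheme in ("proposed", "cole"):
            m = fit_offset_model(frame, scheme)
            out = apply_scheme(frame, m, scheme)
            np.testing.assert_array_equal(
                out["delta_adjusted"].to_numpy(),
                (out["predicted_adjusted"] - out["age"]).to_numpy(),
            )


class TestLeGroupTest:
    def test_two_identical_groups_give_null_f(self):
        rng = np.random.default_rng(2)
        deltas = rng.normal(0, 3, size=40)
        ages = rng.uniform(50, 90, size=40)
        res = le_group_test(
            np.concatenate([deltas, deltas]),
            np.concatenate([ages, ages]),
            ["A"] * 40 + ["B"] * 40,
        )
        assert res.f_stat == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-8)

    def test_matches_ancova_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = 60
            ages = rng.uniform(47, 94, size=n)
            groups = rng.choice(["CN", "MCI", "AD"], size=n)
            deltas = -0.5 * ages + rng.normal(0, 3, size=n)
            res = le_group_test(deltas, ages, groups)
            f, df_b, df_w = oracles.ancova_group_f(deltas, ages, groups)
            assert res.f_stat == pytest.approx(f, abs=1e-8)
            assert (res.df_between, res.df_within) == (df_b, df_w)

    def test_detects_group_offsets_despite_strong_age_bias(self):
        """Injected accelerations {0, +2, +4} with a slope -0.7 age bias:
        the covariate model recovers a significant group effect in nearly
        every replicate."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            sizes = {"CN": 75, "MCI": 561, "AD": 362}
            offsets = {"CN": 0.0, "MCI": 2.0, "AD": 4.0}
            ages = rng.uniform(47, 94, size=sum(sizes.values()))
            groups = np.repeat(list(sizes), list(sizes.values()))
            off = np.array([offsets[g] for g in groups])
            deltas = -0.7 * ages + 50 + off + rng.normal(0, 3.44, size=len(ages))
            res = le_group_test(deltas, ages, groups)
            hits += res.p_value < 0.001
        assert hits >= 48

    def test_type_one_error_calibrated_at_the_null(self):
        """All groups from one distribution: ~5% of replicates reject at
        alpha = 0.05."""
        rejections = 0
        n_rep = 400
        for seed in range(n_rep):
            rng = np.random.default_rng(50_000 + seed)
            ages = rng.uniform(47, 94, size=90)
            deltas = rng.normal(0, 3, size=90)
            groups = ["CN"] * 30 + ["MCI"] * 30 + ["AD"] * 30
            res = le_group_test(deltas, ages, groups)
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            le_group_test([1.0, 2.0, 3.0], [60.0, 70.0, 80.0], ["A", "A", "B"])
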