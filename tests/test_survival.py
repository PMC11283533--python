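"""Parametric fitting, evaluation, and transition-probability conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cllcea.survival import (
    InsufficientDataError,
    KMCurvePoints,
    ParametricSurvivalModel,
    event_prob_schedule,
    fit_parametric,
    linearized_r_squared,
    per_cycle_event_prob,
    pfs_os_decompose,
    survival_at,
)
from cllcea.synthetic import TrialSimSpec, digitize, km_estimate, simulate_subjects


def weibull_points(shape, scale, times):
    times = np.asarray(times, float)
    return KMCurvePoints(times, np.exp(-((times / scale) ** shape)))


class TestKMCurvePoints:
    @pytest.mark.parametrize(
        "time,survival,message",
        [
            ([1, 2, 2], [0.9, 0.8, 0.7], "strictly increasing"),
            ([1, 2, 3], [0.8, 0.9, 0.7], "non-increasing"),
            ([1, 2], [1.2, 0.9], "in \\[0, 1\\]"),
            ([-1, 2], [0.9, 0.8], "non-negative"),
        ],
    )
    def test_invalid_curves_rejected(self, time, survival, message):
        with pytest.raises(ValueError, match=message):
            KMCurvePoints(time, survival)

    def test_csv_round_trip(self, tmp_path):
        curve = weibull_points(1.5, 24.0, np.arange(1, 20))
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = KMCurvePoints.from_csv(path)
        np.testing.assert_allclose(back.time, curve.time)
        np.testing.assert_allclose(back.survival, curve.survival)


class TestFitParametric:
    def test_noise_free_weibull_recovered_exactly(self):
        points = weibull_points(1.5, 24.0, np.arange(1, 61))
        model = fit_parametric(points, family="weibull")
        assert model.shape == pytest.approx(1.5, rel=1e-6)
        assert model.scale == pytest.approx(24.0, rel=1e-6)
        assert linearized_r_squared(points, model) == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_exponential_recovered(self):
        times = np.arange(1, 61, dtype=float)
        points = KMCurvePoints(times, np.exp(-0.05 * times))
        model = fit_parametric(points, family="exponential")
        assert model.shape == 1.0
        assert model.scale == pytest.approx(20.0, rel=1e-9)

    def test_noisy_digitized_fit_agrees_with_grid_search_oracle(self):
        """Fit on a digitized synthetic trial lands near the SSE grid minimizer.

        The oracle minimizes sum-of-squared survival error over a (shape,
        scale) grid — a different criterion from the complementary log-log
        OLS, so the band (0.55 shape, 3.0 scale) reflects the measured
        sampling-scale divergence of the two criteria at n=200.
        """
        records = simulate_subjects(
            TrialSimSpec("pfs", 1.3, 30.0, 200, censor_rate=0.005, admin_censor_time=48.0, seed=42)
        )
        km = km_estimate(records)
        grid = np.arange(1.0, np.floor(km.time[-1]) + 1)
        dig = digitize(km, grid, noise_sd=0.01, seed=42)
        model = fit_parametric(dig)

        shapes = np.arange(0.8, 2.0001, 0.01)
        scales = np.arange(20.0, 40.0001, 0.1)
        K, L = np.meshgrid(shapes, scales, indexing="ij")
        surv = np.exp(-((dig.time[None, None, :] / L[:, :, None]) ** K[:, :, None]))
        sse = ((surv - dig.survival[None, None, :]) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert abs(model.shape - shapes[i]) <= 0.55
        assert abs(model.scale - scales[j]) <= 3.0

    def test_too_few_usable_points_rejected(self):
        points = KMCurvePoints([0.0, 1.0, 2.0, 3.0], [1.0, 1.0, 0.5, 0.0])
        with pytest.raises(InsufficientDataError, match="insufficient data"):
            fit_parametric(points)

    def test_boundary_survival_points_dropped_with_warning(self, caplog):
        times = np.arange(0, 20, dtype=float)
        surv = np.exp(-((times / 8.0) ** 1.2))
        surv[0] = 1.0
        points = KMCurvePoints(times, surv)
        with caplog.at_level("WARNING", logger="cllcea.survival"):
            model = fit_parametric(points)
        assert "dropping 1 point" in caplog.text
        assert model.shape == pytest.approx(1.2, rel=1e-6)

    def test_covariance_is_symmetric_psd_and_serializes(self, tmp_path):
        rng = np.random.default_rng(5)
        times = np.arange(1, 40, dtype=float)
        surv = np.exp(-((times / 20.0) ** 1.4))
        noisy = np.minimum.accumulate(np.clip(surv + rng.normal(0, 0.01, times.size), 0, 1))
        model = fit_parametric(KMCurvePoints(times, noisy))
        cov = model.coef_covariance
        assert cov.shape == (2, 2)
        assert np.all(np.linalg.eigvalsh(cov) >= -1e-12)
        path = tmp_path / "model.json"
        model.save(path)
        back = ParametricSurvivalModel.load(path)
        assert back.shape == model.shape and back.scale == model.scale
        np.testing.assert_allclose(back.coef_covariance, cov)


class TestSurvivalAt:
    @pytest.mark.parametrize(
        "shape,scale,t,expected",
        [(1.0, 20.0, 0.0, 1.0), (1.0, 20.0, 20.0, np.exp(-1)), (2.0, 10.0, 10.0, np.exp(-1))],
    )
    def test_closed_forms(self, shape, scale, t, expected):
        model = ParametricSurvivalModel("weibull", shape, scale)
        assert survival_at(model, t) == pytest.approx(expected, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            survival_at(ParametricSurvivalModel("weibull", 1.2, 10.0), -1.0)

    @settings(deadline=None, max_examples=50)
    @given(
        shape=st.floats(0.3, 4.0),
        scale=st.floats(1.0, 200.0),
    )
    def test_survival_is_a_valid_nonincreasing_curve(self, shape, scale):
        model = ParametricSurvivalModel("weibull", shape, scale)
        t = np.linspace(0, 300, 400)
        s = model.survival(t)
        assert s[0] == 1.0
        assert np.all((s >= 0) & (s <= 1))
        assert np.all(np.diff(s) <= 1e-15)


class TestPerCycleEventProb:
    def test_exponential_is_memoryless(self):
        model = ParametricSurvivalModel("exponential", 1.0, 20.0)  # rate 0.05/month
        probs = [per_cycle_event_prob(model, i) for i in (0, 5, 50, 119)]
        assert np.allclose(probs, 1 - np.exp(-0.05), rtol=1e-12)

    def test_increasing_hazard_gives_increasing_schedule(self):
        model = ParametricSurvivalModel("weibull", 1.5, 30.0)
        p = event_prob_schedule(model, 120)
        assert np.all(np.diff(p) > 0)

    def test_schedule_matches_direct_evaluation_oracle(self):
        model = ParametricSurvivalModel("weibull", 1.3, 30.0)
        p = event_prob_schedule(model, 120)
        grid = np.arange(121.0)
        surv = np.exp(-((grid / 30.0) ** 1.3))  # direct formula, no library call
        np.testing.assert_allclose(p, 1.0 - surv[1:] / surv[:-1], atol=1e-12)

    def test_cumulative_product_identity(self):
        model = ParametricSurvivalModel("weibull", 1.3, 30.0)
        p = event_prob_schedule(model, 120)
        cumulative = np.cumprod(1.0 - p)
        expected = model.survival(np.arange(1.0, 121.0))
        np.testing.assert_allclose(cumulative, expected, atol=1e-9)

    def test_exhausted_curve_returns_certain_event(self):
        model = ParametricSurvivalModel("weibull", 4.0, 1.0)
        assert per_cycle_event_prob(model, 700) == 1.0


class TestPfsOsDecompose:
    def test_identical_models_give_zero_progression(self):
        m = ParametricSurvivalModel("weibull", 1.3, 25.0)
        for i in (0, 10, 60):
            p_prog, p_death = pfs_os_decompose(m, m, i)
            assert p_prog == 0.0
            assert p_death == per_cycle_event_prob(m, i)

    def test_negligible_death_hazard_leaves_pfs_probability(self):
        pfs = ParametricSurvivalModel("weibull", 1.3, 25.0)
        os_ = ParametricSurvivalModel("exponential", 1.0, 1e12)
        p_prog, p_death = pfs_os_decompose(pfs, os_, 5)
        assert p_death == pytest.approx(0.0, abs=1e-10)
        assert p_prog == pytest.approx(per_cycle_event_prob(pfs, 5), abs=1e-10)

    def test_exponential_closed_form(self):
        pfs = ParametricSurvivalModel("exponential", 1.0, 1 / 0.08)
        os_ = ParametricSurvivalModel("exponential", 1.0, 1 / 0.02)
        p_prog, p_death = pfs_os_decompose(pfs, os_, 7)
        assert p_death == pytest.approx(1 - np.exp(-0.02), rel=1e-9)
        assert p_prog == pytest.approx((1 - np.exp(-0.08)) - (1 - np.exp(-0.02)), rel=1e-9)
        assert p_prog + p_death <= 1.0
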