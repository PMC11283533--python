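"""Parameter sampling, PSA execution, and summary statistics."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from cllcea.markov import ModelConfig
from cllcea.model import run_deterministic
from cllcea.psa import (
    ParameterDistributionSpec,
    PSAConfig,
    PSASampleSet,
    beta_moment_match,
    build_distribution_specs,
    run_psa,
    sample_parameters,
    summarize,
)
from cllcea.survival import ParametricSurvivalModel


def strip_variability(inputs):
    """All-zero-variability copy of the model inputs (degenerate PSA)."""
    models = {
        k: ParametricSurvivalModel(m.family, m.shape, m.scale, None)
        for k, m in inputs.survival_models.items()
    }
    utilities = {k: replace(u, sd=0.0) for k, u in inputs.utilities.items()}
    return replace(
        inputs,
        survival_models=models,
        utilities=utilities,
        cost_variability=0.0,
        assay=replace(inputs.assay, cost_variability=0.0),
    )


class TestBetaMomentMatch:
    def test_matches_independent_moment_equation_solution(self):
        """First-line utility 0.78 (SD 0.14): solve the moment equations
        directly and compare."""
        mean, sd = 0.78, 0.14
        nu = mean * (1 - mean) / sd**2 - 1  # independent arithmetic
        alpha_expected, beta_expected = mean * nu, (1 - mean) * nu
        alpha, beta = beta_moment_match(mean, sd)
        assert alpha == pytest.approx(alpha_expected, rel=1e-12)
        assert beta == pytest.approx(beta_expected, rel=1e-12)
        assert alpha == pytest.approx(6.05, abs=0.01)
        assert beta == pytest.approx(1.71, abs=0.01)

    def test_large_sample_reproduces_moments(self):
        alpha, beta = beta_moment_match(0.78, 0.14)
        draws = np.random.default_rng(0).beta(alpha, beta, size=1_000_000)
        assert draws.mean() == pytest.approx(0.78, rel=0.005)
        assert draws.std() == pytest.approx(0.14, rel=0.005)
        assert np.all((draws >= 0) & (draws <= 1))

    def test_infeasible_moments_rejected_with_utility_named(self, bundle):
        inputs = replace(
            bundle.inputs,
            utilities={**bundle.inputs.utilities, "ae_minor": replace(
                bundle.inputs.utilities["ae_minor"], sd=0.6)},
        )
        with pytest.raises(ValueError, match="ae_minor"):
            build_distribution_specs(inputs)


class TestSampleParameters:
    COST_SPEC = [
        ParameterDistributionSpec(
            "cost_per_cycle.acalabrutinib", "uniform_pct", {"center": 7615.0, "pct": 0.25}
        )
    ]

    def test_cost_draws_respect_stated_bounds(self):
        draws = np.array(
            [
                sample_parameters(self.COST_SPEC, seed=1, draw_index=d)[
                    "cost_per_cycle.acalabrutinib"
                ]
                for d in range(5000)
            ]
        )
        assert draws.min() >= 5711.25
        assert draws.max() <= 9518.75
        # the draws actually explore the band
        assert draws.min() < 5711.25 + 100
        assert draws.max() > 9518.75 - 100

    def test_degenerate_spec_returns_constant(self):
        spec = [ParameterDistributionSpec("utilities.u", "constant", {"value": 0.78})]
        for d in range(5):
            assert sample_parameters(spec, seed=9, draw_index=d)["utilities.u"] == 0.78

    def test_reproducible_per_seed_draw_and_stream(self):
        a = sample_parameters(self.COST_SPEC, seed=4, draw_index=7)
        b = sample_parameters(self.COST_SPEC, seed=4, draw_index=7)
        c = sample_parameters(self.COST_SPEC, seed=4, draw_index=8)
        d = sample_parameters(self.COST_SPEC, seed=4, draw_index=7, stream=1)
        assert a == b
        assert a != c and a != d


class TestRunPsa:
    def test_degenerate_psa_equals_deterministic_run(self, bundle, model_config):
        inputs = strip_variability(bundle.inputs)
        det = run_deterministic(inputs, model_config)
        res = run_psa(inputs, PSAConfig(n_iterations=3, seed=5), model_config)
        s = res.samples
        assert np.allclose(s["cost_intervention"], det.cost_intervention, atol=1e-9)
        assert np.allclose(s["qaly_intervention"], det.qaly_intervention, atol=1e-9)
        assert np.allclose(s["cost_comparator"], det.cost_comparator, atol=1e-9)

    def test_common_draws_with_full_high_risk_isolate_assay_cost(self, bundle, model_config):
        inputs = replace(
            bundle.inputs, assay=replace(bundle.inputs.assay, prevalence_high_risk=1.0)
        )
        res = run_psa(inputs, PSAConfig(n_iterations=8, seed=2), model_config)
        np.testing.assert_allclose(res.delta_qalys, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.delta_cost, res.samples["assay_cost"], atol=1e-9)

    def test_fixed_seed_reproduces_samples_bitwise(self, bundle, model_config):
        cfg = PSAConfig(n_iterations=5, seed=11)
        a = run_psa(bundle.inputs, cfg, model_config)
        b = run_psa(bundle.inputs, cfg, model_config)
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_independent_mode_draws_comparator_separately(self, bundle, model_config):
        cfg = replace(PSAConfig(n_iterations=5, seed=11), common_draws_across_arms=False)
        res = run_psa(bundle.inputs, cfg, model_config)
        assert not np.allclose(res.samples["cost_comparator"], res.samples["cost_high"])

    def test_invalid_draws_are_resampled_and_counted(self, bundle, model_config):
        """Inflated survival-coefficient uncertainty plus high AE hazards
        makes some draws violate row-stochasticity; they must be resampled."""
        wide_cov = np.array([[0.25, 0.0], [0.0, 0.25]])
        models = {
            k: ParametricSurvivalModel(m.family, m.shape, m.scale, wide_cov)
            for k, m in bundle.inputs.survival_models.items()
        }
        lines = tuple(
            replace(l, p_minor_ae_per_cycle=0.3, p_major_ae_per_cycle=0.3)
            for l in bundle.inputs.high_lines
        )
        low = tuple(
            replace(l, p_minor_ae_per_cycle=0.3, p_major_ae_per_cycle=0.3)
            for l in bundle.inputs.low_lines
        )
        inputs = replace(bundle.inputs, survival_models=models, high_lines=lines, low_lines=low)
        res = run_psa(inputs, PSAConfig(n_iterations=20, seed=0), ModelConfig(n_cycles=24))
        assert len(res.samples) == 20
        assert res.n_rejected > 0


class TestSummarize:
    @staticmethod
    def sample_set(values, column="cost_intervention"):
        n = len(values)
        frame = pd.DataFrame(
            {
                "draw": np.arange(n),
                "cost_intervention": 0.0,
                "qaly_intervention": 0.0,
                "cost_comparator": 0.0,
                "qaly_comparator": 0.0,
            }
        )
        frame[column] = values
        return PSASampleSet(samples=frame, seed=0, common_draws_across_arms=True)

    def test_hand_computed_ci(self):
        table = summarize(self.sample_set([1.0, 2.0, 3.0]))
        row = table.loc["cost_intervention"]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)
        assert row["ci_low"] == pytest.approx(0.04, abs=1e-12)
        assert row["ci_high"] == pytest.approx(3.96, abs=1e-12)

    def test_constant_samples_collapse_ci_to_point(self):
        table = summarize(self.sample_set([5.0, 5.0, 5.0]))
        row = table.loc["cost_intervention"]
        assert row["ci_low"] == row["ci_high"] == 5.0

    def test_standard_normal_ci_endpoints(self):
        draws = np.random.default_rng(123).standard_normal(100_000)
        row = summarize(self.sample_set(draws)).loc["cost_intervention"]
        assert row["ci_low"] == pytest.approx(-1.96, abs=0.02)
        assert row["ci_high"] == pytest.approx(1.96, abs=0.02)
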