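"""Probabilistic sensitivity analysis.

Each PSA draw samples every uncertain parameter, rebuilds both arms, runs
the cohort model, and records one (cost, QALY) pair per arm.  Distribution
assignments follow standard practice for this model class:

* utilities — Beta distributions moment-matched to the published mean/SD,
* drug and adverse-event costs — uniform within +-25% of the list price
  (no published uncertainty); the assay cost within +-75% given its early
  stage of development,
* survival coefficients — multivariate normal on (ln shape, ln scale)
  using the covariance from the curve fit.

By default both arms see the same sampled parameter set per draw (common
random parameters); an independent-sampling mode draws the comparator's
parameters separately.  Reported confidence intervals are
``mean +- 1.96 * SD`` of the sampled distribution (the SD, not the standard
error of the mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .markov import ModelConfig
from .model import ModelInputs, build_arm, run_arm
from .strategies import mix_by_assay
from .survival import ParametricSurvivalModel

logger = logging.getLogger(__name__)

KINDS = ("beta_moment_matched", "uniform_pct", "lognormal_mvn", "constant")

#: Hard cap on rejected-draw resampling, as a multiple of n_iterations.
MAX_REJECTION_FACTOR = 10


@dataclass(frozen=True)
class PSAConfig:
    """Number of Monte-Carlo iterations, master seed, and sampling mode."""

    n_iterations: int = 1000
    seed: int = 0
    common_draws_across_arms: bool = True

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass(frozen=True)
class ParameterDistributionSpec:
    """One uncertain parameter: a target path, a distribution kind, params."""

    target: str
    kind: str
    params: dict

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}")


def beta_moment_match(mean: float, sd: float) -> tuple[float, float]:
    """Solve for Beta(alpha, beta) matching a given mean and SD.

    Requires ``sd**2 < mean * (1 - mean)`` (Beta feasibility).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("beta moment matching requires 0 < mean < 1")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValueError(f"infeasible beta moments: sd^2 = {var} >= mean(1-mean)")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def build_distribution_specs(inputs: ModelInputs) -> list[ParameterDistributionSpec]:
    """Derive the full uncertain-parameter list from the model inputs.

    Infeasible Beta moments are rejected here, at configuration time, with
    the offending utility named.  Parameters with zero spread become
    ``constant`` specs so a fully degenerate PSA reproduces the
    deterministic run exactly.
    """
    specs: list[ParameterDistributionSpec] = []
    for name, u in inputs.utilities.items():
        if u.sd == 0.0:
            specs.append(
                ParameterDistributionSpec(f"utilities.{name}", "constant", {"value": u.mean})
            )
        else:
            try:
                alpha, beta = beta_moment_match(u.mean, u.sd)
            except ValueError as exc:
                raise ValueError(f"utility {name!r}: {exc}") from exc
            specs.append(
                ParameterDistributionSpec(
                    f"utilities.{name}", "beta_moment_matched", {"alpha": alpha, "beta": beta}
                )
            )

    seen: dict[str, "LineDef"] = {}
    for line in (*inputs.high_lines, *inputs.low_lines):
        seen.setdefault(line.drug_label, line)
    for drug, line in seen.items():
        for attr in ("cost_per_cycle", "ae_cost_minor", "ae_cost_major"):
            c = getattr(line, attr)
            specs.append(
                ParameterDistributionSpec(
                    f"{attr}.{drug}",
                    "uniform_pct" if inputs.cost_variability > 0 else "constant",
                    {"center": c, "pct": inputs.cost_variability}
                    if inputs.cost_variability > 0
                    else {"value": c},
                )
            )
    specs.append(
        ParameterDistributionSpec(
            "assay.cost",
            "uniform_pct" if inputs.assay.cost_variability > 0 else "constant",
            {"center": inputs.assay.cost, "pct": inputs.assay.cost_variability}
            if inputs.assay.cost_variability > 0
            else {"value": inputs.assay.cost},
        )
    )
    for key, model in inputs.survival_models.items():
        cov = model.coef_covariance
        if cov is None or not np.any(np.asarray(cov) > 0):
            specs.append(
                ParameterDistributionSpec(
                    f"survival.{key}", "constant", {"value": (model.shape, model.scale)}
                )
            )
        else:
            specs.append(
                ParameterDistributionSpec(
                    f"survival.{key}",
                    "lognormal_mvn",
                    {
                        "mu": np.array([np.log(model.shape), np.log(model.scale)]),
                        "cov": np.asarray(cov, float),
                    },
                )
            )
    return specs


def sample_parameters(
    specs: Sequence[ParameterDistributionSpec],
    seed: int,
    draw_index: int,
    stream: int = 0,
) -> dict:
    """Sample one value per spec, reproducibly for (seed, draw_index, stream).

    ``stream`` separates independent sampling streams (e.g. the comparator
    arm in independent-draw mode, or resampling attempts after a rejected
    draw).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, draw_index)))
    values: dict = {}
    for spec in specs:
        if spec.kind == "constant":
            values[spec.target] = spec.params["value"]
        elif spec.kind == "beta_moment_matched":
            values[spec.target] = float(rng.beta(spec.params["alpha"], spec.params["beta"]))
        elif spec.kind == "uniform_pct":
            c = spec.params["center"]
            pct = spec.params["pct"]
            lo = max(0.0, c * (1.0 - pct))
            hi = c * (1.0 + pct)
            values[spec.target] = float(rng.uniform(lo, hi))
        else:  # lognormal_mvn
            draw = rng.multivariate_normal(
                spec.params["mu"], spec.params["cov"], method="svd"
            )
            values[spec.target] = (float(np.exp(draw[0])), float(np.exp(draw[1])))
    return values


def apply_parameters(inputs: ModelInputs, values: dict) -> ModelInputs:
    """Build a perturbed copy of the inputs from one sampled value set."""
    from .model import LineDef, UtilityInput  # local to avoid re-export confusion

    models = {}
    for key, m in inputs.survival_models.items():
        shape, scale = values.get(f"survival.{key}", (m.shape, m.scale))
        if m.family == "exponential":
            shape = 1.0
        models[key] = ParametricSurvivalModel(m.family, shape, scale, m.coef_covariance)

    def remap(lines: tuple[LineDef, ...]) -> tuple[LineDef, ...]:
        out = []
        for line in lines:
            out.append(
                replace(
                    line,
                    cost_per_cycle=values.get(
                        f"cost_per_cycle.{line.drug_label}", line.cost_per_cycle
                    ),
                    ae_cost_minor=values.get(
                        f"ae_cost_minor.{line.drug_label}", line.ae_cost_minor
                    ),
                    ae_cost_major=values.get(
                        f"ae_cost_major.{line.drug_label}", line.ae_cost_major
                    ),
                )
            )
        return tuple(out)

    utilities = {
        name: UtilityInput(values.get(f"utilities.{name}", u.mean), u.sd)
        for name, u in inputs.utilities.items()
    }
    assay = replace(inputs.assay, cost=values.get("assay.cost", inputs.assay.cost))
    return replace(
        inputs,
        survival_models=models,
        high_lines=remap(inputs.high_lines),
        low_lines=remap(inputs.low_lines),
        utilities=utilities,
        assay=assay,
    )


@dataclass(frozen=True)
class PSASampleSet:
    """Per-draw arm outcomes plus the pathway-level internals.

    ``samples`` has one row per draw with intervention/comparator cost and
    QALYs, the underlying high/low pathway outcomes, and the sampled assay
    cost (plus its unit multiplier, used by assay-cost scenario sweeps).
    """

    samples: pd.DataFrame
    seed: int
    common_draws_across_arms: bool
    n_rejected: int = 0

    @property
    def n_iterations(self) -> int:
        return len(self.samples)

    @property
    def delta_cost(self) -> np.ndarray:
        return (self.samples["cost_intervention"] - self.samples["cost_comparator"]).to_numpy()

    @property
    def delta_qalys(self) -> np.ndarray:
        return (self.samples["qaly_intervention"] - self.samples["qaly_comparator"]).to_numpy()

    def to_long_frame(self) -> pd.DataFrame:
        """Long format (draw, arm, cost, qaly) for CSV export."""
        rows = []
        for arm in ("intervention", "comparator"):
            rows.append(
                pd.DataFrame(
                    {
                        "draw": self.samples["draw"],
                        "arm": arm,
                        "cost": self.samples[f"cost_{arm}"],
                        "qaly": self.samples[f"qaly_{arm}"],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True).sort_values(["draw", "arm"], ignore_index=True)

    def write_samples_csv(self, path: str | Path) -> None:
        """Samples CSV with a provenance header (seed and sampling mode)."""
        path = Path(path)
        mode = "common" if self.common_draws_across_arms else "independent"
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed} mode={mode} n={self.n_iterations}\n")
            self.to_long_frame().to_csv(fh, index=False)


def run_psa(
    inputs: ModelInputs,
    psa_config: PSAConfig,
    model_config: ModelConfig | None = None,
) -> PSASampleSet:
    """Run the full two-arm model once per parameter draw.

    In common-draw mode the comparator reuses the high-risk pathway run of
    the same parameter set (the comparator pathway is structurally
    identical), so each draw costs two cohort runs.  Draws whose sampled
    parameters produce an invalid transition schedule are resampled from a
    fresh stream; the count is recorded and capped at
    ``MAX_REJECTION_FACTOR * n_iterations``.
    """
    model_config = model_config or ModelConfig()
    specs = build_distribution_specs(inputs)
    assay_center = inputs.assay.cost
    n = psa_config.n_iterations
    max_rejections = MAX_REJECTION_FACTOR * n
    n_rejected = 0
    records = []
    for d in range(n):
        attempt = 0
        while True:
            try:
                values = sample_parameters(specs, psa_config.seed, d, stream=2 * attempt)
                inputs_d = apply_parameters(inputs, values)
                high = run_arm(build_arm(inputs_d, "high"), model_config)
                low = run_arm(build_arm(inputs_d, "low"), model_config)
                if psa_config.common_draws_across_arms:
                    comp = high
                else:
                    values_c = sample_parameters(
                        specs, psa_config.seed, d, stream=2 * attempt + 1
                    )
                    inputs_c = apply_parameters(inputs, values_c)
                    comp = run_arm(build_arm(inputs_c, "comparator"), model_config)
                break
            except ValueError as exc:
                n_rejected += 1
                logger.warning("draw %d rejected (attempt %d): %s", d, attempt, exc)
                if n_rejected > max_rejections:
                    raise RuntimeError(
                        f"aborting PSA: more than {max_rejections} rejected draws"
                    ) from exc
                attempt += 1
        assay_d = inputs_d.assay.as_spec()
        cost_i, qaly_i = mix_by_assay(assay_d, high, low)
        records.append(
            {
                "draw": d,
                "cost_intervention": cost_i,
                "qaly_intervention": qaly_i,
                "cost_comparator": comp[0],
                "qaly_comparator": comp[1],
                "cost_high": high[0],
                "qaly_high": high[1],
                "cost_low": low[0],
                "qaly_low": low[1],
                "assay_cost": assay_d.cost,
                "assay_cost_unit": assay_d.cost / assay_center if assay_center > 0 else 1.0,
            }
        )
    if n_rejected:
        logger.info("PSA complete with %d rejected draw(s) resampled", n_rejected)
    return PSASampleSet(
        samples=pd.DataFrame.from_records(records),
        seed=psa_config.seed,
        common_draws_across_arms=psa_config.common_draws_across_arms,
        n_rejected=n_rejected,
    )


def summarize(samples: PSASampleSet) -> pd.DataFrame:
    """Means and 95% CIs (mean +- 1.96 * sample SD, n-1 denominator).

    Rows: per-arm cost and QALYs plus the incremental cost and QALYs.
    """
    s = samples.samples
    if len(s) < 2:
        raise ValueError("summarize requires at least 2 draws")
    quantities = {
        "cost_intervention": s["cost_intervention"].to_numpy(),
        "qaly_intervention": s["qaly_intervention"].to_numpy(),
        "cost_comparator": s["cost_comparator"].to_numpy(),
        "qaly_comparator": s["qaly_comparator"].to_numpy(),
        "delta_cost": samples.delta_cost,
        "delta_qalys": samples.delta_qalys,
    }
    rows = []
    for name, arr in quantities.items():
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1))
        rows.append(
            {
                "quantity": name,
                "mean": mean,
                "sd": sd,
                "ci_low": mean - 1.96 * sd,
                "ci_high": mean + 1.96 * sd,
            }
        )
    return pd.DataFrame(rows).set_index("quantity")
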