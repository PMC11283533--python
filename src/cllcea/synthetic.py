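"""Synthetic trial survival data with the structure the analysis assumes.

The published analysis digitizes Kaplan-Meier curves from external trial
figures; no patient-level data are deposited.  This module generates data
with the same statistical structure so the full pipeline is exercisable
end to end without any download:

1. :func:`simulate_subjects` — Weibull event times with exponential plus
   administrative right-censoring,
2. :func:`km_estimate` — the product-limit survival estimate,
3. :func:`digitize` — step-function values on a monthly grid with additive
   Gaussian read-off noise, clamped and re-monotonized (emulating manual
   plot extraction),
4. :func:`make_fixture_bundle` — one digitized PFS and OS curve per
   treatment line of both pathways, plus the reference configuration.

All fixture survival parameters are synthetic: they preserve qualitative
orderings (first-line PFS > second-line > third-line in median; OS above
PFS) but make no attempt to reproduce any published trial's curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from . import config as _config
from .model import ModelInputs
from .survival import KMCurvePoints, ParametricSurvivalModel, fit_parametric


@dataclass(frozen=True)
class TrialSimSpec:
    """Generating truth for one synthetic trial endpoint.

    Event times are Weibull(true_shape, true_scale) months; censoring is
    the minimum of an exponential time (rate ``censor_rate`` per month) and
    an administrative cut-off ``admin_censor_time``.
    """

    endpoint: str  # "pfs" or "os"
    true_shape: float
    true_scale: float
    n_subjects: int
    censor_rate: float = 0.0
    admin_censor_time: float = np.inf
    seed: int | np.random.SeedSequence = 0

    def __post_init__(self) -> None:
        if self.endpoint not in ("pfs", "os"):
            raise ValueError("endpoint must be 'pfs' or 'os'")
        if not (self.true_shape > 0 and self.true_scale > 0):
            raise ValueError("Weibull parameters must be positive")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if not self.admin_censor_time > 0:
            raise ValueError("admin_censor_time must be positive")


def simulate_subjects(spec: TrialSimSpec) -> pd.DataFrame:
    """Simulate right-censored subjects; columns observed_time, event_flag.

    Event times come from the Weibull inverse CDF applied to seeded
    uniforms: ``t = scale * (-ln U) ** (1 / shape)``.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n_subjects)
    event_times = spec.true_scale * (-np.log1p(-u)) ** (1.0 / spec.true_shape)
    if spec.censor_rate > 0:
        censor_times = rng.exponential(1.0 / spec.censor_rate, size=spec.n_subjects)
    else:
        censor_times = np.full(spec.n_subjects, np.inf)
    censor_times = np.minimum(censor_times, spec.admin_censor_time)
    observed = np.minimum(event_times, censor_times)
    flags = (event_times <= censor_times).astype(int)
    return pd.DataFrame({"observed_time": observed, "event_flag": flags})


def km_estimate(records: pd.DataFrame) -> KMCurvePoints:
    """Product-limit (Kaplan-Meier) survival estimate.

    At each distinct event time ``S`` drops by the factor
    ``1 - d / n_at_risk``; censored subjects leave the risk set after their
    observed time.  The returned points are the estimate at every distinct
    observed time (events and censorings) with the number at risk attached.
    """
    if len(records) < 1:
        raise ValueError("at least one subject record is required")
    kmf = KaplanMeierFitter()
    kmf.fit(records["observed_time"], event_observed=records["event_flag"])
    surv = kmf.survival_function_.iloc[:, 0]
    at_risk = kmf.event_table["at_risk"]
    times = surv.index.to_numpy(dtype=float)
    keep = times > 0
    return KMCurvePoints(
        time=times[keep],
        survival=surv.to_numpy(dtype=float)[keep],
        n_at_risk=at_risk.to_numpy(dtype=float)[keep],
    )


def digitize(
    curve: KMCurvePoints,
    grid,
    noise_sd: float = 0.01,
    seed: int | np.random.SeedSequence = 0,
) -> KMCurvePoints:
    """Read the KM step function off at grid times, with extraction noise.

    Values are the step-function survival at each grid time plus seeded
    Gaussian noise of SD ``noise_sd`` (survival units), clamped to [0, 1]
    and re-monotonized with a running minimum — mimicking manual plot
    digitization.  The grid must lie within the observed support of the
    curve.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a non-empty 1-d array")
    if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid times must be non-negative and strictly increasing")
    if grid[-1] > curve.time[-1]:
        raise ValueError(
            f"grid extends to {grid[-1]} months beyond the curve support ({curve.time[-1]})"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    idx = np.searchsorted(curve.time, grid, side="right") - 1
    values = np.where(idx >= 0, curve.survival[np.maximum(idx, 0)], 1.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.clip(values, 0.0, 1.0)
    values = np.minimum.accumulate(values)
    return KMCurvePoints(time=grid, survival=values)


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

#: Synthetic generating truths per treatment line: Weibull (shape, scale)
#: in months for PFS and OS, and the simulated trial size.  Chosen for
#: qualitative realism only, not to match any trial: median PFS ordering
#: 1L > 2L > 3L within each pathway, OS above PFS per line, better
#: first-line outcomes in the low-risk pathway (low-risk disease carries a
#: better prognosis), and an overall regime in which risk-guided sequencing
#: is modestly costlier and more effective than treating everyone along the
#: high-risk sequence.
SYNTHETIC_TRIALS: dict[str, dict] = {
    "acalabrutinib_1l": {"pfs": (1.3, 13.0), "os": (1.2, 25.0), "n_subjects": 300},
    "venetoclax_obinutuzumab_1l": {"pfs": (1.4, 26.0), "os": (1.2, 33.0), "n_subjects": 300},
    "venetoclax_rituximab_2l": {"pfs": (1.3, 9.5), "os": (1.2, 18.0), "n_subjects": 250},
    "acalabrutinib_2l": {"pfs": (1.3, 24.0), "os": (1.2, 29.0), "n_subjects": 250},
    "idelalisib_rituximab_3l": {"pfs": (1.2, 8.0), "os": (1.1, 14.0), "n_subjects": 200},
}

#: Shared synthetic trial design: ~4 years of follow-up with light random
#: drop-out, digitized monthly with 0.01 survival-units of read-off noise.
TRIAL_DESIGN = {"censor_rate": 0.005, "admin_censor_time": 48.0, "digitize_noise_sd": 0.01}


@dataclass(frozen=True)
class FixtureBundle:
    """Paths and in-memory objects of one generated fixture bundle."""

    directory: Path | None
    curves: dict[str, KMCurvePoints]
    models: dict[str, ParametricSurvivalModel]
    inputs: ModelInputs
    seed: int


def _generate_curves(seed: int) -> dict[str, KMCurvePoints]:
    curves: dict[str, KMCurvePoints] = {}
    grid = np.arange(1.0, TRIAL_DESIGN["admin_censor_time"] + 1.0)
    for i, (base, trial) in enumerate(SYNTHETIC_TRIALS.items()):
        for j, endpoint in enumerate(("pfs", "os")):
            shape, scale = trial[endpoint]
            child = np.random.SeedSequence(seed, spawn_key=(i, j))
            sim_seed, digit_seed = child.spawn(2)
            records = simulate_subjects(
                TrialSimSpec(
                    endpoint=endpoint,
                    true_shape=shape,
                    true_scale=scale,
                    n_subjects=trial["n_subjects"],
                    censor_rate=TRIAL_DESIGN["censor_rate"],
                    admin_censor_time=TRIAL_DESIGN["admin_censor_time"],
                    seed=sim_seed,
                )
            )
            km = km_estimate(records)
            usable_grid = grid[grid <= km.time[-1]]
            curves[f"{base}_{endpoint}"] = digitize(
                km, usable_grid, noise_sd=TRIAL_DESIGN["digitize_noise_sd"], seed=digit_seed
            )
    return curves


def make_fixture_bundle(seed: int = 0, out_dir: str | Path | None = None) -> FixtureBundle:
    """Generate the full synthetic analysis bundle.

    Simulates every (treatment line, endpoint) trial, estimates and
    digitizes the KM curves, fits Weibull models, and assembles
    reference-case ModelInputs.  When ``out_dir`` is given, the digitized
    curves are written as ``<key>.csv`` and the reference configuration as
    ``config.yaml`` so the bundle round-trips through
    :func:`cllcea.config.load_bundle`.
    """
    curves = _generate_curves(seed)
    models = {key: fit_parametric(c, family="weibull") for key, c in curves.items()}
    inputs = _config.build_reference_inputs(models)

    directory = None
    if out_dir is not None:
        directory = Path(out_dir)
        directory.mkdir(parents=True, exist_ok=True)
        curve_files = {}
        for key, curve in curves.items():
            fname = f"{key}.csv"
            curve.to_csv(directory / fname)
            curve_files[key] = fname
        _config.write_config(_config.reference_config_dict(curve_files), directory / "config.yaml")
    return FixtureBundle(directory=directory, curves=curves, models=models, inputs=inputs, seed=seed)
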