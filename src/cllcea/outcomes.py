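"""Cost-effectiveness statistics: ICER, NMB, CE plane, CEAC, scenarios.

All statistics operate on incremental quantities ``dC = C_int - C_comp``
and ``dE = E_int - E_comp``:

* ICER = dC / dE, with dominance labels replacing the ratio when the signs
  make division misleading ("dominant": cheaper and more effective;
  "dominated": costlier and less effective) and an explicit label when
  |dE| is below tolerance,
* NMB = dE * wtp - dC at a willingness-to-pay threshold (reference
  $50,000/QALY),
* CEAC(lambda) = fraction of probabilistic draws with positive NMB,
* CE-plane quadrant proportions (NE, SE, SW, NW) by the signs of (dE, dC).

Probabilistic ICERs are reported as the ratio of mean increments
(mean(dC) / mean(dE)), not the mean of per-draw ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined (ΔE ≈ 0)"

#: |dE| below this (QALY) is treated as zero when forming an ICER.
DELTA_E_TOL = 1e-9


@dataclass(frozen=True)
class CEAConfig:
    """Willingness-to-pay threshold and the CEAC evaluation grid."""

    wtp_threshold: float = 50_000.0
    ceac_grid: np.ndarray = field(default_factory=lambda: np.arange(0.0, 150_001.0, 1000.0))

    def __post_init__(self) -> None:
        grid = np.asarray(self.ceac_grid, dtype=float)
        if grid.size and (np.any(grid < 0) or np.any(np.diff(grid) <= 0)):
            raise ValueError("ceac_grid thresholds must be non-negative and increasing")
        object.__setattr__(self, "ceac_grid", grid)


def icer(delta_cost: float, delta_qalys: float, zero_tol: float = DELTA_E_TOL) -> float | str:
    """Incremental cost-effectiveness ratio or a dominance label."""
    if abs(delta_qalys) < zero_tol:
        return DOMINANT if delta_cost < 0 else UNDEFINED
    if delta_cost < 0 and delta_qalys > 0:
        return DOMINANT
    if delta_cost > 0 and delta_qalys < 0:
        return DOMINATED
    return delta_cost / delta_qalys


def nmb(delta_cost: float, delta_qalys: float, wtp: float = 50_000.0) -> float:
    """Net monetary benefit ``dE * wtp - dC`` in CAD."""
    return delta_qalys * wtp - delta_cost


def _deltas(samples) -> tuple[np.ndarray, np.ndarray]:
    """Extract (dC, dE) arrays from a sample set or a (dC, dE) pair."""
    if hasattr(samples, "delta_cost") and hasattr(samples, "delta_qalys"):
        return np.asarray(samples.delta_cost, float), np.asarray(samples.delta_qalys, float)
    dc, de = samples
    return np.asarray(dc, float), np.asarray(de, float)


def ceac(samples, thresholds=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    At each willingness-to-pay ``lambda`` the probability of the
    intervention being cost-effective is the fraction of draws with
    ``lambda * dE - dC > 0``.  Draws with dE exactly zero therefore count
    as cost-effective iff they save money.
    """
    dc, de = _deltas(samples)
    grid = CEAConfig().ceac_grid if thresholds is None else np.asarray(thresholds, float)
    prob = [(lam * de - dc > 0).mean() for lam in grid]
    return pd.DataFrame({"threshold": grid, "probability": prob})


def probability_cost_effective(samples, wtp: float = 50_000.0) -> float:
    """Fraction of draws with positive NMB at a single threshold."""
    dc, de = _deltas(samples)
    return float((wtp * de - dc > 0).mean())


def ce_plane_quadrants(samples) -> np.ndarray:
    """CE-plane quadrant proportions (NE, SE, SW, NW).

    Quadrants follow the signs of (dE, dC) with dE on the x axis: NE = more
    effective & more costly, SE = more effective & cheaper (dominant),
    SW = less effective & cheaper, NW = less effective & costlier
    (dominated).  Tie rule: a draw with dE == 0 counts as "not more
    effective" (west side); dC == 0 counts as "not more costly" (south).
    """
    dc, de = _deltas(samples)
    n = dc.size
    if n == 0:
        raise ValueError("at least one draw is required")
    east = de > 0
    north = dc > 0
    ne = float((east & north).sum()) / n
    se = float((east & ~north).sum()) / n
    sw = float((~east & ~north).sum()) / n
    nw = float((~east & north).sum()) / n
    return np.array([ne, se, sw, nw])


@dataclass(frozen=True)
class CEAResult:
    """Summary CEA statistics for a probabilistic sample set."""

    delta_cost: float
    delta_qalys: float
    icer: float | str
    nmb: float
    quadrant_proportions: np.ndarray
    ceac: pd.DataFrame

    def __post_init__(self) -> None:
        q = np.asarray(self.quadrant_proportions, float)
        if q.shape != (4,) or abs(q.sum() - 1.0) > 1e-9:
            raise ValueError("quadrant proportions must be 4 fractions summing to 1")
        object.__setattr__(self, "quadrant_proportions", q)


def cea_summary(samples, config: CEAConfig | None = None) -> CEAResult:
    """Mean increments, ratio-of-means ICER, NMB, quadrants and CEAC."""
    config = config or CEAConfig()
    dc, de = _deltas(samples)
    dc_bar = float(dc.mean())
    de_bar = float(de.mean())
    return CEAResult(
        delta_cost=dc_bar,
        delta_qalys=de_bar,
        icer=icer(dc_bar, de_bar),
        nmb=nmb(dc_bar, de_bar, config.wtp_threshold),
        quadrant_proportions=ce_plane_quadrants((dc, de)),
        ceac=ceac((dc, de), config.ceac_grid),
    )


def scenario_sweep(
    inputs,
    axis: str,
    values,
    model_config=None,
    psa_config=None,
) -> pd.DataFrame:
    """Sweep the assay cost or the high-risk prevalence.

    Pathway-level outcomes do not depend on either axis, so they are
    computed once (deterministically at the input means, or as one
    probabilistic sample set when ``psa_config`` is given) and re-mixed per
    scenario value.  Returns one row per value with dC, dE and the ICER
    (ratio of means in probabilistic mode).
    """
    from dataclasses import replace as _replace

    from . import psa as _psa
    from .markov import ModelConfig
    from .model import run_pathway_outcomes
    from .strategies import mix_by_assay

    if axis not in ("assay_cost", "prevalence"):
        raise ValueError(f"unknown scenario axis {axis!r}")
    values = list(values)
    if axis == "assay_cost" and any(v < 0 for v in values):
        raise ValueError("assay costs must be >= 0")
    if axis == "prevalence" and any(not 0 <= v <= 1 for v in values):
        raise ValueError("prevalences must be in [0, 1]")
    model_config = model_config or ModelConfig()

    rows = []
    if psa_config is None or psa_config.n_iterations == 1:
        pathways = run_pathway_outcomes(inputs, model_config)
        cost_c, qaly_c = pathways["high"]
        for v in values:
            assay = inputs.assay.as_spec()
            if axis == "assay_cost":
                assay = _replace(assay, cost=float(v))
            else:
                assay = _replace(assay, prevalence_high_risk=float(v))
            cost_i, qaly_i = mix_by_assay(assay, pathways["high"], pathways["low"])
            dc = cost_i - cost_c
            de = qaly_i - qaly_c
            rows.append({"value": v, "delta_cost": dc, "delta_qalys": de, "icer": icer(dc, de)})
    else:
        res = _psa.run_psa(inputs, psa_config, model_config)
        s = res.samples
        for v in values:
            if axis == "assay_cost":
                assay_draws = s["assay_cost_unit"].to_numpy() * float(v)
                pi = inputs.assay.prevalence_high_risk
            else:
                assay_draws = s["assay_cost"].to_numpy()
                pi = float(v)
            cost_i = (
                pi * s["cost_high"] + (1 - pi) * s["cost_low"] + assay_draws
            ).to_numpy()
            qaly_i = (pi * s["qaly_high"] + (1 - pi) * s["qaly_low"]).to_numpy()
            dc = float((cost_i - s["cost_comparator"]).mean())
            de = float((qaly_i - s["qaly_comparator"]).mean())
            rows.append({"value": v, "delta_cost": dc, "delta_qalys": de, "icer": icer(dc, de)})
    return pd.DataFrame(rows, columns=["value", "delta_cost", "delta_qalys", "icer"])


def write_ce_plane(samples, path) -> None:
    """Per-draw (dE, dC) pairs as CSV for external plotting."""
    dc, de = _deltas(samples)
    pd.DataFrame({"delta_qalys": de, "delta_cost": dc}).to_csv(path, index=False)


def plot_ce_plane(samples, path=None, wtp: float = 50_000.0):
    """Scatter of probabilistic draws on the cost-effectiveness plane."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    dc, de = _deltas(samples)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(de, dc, s=8, alpha=0.5)
    lim = max(abs(de).max(), 1e-9)
    xs = np.linspace(-lim, lim, 2)
    ax.plot(xs, wtp * xs, color="grey", lw=1, ls="--", label=f"WTP {wtp:,.0f}/QALY")
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (CAD)")
    ax.legend(frameon=False)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_ceac(ceac_df: pd.DataFrame, path=None):
    """Cost-effectiveness acceptability curve figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac_df["threshold"], ceac_df["probability"])
    ax.set_xlabel("Willingness to pay (CAD per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
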