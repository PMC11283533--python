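"""Discrete-time cohort Markov engine with discounting.

Generic machinery for state-transition models: health-state definitions,
per-cycle (time-dependent) row-stochastic transition matrices, cohort
propagation, and accumulation of discounted costs and quality-adjusted
life-years.  Nothing in this module knows about the disease; the strategy
layer builds the schedules.

Conventions
-----------
* cycle length is in months; discounting uses an annual discrete rate with
  fractional exponents: ``d(t) = (1 + r) ** (-(t * dt) / 12)``,
* utilities are annual-equivalent weights, so each cycle accrues
  ``occupancy * utility * dt / 12`` QALYs,
* outcomes accrue on cycle-start occupancy (cycles ``0 .. n-1``); an
  optional half-cycle correction averages adjacent occupancies instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONSERVATION_ATOL = 1e-12


@dataclass(frozen=True)
class HealthStateSpec:
    """One mutually exclusive health state.

    ``utility`` is an annual-equivalent weight in [0, 1]; ``cost_per_cycle``
    is in CAD.  An absorbing state (death) must carry zero utility and cost.
    ``line_tag`` optionally records which treatment line the state belongs to.
    """

    name: str
    utility: float
    cost_per_cycle: float = 0.0
    absorbing: bool = False
    line_tag: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.utility <= 1.0:
            raise ValueError(f"state {self.name!r}: utility must be in [0, 1]")
        if self.cost_per_cycle < 0:
            raise ValueError(f"state {self.name!r}: cost_per_cycle must be >= 0")
        if self.absorbing and (self.utility != 0.0 or self.cost_per_cycle != 0.0):
            raise ValueError(f"absorbing state {self.name!r} must have zero utility and cost")
        if self.line_tag is not None and self.line_tag not in (1, 2, 3):
            raise ValueError(f"state {self.name!r}: line_tag must be 1..3 or None")


@dataclass(frozen=True)
class ModelConfig:
    """Run configuration: horizon, cycle length, discounting.

    Reference case: 120 one-month cycles (10 years), 1.5% annual discount
    rate, no half-cycle correction.
    """

    n_cycles: int = 120
    cycle_length: float = 1.0
    discount_rate_annual: float = 0.015
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not self.cycle_length > 0:
            raise ValueError("cycle_length must be positive")
        if self.discount_rate_annual < 0:
            raise ValueError("discount rate must be >= 0")

    @property
    def horizon_months(self) -> float:
        return self.n_cycles * self.cycle_length


@dataclass(frozen=True)
class TransitionSchedule:
    """Ordered states plus one row-stochastic matrix per cycle."""

    states: tuple[HealthStateSpec, ...]
    matrices: np.ndarray  # (n_cycles, S, S)

    def __post_init__(self) -> None:
        states = tuple(self.states)
        object.__setattr__(self, "states", states)
        mats = np.asarray(self.matrices, dtype=float)
        if mats.ndim != 3 or mats.shape[1] != mats.shape[2] or mats.shape[1] != len(states):
            raise ValueError("matrices must have shape (n_cycles, S, S) matching the state list")
        object.__setattr__(self, "matrices", mats)

    @property
    def n_cycles(self) -> int:
        return self.matrices.shape[0]

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    def index(self, name: str) -> int:
        return self.state_names.index(name)

    def validate(self, atol: float = CONSERVATION_ATOL) -> None:
        """Check row-stochasticity, entry bounds, and absorbing rows."""
        mats = self.matrices
        if np.any(mats < -atol) or np.any(mats > 1 + atol):
            raise ValueError("transition entries must lie in [0, 1]")
        row_sums = mats.sum(axis=2)
        bad = np.argwhere(np.abs(row_sums - 1.0) > atol)
        if bad.size:
            t, i = bad[0]
            raise ValueError(
                f"non-stochastic row at cycle {t}, state {self.states[i].name!r} "
                f"(sum {row_sums[t, i]!r})"
            )
        for i, s in enumerate(self.states):
            if s.absorbing:
                expected = np.zeros(len(self.states))
                expected[i] = 1.0
                if not np.allclose(mats[:, i, :], expected, atol=atol):
                    raise ValueError(f"absorbing state {s.name!r} must have an identity row")

    @property
    def costs(self) -> np.ndarray:
        return np.array([s.cost_per_cycle for s in self.states])

    @property
    def utilities(self) -> np.ndarray:
        return np.array([s.utility for s in self.states])


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy fractions per cycle, cycles ``0 .. n_cycles``."""

    state_names: tuple[str, ...]
    occupancy: np.ndarray  # (n_cycles + 1, S)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != len(self.state_names):
            raise ValueError("occupancy must be (n_cycles + 1, S)")
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "state_names", tuple(self.state_names))

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(self.state_names))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df


def run_cohort(
    initial_distribution: Sequence[float],
    schedule: TransitionSchedule,
    config: ModelConfig,
) -> CohortTrace:
    """Propagate a cohort through the transition schedule.

    The initial distribution must sum to 1; the schedule must cover at
    least ``config.n_cycles`` cycles.  Row-stochasticity is checked for the
    cycles actually used and violations are reported with the offending
    cycle and state named.
    """
    init = np.asarray(initial_distribution, dtype=float)
    if init.shape != (len(schedule.states),):
        raise ValueError("initial distribution length must match the state list")
    if abs(init.sum() - 1.0) > 1e-9:
        raise ValueError(f"initial distribution must sum to 1 (got {init.sum()!r})")
    if np.any(init < 0):
        raise ValueError("initial occupancies must be non-negative")
    if schedule.n_cycles < config.n_cycles:
        raise ValueError(
            f"schedule covers {schedule.n_cycles} cycles but config requires {config.n_cycles}"
        )
    mats = schedule.matrices[: config.n_cycles]
    row_sums = mats.sum(axis=2)
    bad = np.argwhere(np.abs(row_sums - 1.0) > CONSERVATION_ATOL)
    if bad.size:
        t, i = bad[0]
        raise ValueError(
            f"non-stochastic row at cycle {t}, state {schedule.states[i].name!r} "
            f"(sum {row_sums[t, i]!r})"
        )
    occ = np.empty((config.n_cycles + 1, len(schedule.states)))
    occ[0] = init
    for t in range(config.n_cycles):
        occ[t + 1] = occ[t] @ mats[t]
    return CohortTrace(schedule.state_names, occ)


def discount_factor(cycle_index: int, config: ModelConfig) -> float:
    """Discount factor ``(1 + r) ** (-(cycle * dt) / 12)`` for one cycle index."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be non-negative")
    months = cycle_index * config.cycle_length
    return float((1.0 + config.discount_rate_annual) ** (-months / 12.0))


def discount_factors(config: ModelConfig) -> np.ndarray:
    """Discount factors for cycles ``0 .. n_cycles - 1``."""
    months = np.arange(config.n_cycles, dtype=float) * config.cycle_length
    return (1.0 + config.discount_rate_annual) ** (-months / 12.0)


def accumulate_outcomes(
    trace: CohortTrace,
    schedule: TransitionSchedule,
    config: ModelConfig,
    one_time_costs: Iterable[tuple[int, float]] = (),
) -> tuple[float, float]:
    """Discounted (total cost, total QALYs) for a cohort trace.

    Per cycle ``t`` the cohort accrues ``sum_s occ[t, s] * cost_s * d(t)``
    in cost and ``sum_s occ[t, s] * utility_s * (dt / 12) * d(t)`` in QALYs.
    One-time costs are ``(cycle, amount)`` pairs added with that cycle's
    discount factor; a cycle beyond the horizon is rejected.
    """
    if trace.state_names != schedule.state_names:
        raise ValueError("trace and schedule state lists differ")
    if trace.n_cycles < config.n_cycles:
        raise ValueError("trace is shorter than the configured horizon")
    if config.half_cycle_correction:
        occ = 0.5 * (trace.occupancy[: config.n_cycles] + trace.occupancy[1 : config.n_cycles + 1])
    else:
        occ = trace.occupancy[: config.n_cycles]
    d = discount_factors(config)
    cost = float((occ @ schedule.costs) @ d)
    qalys = float((occ @ schedule.utilities) @ d * (config.cycle_length / 12.0))
    for cycle, amount in one_time_costs:
        if not 0 <= cycle <= config.n_cycles:
            raise ValueError(f"one-time cost at cycle {cycle} is beyond the horizon")
        cost += amount * discount_factor(cycle, config)
    return cost, qalys


def trace_ledger(
    trace: CohortTrace, schedule: TransitionSchedule, config: ModelConfig
) -> pd.DataFrame:
    """Long-format per-cycle ledger: occupancy, discounted cost and QALYs."""
    occ = trace.occupancy[: config.n_cycles]
    d = discount_factors(config)
    rows = []
    for i, name in enumerate(schedule.state_names):
        rows.append(
            pd.DataFrame(
                {
                    "cycle": np.arange(config.n_cycles),
                    "state": name,
                    "occupancy": occ[:, i],
                    "discounted_cost": occ[:, i] * schedule.costs[i] * d,
                    "discounted_qalys": occ[:, i]
                    * schedule.utilities[i]
                    * (config.cycle_length / 12.0)
                    * d,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
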