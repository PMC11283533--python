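"""Independent oracles shared across test modules.

These implementations deliberately avoid the library code paths they
check: a first-order microsimulation for the cohort engine, and a direct
product-limit estimator for the Kaplan-Meier routine.
"""

from __future__ import annotations

import numpy as np


def microsimulate(schedule, n_cycles: int, n_subjects: int, seed: int, initial_state: int = 0):
    """First-order microsimulation through a transition schedule.

    Simulates ``n_subjects`` independent patients cycle by cycle using the
    schedule's per-cycle matrices and returns the occupancy fractions,
    shape ``(n_cycles + 1, S)``.
    """
    rng = np.random.default_rng(seed)
    S = len(schedule.states)
    state = np.full(n_subjects, initial_state, dtype=np.int64)
    occ = np.zeros((n_cycles + 1, S))
    occ[0, initial_state] = 1.0
    for t in range(n_cycles):
        u = rng.random(n_subjects)
        new = np.empty_like(state)
        for s in range(S):
            mask = state == s
            if not mask.any():
                continue
            cum = np.cumsum(schedule.matrices[t][s])
            new[mask] = np.searchsorted(cum, u[mask], side="right")
        np.clip(new, 0, S - 1, out=new)
        state = new
        occ[t + 1] = np.bincount(state, minlength=S) / n_subjects
    return occ


def assert_within_monte_carlo_error(
    cohort_occ,
    micro_occ,
    n_subjects: int,
    n_se: float = 3.0,
    max_violation_fraction: float = 0.005,
    hard_cap_se: float = 5.0,
):
    """Assert the microsimulation agrees with the cohort at MC precision.

    Per cell (cycle, state) the tolerance is ``n_se`` binomial standard
    errors (SE from the cohort occupancy) plus ``n_se / N`` for Poisson
    discreteness at tiny occupancies.  Because a 3-SE band is a per-cell
    band, the maximum over the ~1500 (correlated) cells of a *correct*
    simulation routinely reaches ~3.5 SE; the check therefore allows a
    small fraction of cells (0.5%, versus ~0.3% expected under
    independence) beyond ``n_se`` SEs, with a hard simultaneous cap of
    ``hard_cap_se`` SEs that no cell may exceed.
    """
    p = np.clip(cohort_occ, 0.0, 1.0)
    se = np.sqrt(p * (1.0 - p) / n_subjects)
    err = np.abs(micro_occ - cohort_occ)
    soft = n_se * se + n_se / n_subjects
    hard = hard_cap_se * se + hard_cap_se / n_subjects
    violation_fraction = float(np.mean(err > soft))
    worst = np.unravel_index(np.argmax(err - hard), err.shape)
    assert violation_fraction <= max_violation_fraction, (
        f"{violation_fraction:.2%} of cells deviate beyond {n_se} Monte-Carlo SEs "
        f"(allowed {max_violation_fraction:.2%})"
    )
    assert np.all(err <= hard), (
        f"microsimulation deviates beyond {hard_cap_se} Monte-Carlo SEs at "
        f"cycle/state {worst}: |err|={err[worst]:.3e}, cap={hard[worst]:.3e}"
    )


def product_limit(times, events):
    """Direct product-limit estimator (independent of lifelines).

    Returns (distinct_sorted_times, survival) over all observed times.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    order = np.argsort(times, kind="stable")
    times = times[order]
    events = events[order]
    distinct = np.unique(times)
    s = 1.0
    out = []
    for t in distinct:
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        if at_risk > 0:
            s *= 1.0 - d / at_risk
        out.append(s)
    return distinct, np.array(out)
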