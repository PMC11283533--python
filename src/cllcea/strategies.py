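"""Two-arm CLL treatment-sequencing strategies as Markov schedules.

The decision problem compares an assay-guided arm against standard of care.
In the assay arm a genetic test stratifies patients by risk (del17p, TP53
mutation and/or unmutated IGHV): high-risk patients start acalabrutinib and
move to venetoclax + rituximab on progression; low-risk patients start
venetoclax + obinutuzumab (12 fixed cycles, then a treatment-free interval)
and move to acalabrutinib.  The comparator treats everyone along the
high-risk sequence.  Idelalisib + rituximab is third line in all pathways.

Each pathway is expanded into per-line health states (on treatment, minor
and major adverse-event excursions, a treatment-free interval for
fixed-duration regimens) plus a shared post-third-line progression state
and death, and compiled into per-cycle transition matrices.

Line-local clocks
-----------------
Trial survival curves are functions of time since the line started, not
model time, so per-line hazards must run on line-local clocks.
:func:`build_arm_schedule` therefore performs an internal forward pass that
stratifies occupancy by time-in-line and emits, for every model cycle, the
occupancy-weighted aggregate transition matrix.  Propagating a cohort
through those matrices reproduces the stratified (semi-Markov) cohort
exactly — for the canonical initial distribution in which the whole cohort
starts first-line treatment at cycle 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np

from .markov import HealthStateSpec, ModelConfig, TransitionSchedule
from .survival import ParametricSurvivalModel, event_prob_schedule

PATHWAYS = ("high", "low", "comparator")

#: Health-state utility weights (annual equivalents) for the expanded
#: state space; on-treatment utilities are per line, adverse-event and
#: treatment-free weights are shared across lines.
DEFAULT_UTILITIES: Mapping[str, float] = MappingProxyType(
    {
        "on_treatment_1": 0.78,
        "on_treatment_2": 0.71,
        "on_treatment_3": 0.65,
        "ae_major": 0.69,
        "ae_minor": 0.73,
        "treatment_free": 0.91,
        "progression_post_3l": 0.68,
    }
)


@dataclass(frozen=True)
class TreatmentLineSpec:
    """One treatment line: drug, per-cycle cost, duration, survival, AEs.

    ``fixed_duration_cycles`` is ``None`` for treat-to-progression regimens
    (BTK inhibitors, idelalisib + rituximab) and the number of cycles for
    time-limited regimens (12 for venetoclax + obinutuzumab, 24 for
    venetoclax + rituximab).  Adverse-event probabilities are constant
    per-cycle hazards while on treatment.
    """

    drug_label: str
    cost_per_cycle: float
    pfs_model: ParametricSurvivalModel
    os_model: ParametricSurvivalModel
    fixed_duration_cycles: int | None = None
    p_minor_ae_per_cycle: float = 0.0
    p_major_ae_per_cycle: float = 0.0
    ae_cost_minor: float = 0.0
    ae_cost_major: float = 0.0

    def __post_init__(self) -> None:
        if self.cost_per_cycle < 0:
            raise ValueError(f"{self.drug_label}: cost_per_cycle must be >= 0")
        if self.ae_cost_minor < 0 or self.ae_cost_major < 0:
            raise ValueError(f"{self.drug_label}: adverse-event costs must be >= 0")
        for p in (self.p_minor_ae_per_cycle, self.p_major_ae_per_cycle):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.drug_label}: AE probabilities must be in [0, 1]")
        if self.fixed_duration_cycles is not None and self.fixed_duration_cycles <= 0:
            raise ValueError(f"{self.drug_label}: fixed duration must be positive when present")


@dataclass(frozen=True)
class AssaySpec:
    """The risk-stratification assay: one-time cost, prevalence, accuracy.

    The reference case assumes a $1000 CAD test that classifies 50% of
    patients as high-risk with no false positives or negatives
    (sensitivity = specificity = 1).
    """

    cost: float = 1000.0
    prevalence_high_risk: float = 0.5
    sensitivity: float = 1.0
    specificity: float = 1.0

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError("assay cost must be >= 0")
        for name in ("prevalence_high_risk", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"assay {name} must be in [0, 1]")


@dataclass(frozen=True)
class StrategyArm:
    """An ordered three-line treatment pathway plus optional assay."""

    label: str
    lines: tuple[TreatmentLineSpec, ...]
    assay: AssaySpec | None = None
    utilities: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_UTILITIES))

    def __post_init__(self) -> None:
        lines = tuple(self.lines)
        if len(lines) != 3:
            raise ValueError(f"arm {self.label!r}: exactly three treatment lines are required")
        object.__setattr__(self, "lines", lines)


def expand_states(arm: StrategyArm) -> list[HealthStateSpec]:
    """Expand a pathway into its ordered health-state list.

    Per line ``i``: ``on_treatment_i``, ``ae_minor_i``, ``ae_major_i`` and —
    for fixed-duration regimens only — ``treatment_free_i``.  Shared states:
    ``progression_post_3l`` (relapse after third line) and absorbing
    ``death``.  Utilities are attached from ``arm.utilities``; the
    minor-AE state keeps the drug cost (treatment continues) plus the
    minor-AE cost, while the major-AE state carries only the AE cost
    (treatment is discontinued).
    """
    u = arm.utilities
    states: list[HealthStateSpec] = []
    try:
        for i, line in enumerate(arm.lines, start=1):
            states.append(
                HealthStateSpec(
                    f"on_treatment_{i}", u[f"on_treatment_{i}"], line.cost_per_cycle, line_tag=i
                )
            )
            states.append(
                HealthStateSpec(
                    f"ae_minor_{i}",
                    u["ae_minor"],
                    line.cost_per_cycle + line.ae_cost_minor,
                    line_tag=i,
                )
            )
            states.append(
                HealthStateSpec(f"ae_major_{i}", u["ae_major"], line.ae_cost_major, line_tag=i)
            )
            if line.fixed_duration_cycles is not None:
                states.append(
                    HealthStateSpec(f"treatment_free_{i}", u["treatment_free"], 0.0, line_tag=i)
                )
        states.append(HealthStateSpec("progression_post_3l", u["progression_post_3l"], 0.0))
    except KeyError as exc:
        raise ValueError(f"arm {arm.label!r}: missing utility for state {exc.args[0]!r}") from exc
    states.append(HealthStateSpec("death", 0.0, 0.0, absorbing=True))
    return states


def _line_hazards(
    line: TreatmentLineSpec, config: ModelConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle (progression, death) probabilities on the line-local clock."""
    p_pfs = event_prob_schedule(line.pfs_model, config.n_cycles, config.cycle_length)
    p_death = event_prob_schedule(line.os_model, config.n_cycles, config.cycle_length)
    p_prog = np.clip(p_pfs - p_death, 0.0, None)
    return p_prog, p_death


def build_arm_schedule(arm: StrategyArm, config: ModelConfig) -> TransitionSchedule:
    """Compile a pathway into per-cycle transition matrices.

    Transition rules, all on the line-local clock ``a`` (cycles since the
    line began):

    * ``on_treatment_i``: death per the line's OS model; progression to the
      next line (or to ``progression_post_3l`` after line 3, line-3 clock
      continuing); constant-hazard minor/major AE excursions; survivors of a
      fixed-duration regimen move to ``treatment_free_i`` on completing the
      duration.
    * ``ae_minor_i``: one-cycle excursion; survivors return to the same
      line's on-treatment state (or its treatment-free state if the
      duration completed during the excursion).
    * ``ae_major_i``: one-cycle excursion; survivors discontinue and
      advance to the next line (after line 3, to ``progression_post_3l``).
    * ``treatment_free_i``: the completed line's PFS clock continues; death
      or progression to the next line, no drug cost, no AEs.
    * ``progression_post_3l``: death per the third-line OS model, clock
      continuing.

    The emitted matrices are occupancy-weighted aggregates of the internal
    time-in-line stratification and are exact for a cohort that starts
    entirely in ``on_treatment_1`` at cycle 0 (see module docstring).
    """
    states = expand_states(arm)
    names = [s.name for s in states]
    idx = {n: j for j, n in enumerate(names)}
    n = config.n_cycles
    n_lines = len(arm.lines)
    big_a = n + 1  # maximum line age tracked

    p_prog = {}
    p_death = {}
    for i, line in enumerate(arm.lines, start=1):
        pp, pd_ = _line_hazards(line, config)
        total = pp + pd_ + line.p_minor_ae_per_cycle + line.p_major_ae_per_cycle
        bad = np.flatnonzero(total > 1.0 + 1e-12)
        if bad.size:
            raise ValueError(
                f"arm {arm.label!r}, line {i} ({line.drug_label}): competing per-cycle "
                f"probabilities sum to {total[bad[0]]:.6f} > 1 at cycle {int(bad[0])}"
            )
        p_prog[i] = pp
        p_death[i] = pd_

    S = len(states)
    occ = np.zeros((S, big_a))
    occ[idx["on_treatment_1"], 0] = 1.0
    mats = np.zeros((n, S, S))
    i_death = idx["death"]
    i_post = idx["progression_post_3l"]

    def canonical_weights(j: int, t: int) -> np.ndarray:
        w = np.zeros(big_a)
        w[0] = 1.0
        return w

    for t in range(n):
        new = np.zeros_like(occ)
        P = mats[t]

        for i, line in enumerate(arm.lines, start=1):
            i_on = idx[f"on_treatment_{i}"]
            i_aem = idx[f"ae_minor_{i}"]
            i_aeM = idx[f"ae_major_{i}"]
            dur = line.fixed_duration_cycles
            i_tf = idx[f"treatment_free_{i}"] if dur is not None else None
            i_next = idx[f"on_treatment_{i + 1}"] if i < n_lines else None
            pd_i = p_death[i]
            pp_i = p_prog[i]
            pM = line.p_major_ae_per_cycle
            pm = line.p_minor_ae_per_cycle

            # --- on_treatment_i ---------------------------------------
            w = occ[i_on, :n]
            m = w.sum()
            wr = w if m > 0 else canonical_weights(i_on, t)[:n]
            stay = 1.0 - pd_i - pp_i - pM - pm
            sv = wr * stay
            f = np.zeros(S)
            f[i_death] = wr @ pd_i
            if i_next is not None:
                f[i_next] = wr @ pp_i
            else:
                # third-line progression: post-3L state, line-3 clock continues
                new[i_post, 1 : n + 1] += w * pp_i
                f[i_post] = wr @ pp_i
            f[i_aeM] = wr.sum() * pM
            f[i_aem] = wr.sum() * pm
            if dur is not None:
                f[i_tf] = sv[dur - 1] if dur - 1 < n else 0.0
                f[i_on] = sv.sum() - (sv[dur - 1] if dur - 1 < n else 0.0)
            else:
                f[i_on] = sv.sum()
            P[i_on] = f / f.sum()
            if m > 0:
                new[i_death, 0] += w @ pd_i
                if i_next is not None:
                    new[i_next, 0] += w @ pp_i
                new[i_aeM, 1 : n + 1] += w * pM
                new[i_aem, 1 : n + 1] += w * pm
                svm = w * stay
                if dur is not None and dur - 1 < n:
                    new[i_tf, dur] += svm[dur - 1]
                    svm = svm.copy()
                    svm[dur - 1] = 0.0
                new[i_on, 1 : n + 1] += svm

            # --- ae_minor_i: one-cycle excursion, return to treatment --
            w = occ[i_aem, :n]
            m = w.sum()
            wr = w if m > 0 else canonical_weights(i_aem, t)[:n]
            f = np.zeros(S)
            f[i_death] = wr @ pd_i
            surv = wr * (1.0 - pd_i)
            if dur is not None:
                back_tf = surv[dur - 1 :].sum()
                f[i_tf] = back_tf
                f[i_on] = surv.sum() - back_tf
            else:
                f[i_on] = surv.sum()
            P[i_aem] = f / f.sum()
            if m > 0:
                new[i_death, 0] += w @ pd_i
                svm = w * (1.0 - pd_i)
                if dur is not None:
                    tail = svm[dur - 1 :].copy()
                    new[i_tf, dur : n + 1] += tail
                    svm = svm.copy()
                    svm[dur - 1 :] = 0.0
                new[i_on, 1 : n + 1] += svm

            # --- ae_major_i: one-cycle excursion, discontinue ----------
            w = occ[i_aeM, :n]
            m = w.sum()
            wr = w if m > 0 else canonical_weights(i_aeM, t)[:n]
            f = np.zeros(S)
            f[i_death] = wr @ pd_i
            if i_next is not None:
                f[i_next] = wr.sum() - f[i_death]
            else:
                f[i_post] = wr.sum() - f[i_death]
            P[i_aeM] = f / f.sum()
            if m > 0:
                new[i_death, 0] += w @ pd_i
                svm = w * (1.0 - pd_i)
                if i_next is not None:
                    new[i_next, 0] += svm.sum()
                else:
                    new[i_post, 1 : n + 1] += svm

            # --- treatment_free_i: PFS clock continues -----------------
            if dur is not None:
                w = occ[i_tf, :n]
                m = w.sum()
                wr = w if m > 0 else canonical_weights(i_tf, t)[:n]
                f = np.zeros(S)
                f[i_death] = wr @ pd_i
                prog = wr @ pp_i
                if i_next is not None:
                    f[i_next] = prog
                else:
                    f[i_post] = prog
                f[i_tf] = wr @ (1.0 - pd_i - pp_i)
                P[i_tf] = f / f.sum()
                if m > 0:
                    new[i_death, 0] += w @ pd_i
                    if i_next is not None:
                        new[i_next, 0] += w @ pp_i
                    else:
                        new[i_post, 1 : n + 1] += w * pp_i
                    new[i_tf, 1 : n + 1] += w * (1.0 - pd_i - pp_i)

        # --- progression_post_3l: third-line OS clock continues --------
        pd_last = p_death[n_lines]
        w = occ[i_post, :n]
        m = w.sum()
        wr = w if m > 0 else canonical_weights(i_post, t)[:n]
        f = np.zeros(S)
        f[i_death] = wr @ pd_last
        f[i_post] = wr @ (1.0 - pd_last)
        P[i_post] = f / f.sum()
        if m > 0:
            new[i_death, 0] += w @ pd_last
            new[i_post, 1 : n + 1] += w * (1.0 - pd_last)

        # --- death ------------------------------------------------------
        P[i_death, i_death] = 1.0
        new[i_death, 0] += occ[i_death].sum()

        occ = new

    schedule = TransitionSchedule(tuple(states), mats)
    return schedule


def mix_by_assay(
    assay: AssaySpec,
    high_outcomes: tuple[float, float],
    low_outcomes: tuple[float, float],
) -> tuple[float, float]:
    """Population-weighted (cost, QALY) mix of the two risk pathways.

    Returns ``pi * high + (1 - pi) * low`` plus the assay cost applied once
    per patient at model start.  The reference case assumes a perfectly
    accurate test; imperfect sensitivity/specificity would require outcome
    estimates for misclassified pathways, which this model does not carry.
    """
    if assay.sensitivity != 1.0 or assay.specificity != 1.0:
        raise ValueError(
            "sensitivity/specificity below 1 requires misclassification pathway outcomes, "
            "which are not modelled; the reference case assumes a perfectly accurate assay"
        )
    pi = assay.prevalence_high_risk
    cost = pi * high_outcomes[0] + (1.0 - pi) * low_outcomes[0] + assay.cost
    qalys = pi * high_outcomes[1] + (1.0 - pi) * low_outcomes[1]
    return cost, qalys
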