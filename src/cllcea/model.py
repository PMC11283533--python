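"""End-to-end model assembly: inputs, arms, deterministic runs.

:class:`ModelInputs` is the single bundle of numbers the analysis needs —
fitted survival models, the two pathway line plans, utility means and SDs,
and the assay description — and is what the PSA perturbs draw by draw.
:func:`run_deterministic` evaluates the two-arm comparison at the input
means and returns arm-level costs/QALYs plus the incremental statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping

import numpy as np

from . import outcomes as _outcomes
from .markov import ModelConfig, run_cohort, accumulate_outcomes
from .strategies import (
    AssaySpec,
    StrategyArm,
    TreatmentLineSpec,
    build_arm_schedule,
    expand_states,
    mix_by_assay,
)
from .survival import ParametricSurvivalModel


@dataclass(frozen=True)
class UtilityInput:
    """Mean and standard deviation of a health-state utility weight."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError("utility mean must be in [0, 1]")
        if self.sd < 0:
            raise ValueError("utility SD must be >= 0")


@dataclass(frozen=True)
class AssayInput:
    """Assay cost/prevalence/accuracy plus its cost-variability band (+-75%)."""

    cost: float = 1000.0
    prevalence_high_risk: float = 0.5
    sensitivity: float = 1.0
    specificity: float = 1.0
    cost_variability: float = 0.75

    def as_spec(self) -> AssaySpec:
        return AssaySpec(
            cost=self.cost,
            prevalence_high_risk=self.prevalence_high_risk,
            sensitivity=self.sensitivity,
            specificity=self.specificity,
        )


@dataclass(frozen=True)
class LineDef:
    """A treatment line by reference: drug, cost, duration, survival keys."""

    drug_label: str
    cost_per_cycle: float
    pfs_key: str
    os_key: str
    fixed_duration_cycles: int | None = None
    p_minor_ae_per_cycle: float = 0.0
    p_major_ae_per_cycle: float = 0.0
    ae_cost_minor: float = 0.0
    ae_cost_major: float = 0.0


@dataclass(frozen=True)
class ModelInputs:
    """Everything the two-arm model consumes.

    ``survival_models`` maps keys referenced by the line definitions to
    fitted models; ``high_lines``/``low_lines`` are the two risk pathways
    (the comparator reuses the high-risk pathway); ``cost_variability`` is
    the +-fraction applied to every drug/AE cost in the PSA.
    """

    survival_models: Mapping[str, ParametricSurvivalModel]
    high_lines: tuple[LineDef, ...]
    low_lines: tuple[LineDef, ...]
    utilities: Mapping[str, UtilityInput]
    assay: AssayInput = AssayInput()
    cost_variability: float = 0.25
    wtp_threshold: float = 50000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "survival_models", dict(self.survival_models))
        object.__setattr__(self, "high_lines", tuple(self.high_lines))
        object.__setattr__(self, "low_lines", tuple(self.low_lines))
        object.__setattr__(self, "utilities", dict(self.utilities))
        for lines in (self.high_lines, self.low_lines):
            for line in lines:
                for key in (line.pfs_key, line.os_key):
                    if key not in self.survival_models:
                        raise ValueError(
                            f"line {line.drug_label!r} references unknown survival model {key!r}"
                        )

    def utility_means(self) -> dict[str, float]:
        return {name: u.mean for name, u in self.utilities.items()}


def _make_line(line: LineDef, models: Mapping[str, ParametricSurvivalModel]) -> TreatmentLineSpec:
    return TreatmentLineSpec(
        drug_label=line.drug_label,
        cost_per_cycle=line.cost_per_cycle,
        pfs_model=models[line.pfs_key],
        os_model=models[line.os_key],
        fixed_duration_cycles=line.fixed_duration_cycles,
        p_minor_ae_per_cycle=line.p_minor_ae_per_cycle,
        p_major_ae_per_cycle=line.p_major_ae_per_cycle,
        ae_cost_minor=line.ae_cost_minor,
        ae_cost_major=line.ae_cost_major,
    )


def build_arm(inputs: ModelInputs, pathway: str) -> StrategyArm:
    """Materialize one pathway ('high', 'low' or 'comparator') as a StrategyArm.

    The comparator is the high-risk sequence without the assay.
    """
    if pathway not in ("high", "low", "comparator"):
        raise ValueError(f"unknown pathway {pathway!r}")
    line_defs = inputs.low_lines if pathway == "low" else inputs.high_lines
    lines = tuple(_make_line(ld, inputs.survival_models) for ld in line_defs)
    assay = inputs.assay.as_spec() if pathway in ("high", "low") else None
    return StrategyArm(
        label=pathway, lines=lines, assay=assay, utilities=inputs.utility_means()
    )


def run_arm(arm: StrategyArm, config: ModelConfig) -> tuple[float, float]:
    """Build the arm's schedule, run the cohort, and accumulate outcomes.

    The cohort starts entirely in first-line treatment.  Returns the
    discounted (cost, QALYs) for one patient following this pathway,
    exclusive of any assay cost.
    """
    schedule = build_arm_schedule(arm, config)
    initial = np.zeros(len(schedule.states))
    initial[schedule.index("on_treatment_1")] = 1.0
    trace = run_cohort(initial, schedule, config)
    return accumulate_outcomes(trace, schedule, config)


def run_pathway_outcomes(inputs: ModelInputs, config: ModelConfig) -> dict[str, tuple[float, float]]:
    """Discounted (cost, QALYs) for the high- and low-risk pathways.

    The comparator pathway is identical to the high-risk pathway, so only
    two cohort runs are needed.
    """
    return {
        "high": run_arm(build_arm(inputs, "high"), config),
        "low": run_arm(build_arm(inputs, "low"), config),
    }


@dataclass(frozen=True)
class DeterministicResult:
    """Arm-level and incremental outcomes of a single (mean-input) run."""

    cost_intervention: float
    qaly_intervention: float
    cost_comparator: float
    qaly_comparator: float
    wtp_threshold: float

    @property
    def delta_cost(self) -> float:
        return self.cost_intervention - self.cost_comparator

    @property
    def delta_qalys(self) -> float:
        return self.qaly_intervention - self.qaly_comparator

    @property
    def icer(self) -> float | str:
        return _outcomes.icer(self.delta_cost, self.delta_qalys)

    @property
    def nmb(self) -> float:
        return _outcomes.nmb(self.delta_cost, self.delta_qalys, self.wtp_threshold)


def run_deterministic(inputs: ModelInputs, config: ModelConfig) -> DeterministicResult:
    """Evaluate both arms at the input means.

    The intervention arm is the assay-weighted mix of the high- and
    low-risk pathways plus the assay cost; the comparator treats everyone
    along the high-risk sequence with no assay.
    """
    pathways = run_pathway_outcomes(inputs, config)
    cost_i, qaly_i = mix_by_assay(inputs.assay.as_spec(), pathways["high"], pathways["low"])
    cost_c, qaly_c = pathways["high"]
    return DeterministicResult(
        cost_intervention=cost_i,
        qaly_intervention=qaly_i,
        cost_comparator=cost_c,
        qaly_comparator=qaly_c,
        wtp_threshold=inputs.wtp_threshold,
    )
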