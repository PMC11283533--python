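"""Reference-case configuration: costs, utilities, pathways, I/O.

Base-case parameter tables for the assay-guided CLL sequencing analysis
(2021 CAD, British Columbia healthcare-system perspective):

* per-cycle drug costs from Canadian list prices — acalabrutinib $7615 (no
  fixed duration), venetoclax + obinutuzumab $10,400 (average over 12
  cycles), venetoclax + rituximab $7614 (average over 24 cycles),
  idelalisib + rituximab $9754 (no fixed duration),
* standard-gamble health-state utilities with SDs,
* a $1000 risk-stratification assay classifying 50% of patients high-risk,
* 120 one-month cycles, 1.5% annual discounting, $50,000/QALY threshold.

Adverse-event hazards and costs are not published for this model; the
defaults here are synthetic placeholders (see ``AE_DEFAULTS``) and are
ordinary configuration inputs.

This module also reads/writes the YAML strategy-configuration document
used by the CLI and fixture bundles.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .markov import ModelConfig
from .model import AssayInput, LineDef, ModelInputs, UtilityInput
from .survival import KMCurvePoints, ParametricSurvivalModel, fit_parametric

#: Per-cycle drug costs, 2021 CAD list prices.
REFERENCE_COSTS = {
    "acalabrutinib": 7615.0,
    "venetoclax_obinutuzumab": 10_400.0,
    "venetoclax_rituximab": 7614.0,
    "idelalisib_rituximab": 9754.0,
}

#: Fixed regimen durations in cycles; absent drugs treat to progression.
FIXED_DURATIONS = {
    "venetoclax_obinutuzumab": 12,
    "venetoclax_rituximab": 24,
}

#: Health-state utility (mean, SD), standard-gamble elicitation in CLL.
UTILITY_TABLE = {
    "on_treatment_1": (0.78, 0.14),
    "on_treatment_2": (0.71, 0.17),
    "on_treatment_3": (0.65, 0.22),
    "ae_major": (0.69, 0.18),
    "ae_minor": (0.73, 0.17),
    "treatment_free": (0.91, 0.11),
    "progression_post_3l": (0.68, 0.20),
}

#: Synthetic adverse-event defaults (per-cycle hazards, per-event costs in
#: CAD); the published model prints none, so these are free inputs.
AE_DEFAULTS = {
    "p_minor_ae_per_cycle": 0.02,
    "p_major_ae_per_cycle": 0.005,
    "ae_cost_minor": 500.0,
    "ae_cost_major": 5000.0,
}

#: Pathway line plans as (drug_label, curve-key base) per line.  The
#: comparator arm reuses the high-risk sequence.
HIGH_SEQUENCE = (
    ("acalabrutinib", "acalabrutinib_1l"),
    ("venetoclax_rituximab", "venetoclax_rituximab_2l"),
    ("idelalisib_rituximab", "idelalisib_rituximab_3l"),
)
LOW_SEQUENCE = (
    ("venetoclax_obinutuzumab", "venetoclax_obinutuzumab_1l"),
    ("acalabrutinib", "acalabrutinib_2l"),
    ("idelalisib_rituximab", "idelalisib_rituximab_3l"),
)

DEFAULT_ASSAY = AssayInput(
    cost=1000.0, prevalence_high_risk=0.5, sensitivity=1.0, specificity=1.0, cost_variability=0.75
)

DEFAULT_WTP = 50_000.0
DEFAULT_COST_VARIABILITY = 0.25


def default_model_config() -> ModelConfig:
    """Reference run configuration: 120 x 1-month cycles, 1.5% discounting."""
    return ModelConfig(
        n_cycles=120, cycle_length=1.0, discount_rate_annual=0.015, half_cycle_correction=False
    )


def _reference_lines(sequence) -> tuple[LineDef, ...]:
    return tuple(
        LineDef(
            drug_label=drug,
            cost_per_cycle=REFERENCE_COSTS[drug],
            pfs_key=f"{base}_pfs",
            os_key=f"{base}_os",
            fixed_duration_cycles=FIXED_DURATIONS.get(drug),
            **AE_DEFAULTS,
        )
        for drug, base in sequence
    )


def build_reference_inputs(
    survival_models: dict[str, ParametricSurvivalModel],
) -> ModelInputs:
    """Assemble reference-case ModelInputs around a fitted survival registry."""
    return ModelInputs(
        survival_models=survival_models,
        high_lines=_reference_lines(HIGH_SEQUENCE),
        low_lines=_reference_lines(LOW_SEQUENCE),
        utilities={k: UtilityInput(m, s) for k, (m, s) in UTILITY_TABLE.items()},
        assay=DEFAULT_ASSAY,
        cost_variability=DEFAULT_COST_VARIABILITY,
        wtp_threshold=DEFAULT_WTP,
    )


def reference_config_dict(curve_files: dict[str, str]) -> dict:
    """The reference configuration as a plain dict for YAML serialization.

    ``curve_files`` maps curve keys (e.g. ``acalabrutinib_1l_pfs``) to KM
    CSV filenames relative to the bundle directory.
    """

    def line_entry(drug: str, base: str, line_no: int) -> dict:
        return {
            "drug": drug,
            "line": line_no,
            "cost_per_cycle": REFERENCE_COSTS[drug],
            "fixed_duration_cycles": FIXED_DURATIONS.get(drug),
            "pfs_curve": curve_files[f"{base}_pfs"],
            "os_curve": curve_files[f"{base}_os"],
            **AE_DEFAULTS,
        }

    return {
        "model": {
            "n_cycles": 120,
            "cycle_length_months": 1.0,
            "discount_rate_annual": 0.015,
            "half_cycle_correction": False,
        },
        "wtp_threshold": DEFAULT_WTP,
        "cost_variability": DEFAULT_COST_VARIABILITY,
        "assay": {
            "cost": DEFAULT_ASSAY.cost,
            "prevalence_high_risk": DEFAULT_ASSAY.prevalence_high_risk,
            "sensitivity": DEFAULT_ASSAY.sensitivity,
            "specificity": DEFAULT_ASSAY.specificity,
            "cost_variability": DEFAULT_ASSAY.cost_variability,
        },
        "utilities": {k: {"mean": m, "sd": s} for k, (m, s) in UTILITY_TABLE.items()},
        "pathways": {
            "high": [line_entry(d, b, i + 1) for i, (d, b) in enumerate(HIGH_SEQUENCE)],
            "low": [line_entry(d, b, i + 1) for i, (d, b) in enumerate(LOW_SEQUENCE)],
        },
    }


def write_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def load_config(path: str | Path) -> dict:
    config = yaml.safe_load(Path(path).read_text())
    for key in ("model", "assay", "utilities", "pathways"):
        if key not in config:
            raise ValueError(f"{path}: configuration is missing the {key!r} section")
    for pathway in ("high", "low"):
        lines = config["pathways"].get(pathway, [])
        if len(lines) != 3:
            raise ValueError(f"{path}: pathway {pathway!r} must define exactly 3 lines")
    return config


def model_config_from_dict(config: dict) -> ModelConfig:
    m = config["model"]
    return ModelConfig(
        n_cycles=int(m["n_cycles"]),
        cycle_length=float(m.get("cycle_length_months", 1.0)),
        discount_rate_annual=float(m.get("discount_rate_annual", 0.015)),
        half_cycle_correction=bool(m.get("half_cycle_correction", False)),
    )


def load_bundle(bundle_dir: str | Path) -> tuple[ModelInputs, ModelConfig]:
    """Load a fixture/analysis bundle: config.yaml plus KM curve CSVs.

    Curves are fitted on load (Weibull complementary log-log OLS); the
    resulting ModelInputs carries the fit covariances for the PSA.
    """
    bundle_dir = Path(bundle_dir)
    config = load_config(bundle_dir / "config.yaml")

    models: dict[str, ParametricSurvivalModel] = {}
    lines_by_pathway: dict[str, tuple[LineDef, ...]] = {}
    for pathway in ("high", "low"):
        defs = []
        for entry in config["pathways"][pathway]:
            base = f"{entry['drug']}_{entry['line']}l"
            for endpoint, col in (("pfs", "pfs_curve"), ("os", "os_curve")):
                key = f"{base}_{endpoint}"
                if key not in models:
                    points = KMCurvePoints.from_csv(bundle_dir / entry[col])
                    models[key] = fit_parametric(points, family="weibull")
            defs.append(
                LineDef(
                    drug_label=entry["drug"],
                    cost_per_cycle=float(entry["cost_per_cycle"]),
                    pfs_key=f"{base}_pfs",
                    os_key=f"{base}_os",
                    fixed_duration_cycles=entry.get("fixed_duration_cycles"),
                    p_minor_ae_per_cycle=float(entry.get("p_minor_ae_per_cycle", 0.0)),
                    p_major_ae_per_cycle=float(entry.get("p_major_ae_per_cycle", 0.0)),
                    ae_cost_minor=float(entry.get("ae_cost_minor", 0.0)),
                    ae_cost_major=float(entry.get("ae_cost_major", 0.0)),
                )
            )
        lines_by_pathway[pathway] = tuple(defs)

    a = config["assay"]
    inputs = ModelInputs(
        survival_models=models,
        high_lines=lines_by_pathway["high"],
        low_lines=lines_by_pathway["low"],
        utilities={
            k: UtilityInput(float(v["mean"]), float(v.get("sd", 0.0)))
            for k, v in config["utilities"].items()
        },
        assay=AssayInput(
            cost=float(a["cost"]),
            prevalence_high_risk=float(a["prevalence_high_risk"]),
            sensitivity=float(a.get("sensitivity", 1.0)),
            specificity=float(a.get("specificity", 1.0)),
            cost_variability=float(a.get("cost_variability", 0.75)),
        ),
        cost_variability=float(config.get("cost_variability", DEFAULT_COST_VARIABILITY)),
        wtp_threshold=float(config.get("wtp_threshold", DEFAULT_WTP)),
    )
    return inputs, model_config_from_dict(config)
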