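"""The reference-case cost-effectiveness analysis, deterministic and PSA.

Compares assay-guided treatment sequencing (a $1000 test stratifying 50%
of patients high-risk) against treating everyone along the high-risk
sequence, then propagates parameter uncertainty with a probabilistic
sensitivity analysis and summarizes the cost-effectiveness statistics.
"""

from cllcea import (
    CEAConfig,
    PSAConfig,
    cea_summary,
    make_fixture_bundle,
    probability_cost_effective,
    run_deterministic,
    run_psa,
    summarize,
)
from cllcea.config import default_model_config

bundle = make_fixture_bundle(seed=1)
config = default_model_config()

det = run_deterministic(bundle.inputs, config)
print("deterministic run (mean inputs):")
print(f"  intervention ${det.cost_intervention:,.0f} / {det.qaly_intervention:.3f} QALYs")
print(f"  comparator   ${det.cost_comparator:,.0f} / {det.qaly_comparator:.3f} QALYs")
print(f"  dC ${det.delta_cost:,.0f}, dE {det.delta_qalys:.3f} QALYs, "
      f"ICER ${det.icer:,.0f}/QALY, NMB ${det.nmb:,.0f}")

samples = run_psa(bundle.inputs, PSAConfig(n_iterations=200, seed=1), config)
print("\nprobabilistic analysis (200 draws, common parameters across arms):")
print(summarize(samples).round(2).to_string())

cea = cea_summary(samples, CEAConfig(wtp_threshold=50_000.0))
ne, se, sw, nw = cea.quadrant_proportions
print(f"\nratio-of-means ICER ${cea.icer:,.0f}/QALY, NMB ${cea.nmb:,.0f}")
print(f"CE-plane quadrants: {ne:.0%} costlier+better, {se:.0%} dominant, "
      f"{sw:.0%} cheaper+worse, {nw:.0%} dominated")
print(f"probability cost-effective at $50,000/QALY: "
      f"{probability_cost_effective(samples, 50_000.0):.0%}")
print("(a positive NMB / ICER below the threshold means the assay-guided "
      "strategy buys QALYs at an acceptable price)")
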