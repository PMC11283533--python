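# Methods

This note documents the model implemented by `cllcea`: its structure and
assumptions, the parameter defaults and why they were chosen, what the
synthetic data generator does and does not emulate, and the numerical
conventions a re-implementer would need.

## Decision problem and arms

Two strategies for sequencing first-line CLL therapy are compared over a
10-year horizon from a provincial healthcare-system perspective (2021 CAD):

* **Assay-guided arm.** Every patient takes a $1000 genetic test at model
  start. A fraction π = 0.5 is classified high-risk and starts
  acalabrutinib (BTK inhibitor, treat to progression or toxicity),
  followed by venetoclax + rituximab (24 cycles) in second line. Low-risk
  patients start venetoclax + obinutuzumab (12 cycles, then a
  treatment-free interval), followed by acalabrutinib. The base case
  assumes a perfectly accurate test (sensitivity = specificity = 1);
  imperfect accuracy is structurally representable but rejected at run
  time because outcomes for misclassified pathways are not modelled.
* **Comparator arm.** All patients follow the high-risk sequence with no
  test. It is, by construction, bitwise identical to the high-risk pathway
  of the intervention arm — so at π = 1 the arms differ by exactly the
  assay cost and zero QALYs, a structural identity the tests assert.

Idelalisib + rituximab is third line in every pathway. After third-line
progression patients occupy a relapse state (utility 0.68, no drug cost)
until death, governed by the third-line OS model; the same convention is
applied to patients who discontinue third line for a major adverse event,
since no later line exists.

## Survival extrapolation

Inputs are digitized Kaplan-Meier coordinates (time in months, survival
fraction) per line and endpoint. The reference family is the Weibull,
`S(t) = exp(−(t/λ)^k)`, fitted by OLS on `ln(−ln S)` against `ln t`:
deterministic, desk-scale, and exactly invertible on noise-free curves
(the suite checks recovery to 1e-6 relative). Points at S = 0 or 1 are
dropped (log undefined) with a logged warning; at least three usable
points are required. Patient-level curve reconstruction is deliberately
out of scope. The exponential family is the shape = 1 special case with
only the intercept estimated.

The fit covariance is mapped by the delta method to `(ln k, ln λ)` and
stored with the model; it is the sampling distribution used by the PSA.

Per-cycle event probabilities are `p_i = 1 − S((i+1)Δ)/S(iΔ)`; the death
probability comes from the OS model and progression is the PFS excess,
`p_prog = max(0, p_pfs − p_death)`, a competing-risk floor needed because
PFS counts deaths as events. A curve that has reached zero yields
probability 1.

**Known estimator property.** The complementary log-log transform
amplifies fixed-size digitization noise in the deep survival tail, so with
noise held fixed the shape estimate acquires an upward bias as trial size
grows; consistency holds in the joint limit of many subjects and shrinking
noise. At trial scale (n = 500, σ = 0.01) the estimator is unbiased to
within ~0.5% (200-replicate check in the acceptance suite).

## State space and transition construction

Each pathway expands to: per line — `on_treatment_i`, `ae_minor_i`,
`ae_major_i`, and `treatment_free_i` for fixed-duration regimens only —
plus shared `progression_post_3l` and absorbing `death` (12 states for
both reference pathways). Utilities (annual-equivalent weights, standard
gamble): on treatment 0.78 / 0.71 / 0.65 by line, minor AE 0.73, major AE
0.69, treatment-free 0.91, relapse 0.68, death 0.

Transition rules per cycle, on the line-local clock:

* from on-treatment: death (OS hazard), progression to the next line's
  on-treatment state, constant-hazard minor/major AE excursions, and —
  on completing a fixed duration progression-free — the treatment-free
  state. Competing per-cycle probabilities must sum to ≤ 1 or the
  configuration is rejected with the offending cycle named.
* minor AE: a one-cycle excursion (treatment continues, so the state
  carries drug cost plus the AE cost); survivors return to on-treatment.
  Major AE: a one-cycle excursion (AE cost only), then discontinuation and
  advance to the next line. The source tables characterize minor events as
  ones patients continue through and major events as discontinuing; dwell
  time is not specified anywhere, and one cycle is the tractable choice.
* treatment-free interval: the completed line's PFS clock keeps running
  (progression risk persists; drug cost stops; no AEs). Whether the
  progression clock should instead reset is unspecified in the source
  material; the continuing-clock reading is the conservative one.

**Line-local clocks and the matrix contract.** Trial curves are functions
of time since the line began, but the engine contract is one
row-stochastic matrix per model cycle. `build_arm_schedule` resolves this
by running an internal forward pass stratified by time-in-line and
emitting, per cycle, the occupancy-weighted average transition matrix.
Propagating a cohort through those matrices reproduces the stratified
(semi-Markov) cohort exactly, by linearity — *for the canonical initial
distribution* (the full cohort starting line 1 at cycle 0), which is the
only initial condition the analysis uses. Rows of states with zero
occupancy are filled with their age-0 probabilities to keep every matrix
valid. A first-order microsimulation oracle (200,000 subjects) confirms
the aggregation.

## Cohort engine, discounting, accrual

Occupancy is propagated as `m_{t+1} = m_t P_t`; conservation holds to
1e-12 per cycle and absorbing-state occupancy is non-decreasing.
Discounting uses the annual discrete rate with fractional monthly
exponents, `d(t) = 1.015^(−t/12)` (t in months), per Canadian guidance;
continuous compounding was considered and rejected. Costs accrue as
cycle-start occupancy × state cost × discount; QALYs as occupancy ×
utility × Δ/12 × discount (utilities are annual weights). A half-cycle
correction (trapezoid of adjacent occupancies) is implemented behind a
config flag but **off** in the reference case, since the source analysis
does not state one; the flag is echoed in run manifests. The assay cost is
applied once at cycle 0, where the discount factor is exactly 1.

## Probabilistic sensitivity analysis

1000 draws in the reference case. Per draw:

* utilities ~ Beta moment-matched to (mean, SD); infeasible moments
  (SD² ≥ mean(1−mean)) are rejected at configuration time with the
  utility named; SD = 0 degenerates to the constant mean.
* each drug/AE cost ~ Uniform[0.75c, 1.25c]; the assay cost ~
  Uniform[0.25c, 1.75c] ("±25% / ±75%" read as uniform bounds — the
  source names no distribution; a gamma alternative was considered and
  not adopted as reference).
* survival coefficients ~ MVN on `(ln k, ln λ)` with the fit covariance.

Both arms see identical parameters per draw by default (common random
numbers — standard PSA practice); an independent-sampling mode exists
because some published scenario behaviour (negative ΔC at 100% high-risk
prevalence) is only explicable by independent arm sampling. The mode and
seed are echoed in every output header. Draws producing an invalid
schedule (competing probabilities > 1) are resampled from a fresh stream,
counted, and capped at 10× the iteration count.

Reported 95% CIs are `mean ± 1.96 × sample SD` (n−1 denominator) — the SD
of the PSA distribution, not the standard error of the mean, following the
source's stated formula. Whether that source meant SDs or SEs is
ambiguous (its interval widths are mutually inconsistent under either
reading); the convention used here is recorded in output metadata. The
probabilistic ICER is the ratio of mean increments, ΔC̄/ΔĒ, not the mean
of per-draw ratios — the only convention consistent with the published
headline figures. No CI is reported for the ICER itself: the published
ICER interval cannot be reconstructed from the ΔC and ΔE intervals under
any standard formula, so this package reports the ΔC and ΔE intervals and
the CEAC instead.

Ties and degenerate increments: |ΔE| < 1e-9 QALY yields the label
"undefined (ΔE ≈ 0)" unless ΔC < 0 (then "dominant"); in the CEAC a
ΔE = 0 draw counts as cost-effective iff it saves money (the NMB > 0 rule,
which subsumes the tie). CE-plane quadrants assign ΔE = 0 to the
"not more effective" side and ΔC = 0 to "not more costly". The CEAC grid
default is $0–150,000 in $1,000 steps.

## Synthetic trial generator

The published analysis digitized KM figures from four external trial
programmes; none of that data is redistributable, so the generator
produces data with the same *statistical structure*: Weibull event times
via inverse-CDF on seeded uniforms; exponential drop-out (rate
0.005/month) plus administrative censoring at 48 months (~4 years of
follow-up, typical of the source trials); product-limit estimation;
monthly-grid digitization with σ = 0.01 Gaussian read-off noise, clamped
to [0,1] and re-monotonized by running minimum (plausible for manual plot
extraction). Simulated arm sizes are 300/250/200 subjects for
first/second/third-line trials.

Generating Weibull truths (shape, scale in months) per line:

| curve | PFS | OS |
|---|---|---|
| acalabrutinib, 1L | (1.3, 13) | (1.2, 25) |
| venetoclax + obinutuzumab, 1L | (1.4, 26) | (1.2, 33) |
| venetoclax + rituximab, 2L | (1.3, 9.5) | (1.2, 18) |
| acalabrutinib, 2L | (1.3, 24) | (1.2, 29) |
| idelalisib + rituximab, 3L | (1.2, 8) | (1.1, 14) |

These are explicitly synthetic and reproduce no trial's curves. They were
chosen, once, to satisfy the generator's documented construction contract:
median PFS ordering 1L > 2L > 3L within each pathway, OS above PFS per
line, better first-line outcomes for low-risk disease, and an overall
regime matching the analysis the model exists for — an aggressive-disease
cohort (QALY totals of order 1–2 over ten years) in which assay-guided
sequencing is modestly costlier and more effective, so the ICER is a
positive finite number rather than a dominance label. Across bundle seeds
this yields ΔC of a few thousand to ~$15k and ΔE ≈ 0.3–0.4 QALYs.

What passing tests therefore show: the pipeline's arithmetic, invariants
and conventions are correct under data with trial-like structure. What
they do not show: anything about the actual published trials — real KM
curves are not Weibull, censoring is not exponential, adverse-event
hazards are not constant, and the synthetic effect sizes are not the
published ones.

Adverse-event inputs are not printed in the source tables at all; the
shipped defaults (minor 0.02/cycle at $500, major 0.005/cycle at $5,000)
are synthetic placeholders and ordinary configuration inputs.

## Numerical conventions and problem sizes

* Row-stochasticity tolerance 1e-12; rows are built with the stay
  probability as the exact complement and normalized by the row sum.
* Monte-Carlo oracle checks use a 3-SE-per-cell band with multiplicity
  control (≤ 0.5% of the ~1500 correlated cells may exceed 3 SE, hard cap
  5 SE): a strict 3-SE maximum over that many cells would reject any
  correct implementation.
* Test problem sizes: 200,000-subject microsimulation for the cohort
  oracle; 200 replicates of n = 500 for parameter recovery; 1000-draw
  degenerate PSA for the determinism check — each chosen as the smallest
  size that makes the corresponding band tight enough to be informative.
* All currency is CAD as floats; no currency-year conversion.
* Seeds: every stochastic stage takes an explicit seed; PSA streams are
  `SeedSequence(seed, spawn_key=(stream, draw))`, so draws are
  reproducible individually and across resampling attempts.

## Limitations

* Emitted transition matrices are exact only for the canonical initial
  distribution; reusing a schedule with a different starting vector is a
  (documented) approximation.
* The AE model (constant hazards, one-cycle dwell, cost as a single
  per-cycle charge) is deliberately minimal; dose reductions, drug
  wastage, and time-on-treatment vs PFS distinctions are out of scope.
* Misclassification, budget impact, equity weighting, and frontier
  analysis across more than two strategies are out of scope.
* The cloglog fit downweights nothing: heavy digitization noise in deep
  tails biases the shape upward (see above); flexible families
  (Royston-Parmar splines) are out of scope.
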