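# Methods

## Scope and perspective

`medlysim` implements a cost-utility analysis comparing a heart-failure
telemonitoring program with standard ambulatory care from the public-payer
perspective. Costs are 2019 Canadian dollars; no currency conversion or
inflation indexing is performed. Effects are quality-adjusted life years
(QALYs). Costs and QALYs are discounted at 1.5%/year and accrued monthly
over a 25-year horizon (300 cycles) without half-cycle correction — with
one-month cycles the correction is negligible relative to parameter
uncertainty.

## Virtual cohort

Patients are synthesised from 19 characteristics (demographics, etiology,
five drug classes, LVEF, NYHA class, vitals, six laboratory values, weight,
diuretic dose, ICD status) with published marginal moments from a 315-patient
ambulatory program cohort. Generation is NORTA-style: a latent standard
normal vector with a user-configurable correlation matrix (Cholesky
factored), back-transformed per characteristic:

* continuous: `mean + sd·z`, clipped to physiological bounds
  (LVEF [1,100]%, SBP [60,250] mmHg, sodium [110,160] mEq/L,
  hemoglobin [4,22] g/dL, lymphocytes [1,60]%, cholesterol [50,500] mg/dL,
  urate [1,20] mg/dL, weight [30,250] kg, furosemide-equivalent dose
  [0,2000] mg/day, age [18,100] y);
* binary: indicator `z < Φ⁻¹(p)`;
* NYHA class: ordinal thresholding of the latent value at the normal
  quantiles of the observed cumulative class proportions
  (44/210/303 of 304 → cutpoints −1.059, 0.498, 2.716), which reproduces
  the observed distribution including the rare class IV rather than
  rounding a normal with the printed mean 2.36/SD 0.59.

The source study's own inter-characteristic correlation matrix (derived
from four external HF cohorts) is not distributed; the packaged default is
a sparse, clinically plausible stand-in (age–SBP +0.20, LVEF–NYHA −0.30,
urate–allopurinol +0.30, etc.) and any user matrix is accepted, with an
optional nearest-PSD repair (eigenvalue clipping, logged adjustment norm).

Known generation biases, by construction: clipping shifts means of
marginals with substantial out-of-bounds mass — furosemide dose
(mean 99.57, SD 123.93 mg/day) has ~21% of its normal mass below zero, so
its generated mean is ~114 mg/day (the exact clipped-normal expectation;
the test suite checks against that closed form). Correlations involving
binary or clipped characteristics attenuate relative to the latent values;
tests assert recovery only for continuous unclipped pairs.

## Survival layer

Each patient receives a proportional-hazards score `β'(x − x̄)` once, at
baseline, from a packaged Cox-style coefficient block whose log hazard
ratios follow the commonly cited multivariate ambulatory-HF survival model
(e.g. +0.47 per NYHA class, −0.030 per LVEF point, −0.42 for
beta-blockade, +0.077 per mg/dL urate). Covariates are centered at the
cohort means, so the baseline annual hazard `h₀` is the cohort-average
hazard; the per-patient hazard `h᎐ᵢ = h₀·exp(scoreᵢ)` is constant over the
patient's lifetime (exponential survival per patient; no aging update —
no update rule is published, and the score is stated to be computed once
per generated patient). The coefficient block is plain configuration: any
alternative Cox-style score can be swapped in.

`h₀` is not taken from literature; it is **calibrated** by root-finding
(Brent, fixed random streams, tolerance 10⁻⁴) so that the standard-care
arm's mean discounted QALYs equal the published comparator value, 4.95.
With the packaged coefficients this lands near 0.116/year and gives a
between-patient score SD of ~0.81. The mortality treatment effect
multiplies the hazard (RR 0.81), so treated survival is `S(t)^RR` exactly;
RR on the hazard scale keeps probabilities in [0,1] and matches
proportional-hazards semantics.

Subgroup scenarios (below) reuse the hazard calibrated on the mixed
reference cohort; recalibrating each subgroup to the same anchor would
erase exactly the between-class survival differences of interest.

## Disease engine

States: NYHA I–IV (community), index hospitalization, rehospitalization,
dead (absorbing). Event order within a cycle: death → discharge →
(re)admission → NYHA transition → accrual. Details and rationale:

* **Death.** Community cycles use the survival-layer monthly probability
  (× RR_mort in the telemonitoring arm). Hospital cycles replace it with a
  flat in-hospital monthly probability (default 0.02; no point estimate is
  published with the cited source, and larger values create a
  hospitalization–mortality coupling inconsistent with the published
  one-way sensitivity pattern, where incremental QALYs barely move across
  the hospitalization-RR range).
* **Hospitalization.** Before any admission, the monthly probability is
  class-specific (0.0152/0.024/0.024/0.154). After any admission, the
  30-day readmission probability (0.159/cycle) applies **persistently**,
  including hospital-to-hospital chains (`readmission_scope="persistent"`;
  a strict first-post-discharge-cycle window is available as
  `"first_cycle"`). The persistent reading follows the clinical framing of
  hospitalization as a lasting change in the natural history of HF, and is
  the only structure that reproduces the published scale of lifetime
  hospitalization-linked costs (~10 admissions and ~Can$90k per comparator
  patient, as implied by the published one-way cost sensitivities).
* **Treatment effect on admissions.** RR_hosp (0.753) scales the
  **index** (class-specific) admission probability by default;
  `rr_applies_to_readmission=True` extends it to readmissions. Index-only
  is the package default because it best reproduces the published one-way
  ICER bounds; the published deterministic tables are not jointly
  consistent with any single choice (see Limitations).
* **Class dynamics.** Patients hold their admission class through hospital
  cycles and return to it at discharge; community patients (not admitted,
  not discharged that cycle) move by the monthly 4×4 transition matrix,
  cumulated in column order I→IV.
* **Accrual.** Community cycles cost the class-specific monthly ambulatory
  total (ED + GP + outpatient + drug; the drug component only at age ≥65,
  re-evaluated as patients age 1/12 year per cycle; class IV equals class
  III except the drug component). Hospital cycles cost the mean admission
  cost (Can$8,908; mean length of stay 5.9 days fits within one cycle) and
  subtract the 0.059 hospitalization disutility from the class utility.
  Telemonitoring adds Can$102.50 at entry (Can$102,500 site cost amortized
  over 1,000 patients) plus monthly operations (Can$44.67) and kit rental
  (Full Kit 67.56, Bring-Your-Own-Phone 18.87, Bring-Your-Own-Everything
  3.80), also during hospital cycles (enrolment continues). Utility
  accrues as `u/12` per cycle, discounted at cycle start.
* **Common random numbers.** Each patient's two arms consume one fixed
  uniform stream (3 draws per cycle, consumed every cycle whether used or
  not), so a null intervention (RRs = 1, program costs 0) yields
  identical trajectories arm-to-arm — the engine's primary oracle. A
  per-patient reference implementation and the vectorized cohort engine
  implement identical semantics; tests cross-validate them path by path.

The deterministic reference case simulates 1,000 patients with kit types
allocated 2:1:2 (FK:BYOP:BYOE) by largest-remainder apportionment and a
seeded shuffle (exact counts, no allocation noise). Monte Carlo standard
errors are sd/√n over patients.

## Probabilistic sensitivity analysis

1,000 iterations; each draws one parameter set, holds it fixed, and reruns
the full paired cohort simulation with the *same* patient-level streams —
the plane and CEAC therefore isolate second-order (parameter) uncertainty.
Distributions follow the published table assignments:

* gamma by method of moments for the admission cost (mean 8,908,
  SD 16,867 → shape 0.279) and as multiplicative mean-1 factors on the
  ED/outpatient/drug cost components (coefficients of variation from the
  published unit-cost SDs);
* beta for utilities, hospitalization probabilities, readmission
  probability and disutility, with mean at the point estimate and SD =
  (range width)/3.92; printed ranges with one endpoint at the point
  estimate are used as-is; zero-width ranges degenerate to fixed values;
* Dirichlet for each transition row (concentrations = row × 500; the
  effective sample size is not published — 500 reflects a large source
  trial and is configurable; zero cells floored at 10⁻⁶);
* log-normal for both RRs (`μ = ln point`,
  `σ = (ln upper − ln lower)/3.92`).

General-practitioner fees and program costs are fixed. A
maximum-likelihood negative-binomial fitter (`fit_negbin_mle`, mean/size
parameterization, Poisson fallback for equidispersed counts) and a
utilization-based costing route (`count × unit cost / 6`) are provided for
users with raw utilization counts; the raw counts behind the published
fits are not available, so the default PSA varies unit costs with
utilization fixed at the published medians.

The CEAC reports, at each willingness-to-pay λ in a 0–100,000 grid (step
1,000), the fraction of iterations with positive net monetary benefit
λ·ΔQ − ΔC. Degenerate PSA (all specs fixed) reproduces the deterministic
run exactly and is tested as the module's oracle.

## Scenarios

* **NYHA subgroups** (classes I–III; class IV had one observed patient):
  the latent class assignment is pinned while all other covariates keep
  their correlated heterogeneity; the pin flows into class-conditional
  parameters and the survival score's class covariate.
* **Deployment mixes** 1:0:0, 1:4:5, 0:0:1: only program costs change;
  under common random numbers incremental QALYs are bit-identical across
  mixes and only ΔC moves.
* **One-way effectiveness**: RR_mort ∈ {0.70, 0.94}, RR_hosp ∈
  {0.63, 0.88}, deterministic, with dominance classification.

## Numerical choices

Probabilities exceeding 1 after RR scaling are clamped with a warning
(cannot occur at the packaged values). Calibration objectives are step
functions of `h₀` (finite cohorts, fixed streams); the root lands within
one Monte Carlo step of the anchor (±0.01 QALYs at n = 1,000). ICERs are
undefined (flagged) at ΔQ = 0, and negative ICERs are always accompanied
by a dominance classification. The vectorized engine simulates all
(iteration × patient) paths in one pass: the 1,000 × 1,000 PSA runs in
about a minute on one CPU.

## What the synthetic cohort does and does not show

The generator reproduces marginal moments (exactly, up to documented
clipping bias), the observed NYHA distribution, and whatever correlation
structure it is given. It does not reproduce the source cohort's true
joint distribution (the original correlation matrix is not distributed),
skewed marginals (everything latent is Gaussian), or the missing-data
structure of the observed table. Passing tests therefore certify the
generation mechanism and the downstream pipeline, not distributional
fidelity to the original patients.

## Limitations

* The published deterministic tables are mutually constraining in a way no
  single engine structure expressible from the published inputs satisfies:
  the one-way cost sensitivities imply ~Can$88k of RR-scalable
  hospitalization cost per comparator patient (persistent readmission
  regime), while the published reference-case ΔC (Can$5,011) and the
  class-wise cost gradient imply substantially less. This package's
  defaults reproduce the comparator cost/QALY levels, the incremental
  QALYs, the CEAC region and the one-way ICER bounds, but yield a
  reference ΔC near Can$15k (ICER ≈ Can$22k/QALY vs the published
  Can$8,850) and a non-monotone ICER pattern across NYHA subgroups.
* Treatment effects are constant over lifetime; enrolment never ends;
  quality-of-life gains from telemonitoring itself are excluded (both
  arms share utilities), matching the source assumptions.
* The survival coefficient block is a documented stand-in for the cited
  Cox model's exact vintage; absolute survival is anchored by calibration,
  so only the *relative* risk structure depends on it.
* In-hospital mortality (0.02/cycle) is an assumption — no value is
  published with the citation — and is fully configurable.
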