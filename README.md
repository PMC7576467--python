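# medlysim

Patient-level cost-utility microsimulation of nurse-led telemonitoring for
ambulatory heart-failure patients, from the perspective of a public health
care payer (costs in 2019 Canadian dollars).

Heart failure carries high mortality and frequent, expensive
hospitalizations. Telemonitoring programs — daily weight, blood pressure and
symptom readings triaged by a validated algorithm and a nurse coordinator —
reduce all-cause mortality (relative risk 0.81, 95% CI 0.70–0.94) and
all-cause hospitalization (RR 0.753, 95% CI 0.634–0.879). Whether those
benefits justify the program's equipment and operating costs over a
patient's remaining lifetime is a question for decision modelling: this
package answers it with a first-order Monte Carlo (individual-level)
state-transition model that health-economics analysts can reconfigure,
extend and audit.

## The model

Virtual patients carry 19 correlated clinical, pharmacological, device and
laboratory characteristics, generated NORTA-style: latent multivariate
normal draws (Cholesky-factored correlation matrix), back-transformed to
each characteristic's marginal — continuous `μ + σz` (clipped to
physiological bounds), binary by latent thresholding at `Φ⁻¹(p)`, and NYHA
functional class I–IV by thresholding against the observed class
distribution (44/166/93/1 of 304).

Each patient moves monthly through 7 mutually exclusive states — NYHA I–IV,
index hospitalization, rehospitalization, dead — for up to 25 years with no
half-cycle correction. Mortality follows a Seattle-Heart-Failure-Model-style
proportional-hazards score computed once at baseline,

&nbsp;&nbsp;&nbsp;&nbsp;`h_i = h₀ · exp(β'x_i)`,&nbsp;&nbsp;
`p_month = 1 − exp(−h_i · RR_mort / 12)`,

with `h₀` calibrated so the standard-care arm's mean discounted lifetime
QALYs hit the published comparator anchor (4.95). Hospitalization risk is
class-specific until a first admission; after any admission the 30-day
readmission probability (0.159/cycle) applies persistently —
hospitalization marks a lasting change in the disease trajectory. Cycles
accrue class utilities (0.81/0.72/0.59/0.508, minus 0.059 when
hospitalized), class-specific ambulatory costs, Can$8,908 per admission,
and — in the telemonitoring arm — program costs (Can$102.50 amortized fixed
cost plus Can$44.67 operations and a kit-dependent equipment rental per
month). Both arms of a patient share one random-number stream (common
random numbers), and everything is discounted at 1.5%/year.

Outputs are the standard cost-utility quantities: ΔC, ΔQ, the incremental
cost-effectiveness ratio ΔC/ΔQ with dominance classification, net monetary
benefit, and — from a 1000-iteration probabilistic sensitivity analysis
with gamma/beta/Dirichlet/log-normal parameter uncertainty — the
cost-utility plane and cost-effectiveness acceptability curve (CEAC).

## Worked example

```python
from medlysim import CostUtilityModel

model = CostUtilityModel.from_moments(n=1000, seed=1)   # synthetic cohort
res = model.fit(seed=1)                                  # calibrate + simulate
print(res.summary())
```

```
Cost-utility microsimulation results
======================================================================
patients: 1000    horizon: 300 months    discount rate: 1.5%/yr
baseline annual hazard: 0.1162
----------------------------------------------------------------------
arm             cost (CAD)      MCSE     QALYs    MCSE
standard            98,291     3,505      4.95    0.14
medly              113,818     3,856      5.65    0.15
----------------------------------------------------------------------
incremental cost:        15,527  (MCSE 1,927)
incremental QALYs:        0.703  (MCSE 0.072)
ICER: 22,081 CAD/QALY   [cost_effective_quadrant]
======================================================================
```

Standard care costs ~Can$98k per patient over 25 years (dominated by
repeated hospitalizations) and yields 4.95 discounted QALYs. Telemonitoring
extends life (+0.70 QALYs, mostly through the mortality effect) and avoids
admissions, but pays program costs and the health-care costs of the added
life-months, for a net Can$15.5k — about Can$22k per QALY gained, well
under the conventional Can$50,000/QALY willingness-to-pay threshold.
Monte Carlo standard errors (sd/√n) describe patient-level heterogeneity.

Uncertainty and scenarios:

```python
psa = res.run_psa(n_iterations=1000)
psa.acceptance_at(50_000)        # probability cost-effective at Can$50k/QALY
res.plot_ceac(psa)

from medlysim.scenarios import ScenarioSpec, run_nyha_scenario, run_oneway
run_nyha_scenario(3, ScenarioSpec(seed=1))       # all-NYHA-III cohort
run_oneway("rr_mortality", 0.70, ScenarioSpec(seed=1))
```

or from the shell:

```bash
medlysim --seed 1 run-reference
medlysim --seed 1 run-psa --iterations 1000
medlysim --seed 1 scenario deployment --ratio 1:0:0
```

All inputs live in a YAML config (see
`src/medlysim/data/medly_reference.yaml`); pass `--config` or
`load_config(path)` to override any subset.

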