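# uiascreen

Cost-effectiveness modelling of population-wide screening for unruptured
intracranial aneurysms (UIAs).

About 3 % of adults harbor a UIA; rupture causes aneurysmal subarachnoid
hemorrhage (SAH), which kills or disables close to half of those it strikes.
Blood-based screening tests for UIAs are under development, which raises a
health-economic question: **at what price, and under what conditions, would
screening an entire population once at age 40 be worth it?** This package
answers that question for analysts working in the cost-utility framework:
it implements the full decision model — a seven-state annual-cycle Markov
cohort model comparing population-wide screening (PWS) against standard of
care (SOC) — together with the screening-test cascade, surveillance-imaging
cost schedules, discounting, incremental cost-effectiveness ratios (ICERs),
test-price threshold analysis against willingness-to-pay (WTP) levels,
prevalence sweeps, and probabilistic sensitivity analysis (PSA).

## Model core

States: four "healthy" states (no aneurysm / undetected carrier / carrier
under imaging follow-up / false-negative screen), moderate disability,
severe disability, and death (absorbing). Utilities follow the modified
Rankin scale collapsed to four classes: u = 0.93, 0.76, 0.235, 0. A cohort
entering at age 40 evolves through row-stochastic, age-dependent transition
matrices P_t until extinction; each arm accrues

    Cost = Σ_t  d_t · ( x_t · c_t + event costs ),
    QALY = Σ_t  d_t · ( x_t · u ),      d_t = 1.03^(−t),

where x_t is the state-occupancy row vector. The two arms share mortality,
rupture, detection, and treatment dynamics; they differ in the entry
cascade (test sensitivity/specificity sorting the cohort into TP/FP/FN/TN,
confirmatory MRA, DSA and prophylactic treatment for treat-indicated
positives) and in the screening-test charge. Comparing arms gives

    ICER = (Cost_PWS − Cost_SOC) / (QALY_PWS − QALY_SOC),

and the threshold analysis inverts ICER(price) = WTP for the test price,
exploiting that the ICER is affine in price.

Everything is driven by a schema-validated YAML document; a calibrated
synthetic life table (healthy life expectancy at 40: 41.3 years) and two
complete parameter profiles are generated by the package itself. See
`docs/methods.md` for conventions, the calibration, and its limits.

## Worked example

```bash
uiascreen --out results icer
uiascreen --out results threshold --wtp 50000
```

or, in Python:

```python
from uiascreen import (make_lifetable, make_default_params,
                       evaluate_icer, threshold_price)
from uiascreen.cea import _factory_from_params

lifetable = make_lifetable()                      # calibrated synthetic table
params = make_default_params("calibrated")        # default parameter profile
soc, pws, icer = evaluate_icer(params, lifetable)
print(soc, pws, icer.icer)
```

With the default (calibrated) profile this prints, per cohort member:

```
SOC:  cost €3,138.72   effect 21.494 QALYs
PWS:  cost €22,549.42  effect 21.612 QALYs   (perfect test priced at €811.30)
ICER: €165,395.21 per QALY gained
```

Reading: screening the whole population with a perfect test priced like an
MRA exam (€811.30) buys 0.117 extra QALYs per person at €19,410.70 extra
cost — €165,395 per QALY, far above common WTP levels, so screening at that
price is not cost-effective. The threshold command then solves for the
price at which it would be:

```
wtp 50000  ->  threshold_price €229.19  (attainable: true)
```

i.e. at a WTP of €50,000 per QALY the test may cost at most about €229 and
remain cost-effective; at €20,000 and €100,000 the solved thresholds are
€77.85 and €481.41. There is no non-negative price at which screening
becomes dominant (cheaper *and* more effective). `prevalence` and `psa`
subcommands explore higher-risk populations and joint parameter
uncertainty; `synth` regenerates all synthetic inputs.

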