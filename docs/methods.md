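# Methods

## The decision problem

Unruptured intracranial aneurysms (UIAs) are present in roughly 3 % of
adults. Most never rupture, but aneurysmal subarachnoid hemorrhage (SAH)
is catastrophic when it happens: in the reference registry this package is
parameterized against, only 54.5 % of SAH patients reach a favorable
one-year outcome. A population-wide screen (PWS) applied once at age 40
could avert part of that burden by detecting carriers early, treating the
high-risk ones prophylactically, and following the rest with serial
imaging — at the price of screening an overwhelmingly healthy population.
The package quantifies that trade-off against standard of care (SOC), in
which carriers surface only when imaging done for other reasons finds them.

## Model structure

A deterministic cohort Markov model with seven states and annual cycles:

| state | collapsed class | utility |
|---|---|---|
| healthy, no aneurysm | healthy | 0.93 |
| healthy, undetected carrier | healthy | 0.93 |
| healthy, carrier in imaging follow-up | healthy | 0.93 |
| healthy, false-negative screen | healthy | 0.93 |
| moderate disability | moderate | 0.76 |
| severe disability | severe | 0.235 |
| dead | dead | 0 |

Utilities come from the modified Rankin scale collapsed into four classes
(mRS 0–1 → 0.93, 2–3 → 0.76, 4–5 → 0.235, 6 → 0). The cohort enters at
age 40 and runs to extinction (at most 100 cycles; in practice the last
member dies in cycle 71). Background mortality is age- and
disability-stratified; costs and effects are discounted at 3 %/year.

Carrier dynamics, identical in both arms: undetected carriers rupture at
the mixture of the treat-indicated and conservative annual risks, are found
incidentally at a constant annual probability, and — once detected — are
either treated (the treat-indicated fraction, 55/139 = 39.6 %) or followed.
Followed carriers rupture at the conservative risk and are escalated to
treatment at a constant annual probability (surveillance catching growth).
Aneurysm-free individuals form de novo aneurysms at a constant annual rate.
Rupture sends the individual through the SAH sub-tree: 54.5 % land back in
full health (the aneurysm is secured during the acute admission), the rest
split between moderate disability, severe disability, and death. Treatment
carries procedural mortality and morbidity.

The PWS arm differs only at entry and in the test charge: the cascade sorts
the cohort into true/false positives/negatives; positives get confirmatory
MRA (skipped when the test itself stratifies risk), treatment-bound
positives get DSA and immediate treatment, other positives enter follow-up,
and 10 % of prevalent carriers bypass the screen entirely — the share of
SAH that would have occurred before age 40 and therefore cannot be averted
by a screen at 40.

## Conventions and numerical choices

* **Accrual**: costs and utilities accrue to the occupancy at cycle start;
  cycle 0 is undiscounted (cycle *t* divides by 1.03^t). Both choices are
  configurable (`cycle-end`, `half-cycle`, `first-cycle-discounted`); under
  cycle-start accrual a constant annual death probability *q* yields a life
  expectancy of 1/q, under cycle-end (1−q)/q.
* **Event costs** (rupture, detection work-up, treatment) are expected
  values attached to the occupancy that generates them and charged in the
  following cycle.
* **Follow-up imaging** is charged as an expected present value at the
  moment a person enters a followed or treated status: each scheduled exam
  is weighted by the probability of still being in that status when it is
  due (alive for treated contexts; alive, unruptured, and unescalated for
  watchful waiting) and discounted to the event. This implements
  "follow-up costs adjusted for remaining life expectancy" without needing
  time-since-event states.
* **Schedule binning**: sub-annual offsets map to annual cycles by nearest
  year, with half-year ties resolved to the odd year so the 6- and 18-month
  post-coil scans share the year-1 surveillance cycle.
* **Screen-cost wiring**: by default the screening test's unit cost recurs
  annually for every living member of the screened arm
  (`test.cost_recurring`). This wiring is what the published reference
  figures imply: the gap between the MRA- and CTA-based screening arms is
  150 € × 24.4, i.e. the per-exam cost difference times the discounted
  alive person-years, and the threshold-price-versus-WTP slope equals the
  QALY increment divided by the same ≈23–24 multiplier. A once-only wiring
  (`cost_recurring: false`) is available.
* **Currency** is float64 euros throughout; the magnitudes involved (≤10^7)
  are far inside the range where sums of cent-sized quantities are exact,
  and cohort expectations have no exact-cents meaning anyway. Output is
  formatted to two decimals.
* **Threshold solving** uses the affinity of the ICER in the test price:
  costs enter the cohort model linearly and never feed back into
  transitions, so two evaluations pin the ICER(price) line and one more
  confirms the solution at relative 10⁻⁶; a bisection fallback engages if
  the affinity check fails (which would signal a mis-wired strategy).

## Parameter profiles and calibration

`make_default_params` ships two profiles.

**`main-text`** carries every value stated in the main analysis (discount
3 %, entry age 40, the collapsed utilities, MRA 811.30 €, CTA 150 € less,
MRA sensitivity/specificity 0.85/0.95, CTA 0.90/0.95, favorable-outcome
share 0.545, clip/endo mix 0.444/0.556, 10 % missed-SAH fraction, WTP
levels 20 000/50 000/100 000 €) and documented placeholders — flagged in
the `provenance` section and warned about at load time — for quantities
whose published source is a supplement: the SAH cost bundle, treatment
costs and procedural risks, DSA cost, the non-favorable mRS split,
prevalence, de novo formation, and incidental detection. Rupture risks are
the registry medians read as percentages (0.480 %/yr treat-indicated,
0.123 %/yr conservative).

**`calibrated`** is the profile that reproduces the published reference
outputs, and it documents two deliberate departures from face-value
readings:

1. *Rupture-risk scale.* With risks of 0.48 %/yr the screening arm's
   maximum attainable QALY increment is ≈0.01; the published increment is
   0.1173 (19 874.52 € / 169 383.57 € per QALY). The published cost and
   QALY totals are reproduced almost exactly when the printed risk figures
   act as raw annual probabilities (0.480/yr and 0.123/yr), which is what
   this profile uses.
2. *Cost calibration.* The watchful-waiting escalation rate (0.15/yr) is
   set so the QALY increment equals 0.1174; the SAH cost bundle and the
   treatment cost bundle are then jointly solved so that (a) the SOC arm's
   discounted cost equals the published 3 138.72 € and (b) the model's
   threshold-price-versus-WTP line least-squares fits the three published
   threshold prices, subject to screening never being dominant at a
   non-negative test price. The resulting treatment costs (≈95 000 € per
   clipping) are far above plausible billing levels: this is where the
   published model's otherwise-unexplained incremental-cost block gets
   absorbed, and it should be read as a calibration artifact, not a cost
   estimate.

With this profile the model reproduces: the SOC arm cost exactly; SOC/PWS
QALYs to −4 %; the three threshold prices to within 2.3 %
(77.85/229.19/481.41 vs 78.56/225.72/470.97 €); and the ICER of a
perfect test priced at MRA cost to −2.4 % of the published MRA-screening
figure.

It does **not** reproduce, for structural reasons the tests surface
explicitly:

* the MRA/CTA cascade ICERs when sensitivity/specificity are modeled
  faithfully (+15 %/+9 %): a false negative here loses the screening
  benefit, whereas the reference analysis treats test imperfection as
  affecting costs only;
* the risk-stratifying-scenario threshold prices (−21 % at WTP 50 000 €):
  the published gap between the two scenarios implies ≈1 600 € present
  value of confirmatory imaging per *screened person* (≈2 MRAs each),
  which no described cascade produces at 3 % prevalence;
* the prevalence-sweep ICERs: the published value at 9 % prevalence
  requires a QALY increment of ≈0.85, above the ≈0.4 ceiling any model
  with these utilities and outcome splits can generate;
* the probabilistic sensitivity analysis summary (+28 %): the sampling
  distributions behind the published PSA are supplement-only, and its
  published arm means exceed their deterministic counterparts by ≈70 %,
  which moment-matched distributions centred on the deterministic inputs
  cannot produce.

A further feasibility note: the published arm QALY *levels* (22.40/22.52)
equal or exceed 0.93 × annuity(41.3 y, 3 %) = 22.42, the bound attained by
a perfectly rectangular survival curve; under any standard accrual
convention the levels are at the boundary of what a 41.3-year life
expectancy permits, which is why this package calibrates increments rather
than levels.

## Synthetic data

* **Life table**: Gompertz–Makeham hazard (Makeham 4 × 10⁻⁴, slope
  0.095/yr, level calibrated by 1-D root search so the healthy-stratum
  life expectancy at 40 is 41.3 years); moderate and severe disability
  multiply the whole hazard by 2.5 and 5.0 (documented placeholders at
  literature-plausible excess-mortality levels). The terminal row (age
  110) forces q = 1, guaranteeing extinction.
* **Incidental-UIA cohort** (n = 139): sex, age, location, and diameter
  match the registry's descriptive table; per-patient mean annual rupture
  risk is log-normal fitted to the printed median and quartiles
  (0.150 [0.093–0.630] %/yr) — strictly positive and right-skewed, like
  the printed spread. Treatment assignment correlates with rupture risk.
* **SAH outcome cohort** (n = 275): one-year collapsed outcome classes
  drawn from the SAH sub-tree distribution, mRS grades uniform within
  class.

What these generators emulate is the *marginal structure* of the source
registries — they do not carry covariate correlations (age × risk,
location × size), secular trends, or inter-rater mRS noise, so passing
tests demonstrate internal consistency of the pipeline, not external
validity on real registry data.

## PSA conventions

Beta distributions (moment-matched to mean and sd) for probabilities,
gamma for costs, point masses for structural constants; defaults use sd =
10 % of the mean for probabilities (binomial standard error for the
favorable-outcome share) and 20 % for costs, all overridable in the
config. When the favorable share is sampled alone, the non-favorable split
is rescaled proportionally to keep the landing distribution on the
simplex. The summary statistic is the ICER of mean increments (ratio of
means); per-iteration samples are retained so mean-of-ratios readers can
compute their preferred statistic.

## Known limitations

* The 7-state cohort structure is memoryless: time-since-detection and
  time-since-treatment enter only through expected present-value cost
  streams, not through state.
* Detected carriers' treat-indicated status is re-drawn implicitly at
  detection rather than fixed per individual (a cohort-level
  approximation).
* Treated individuals merge into the aneurysm-free state and can form de
  novo aneurysms again; the (small) double-counting of their follow-up
  streams is ignored.
* The calibrated profile is a reproduction instrument. For prospective
  analyses, replace the calibrated cost bundle and rupture-risk scale with
  jurisdiction-specific estimates via the config.
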