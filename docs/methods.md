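# Methods

## Model structure

The model evaluates four adjuvant radiotherapy options for early breast
cancer — whole-breast or partial-breast irradiation in 15 or 5 fractions —
in two subgroups: patients eligible for partial-breast radiotherapy (SG1,
four arms, cohort entering at age 63) and ineligible patients (SG2, WB15F vs
WB5F, entering at age 60).

**Treatment period (decision tree).** Each arm incurs, at model entry and
undiscounted: a radiotherapy planning cost (£315), per-fraction delivery
costs (£124, uplifted 30% for the fraction of patients receiving cardiac
breath hold — 25% with whole-breast, 10% with partial-breast treatment), and
the expected one-off cost of managing acute skin reactions, the dot product
of the fractionation-specific RTOG-grade probabilities with per-grade costs
(£0/£0/£132/£132/£136). The published RTOG probability vectors sum to 101%
(printed rounding); they are kept as printed for the deterministic dot
product, and validation allows 2% slack around a unit sum.

**Post-treatment period (Markov cohort model).** Five states: alive &
disease free (ADF); first year of locoregional relapse (LRR_y1, a one-cycle
tunnel state that carries the one-off mastectomy and supportive-care costs);
locoregional relapse beyond the first year (LRR_post); distant relapse (DR);
dead. Annual cycles over a 50-year horizon. Constant annual baseline rates
(exponential survival) govern ADF→LRR and ADF→DR per subgroup, LRR→DR
(0.0515/yr) and DR→death (0.2196 / 0.21 per subgroup). Within a cycle,
competing exits are resolved by the proportional-hazards allocation: with
total exit rate R, the probability of any exit is 1 − exp(−R), apportioned
across causes in proportion to their rates. Background mortality for the ADF
and LRR states is the age-matched all-cause hazard with breast-cancer
mortality removed (to avoid double counting modelled breast-cancer deaths);
the same net hazard is used for LRR as for ADF. The registry-based
distant-relapse death rate is treated as already embedding all-cause risk,
so background mortality is *not* added to it by default
(`TransitionRates.dr_background_mortality` toggles this).

**Treatment effects.** Hazard ratios on locoregional recurrence vs WB15F:
0.66 (5F vs 15F) and 0.88 (PB vs WB); PB5F combines them multiplicatively
(log-scale additivity, no synergy or attenuation). The base case assumes a
common distant-recurrence pattern across arms (radiotherapy is a local
treatment); a scenario instead applies the trial-reported distant HR of 1.27
(5F vs 15F). Effects persist for the whole horizon unless a waning horizon
is set (scenarios use 5 and 10 years), after which baseline rates resume.

**Outcomes.** State costs per year: ADF £1,216 (SG1) / £1,412 (SG2), with
£402 added in the first model year; first-year LRR £4,241 treatment +
£2,995 supportive care; later LRR years £2,139; DR £13,426. Because the
ADF cost was estimated from trial resource-use questionnaires covering care
unrelated to breast cancer, the subgroup ADF annual cost is added to each
relapse-state cost by default (`unrelated_addon_policy="adf_equivalent"`;
the magnitude of the unrelated component was not published separately, so
the policy is configurable and recorded in run provenance). Utilities: ADF
0.8302 (SG1) minus 0.0150 for SG2; LRR utility equals ADF; DR applies a
0.3030 decrement. An age index multiplies utilities: 1 at the cohort start
age, declining 0.004 per year of age (floor 0.5) — applied multiplicatively
because the additive-vs-multiplicative convention was not published.

**Accounting.** Costs and QALYs are accumulated from per-cycle state
payoffs with a trapezoidal half-cycle correction (weights 0.5 on the first
and last cycle boundaries) and discounted at 3.5%/yr with end-of-cycle
timing, (1+r)^(−t); the one-off treatment-period costs are exempt from both.
A start-of-cycle timing is available by disabling the correction and
reindexing, but end-of-cycle with trapezoid is the default convention.

## Probabilistic sensitivity analysis

Each uncertain entry carries a distribution parameterised from its published
mean and standard error:

* **Gamma (method of moments)** for costs, baseline transition rates and
  utility decrements: shape = m²/se², rate = m/se². Entries printed as
  "± 20%" are read as se = 0.2 × mean.
* **Lognormal** for hazard ratios: mu = ln(mean), sigma = the published SE
  taken on the log-hazard scale. Check: exp(ln 0.88 ± 1.96 × 0.510) ≈
  (0.32, 2.39) against the published interval (0.34, 2.27) — agreement to
  SE rounding (the interval implies sigma 0.484). The distant-recurrence HR
  for the 5F-vs-15F scenario (1.27) has no printed SE; its log-scale SE
  0.1754 is recovered from the published interval 0.90–1.79.
* **Distant-relapse death rates**: the published SE (0.5102) exceeds both
  means and matches the adjacent log-scale HR SE (0.510) to the printed
  digits; a moment-matched gamma would be mostly mass near zero, implying
  implausible decades-long metastatic survival. The SE is therefore read as
  log-scale and the rate sampled lognormally with median at the published
  mean. The parameter table flags this entry rather than correcting it
  silently.
* **Dirichlet** for RTOG grade vectors, alphas = probs × ess with effective
  sample size 100 by default (the published source gives only mean
  probabilities; ess is configurable). Zero-probability grades stay
  structurally absent.
* **Absolute utilities** are sampled through the disutility 1 − u (gamma on
  mean 0.1698, se 0.004) and truncated so utilities remain in [0, 1];
  state utilities are floored at 0 after subtracting decrements.

One joint draw is shared across arms within an iteration (common random
numbers), mirroring the correlation between arms induced by shared baseline
rates and effect estimates; the within-trial correlation between baseline
rates and relative effects cannot be reproduced without patient-level data,
so entries are sampled independently by default, with an optional
Gaussian-copula hook accepting a user-supplied correlation matrix
(gamma/lognormal entries only). Each entry draws from its own RNG substream
(spawned from the seed in a fixed registry order), so a scenario that
overrides one entry leaves every other entry's draws unchanged — this is
what makes the cost-only and utility-only scenarios change exactly one
dimension of the results under a common seed.

The PSA runs 10,000 draws by default. Internally the cohort recursion is
vectorised over draws (identical closed-form transition formulas as the
single-cohort path; a test asserts the trace equals iterated
transition-matrix products), so a full 10,000-draw, four-arm analysis takes
a few seconds.

## Decision analysis

Options are compared on expected discounted cost and QALYs. Strict
dominance removes options with higher cost and no more QALYs; extended
dominance (on by default, selectable, logged) removes options above the
convex hull before ICERs are computed between consecutive frontier options
ordered by cost. "Probability cost-effective" at threshold λ is the share
of draws in which an option has the highest net monetary benefit λ·QALYs −
cost (ties split equally); for two arms this coincides with "dominates or
has an ICER below λ", and it generalises to four arms. CEACs evaluate this
over a threshold grid.

## Synthetic external inputs

* **Life table**: Gompertz–Makeham all-cause hazard a + b·e^(c·age) with
  a = 5·10⁻⁴, b = 2.5·10⁻⁵, c = 0.095 — about 1% annual mortality in the
  early 60s, ~26-year remaining life expectancy at 60, near-certain death by
  113 (survival from birth ≤ 10⁻³) — minus a Gaussian-shaped breast-cancer
  mortality bump (peak 8·10⁻⁴ at age 85, width 18) chosen as a small,
  old-age-peaking cause consistent with UK female breast-cancer mortality
  being a minor share of all-cause rates. The table spans ages 0–113
  (start 63 + 50-year horizon); hazards are capped at 1.5/yr.
* **Age-utility index**: linear decline of 0.004 per year of age above the
  cohort start age, floored at 0.5 — the magnitude of typical survey-based
  population norms over this age range.
* **Synthetic trial data**: competing exponential event times with
  administrative censoring, used to verify the closed-form rate estimator
  (events / person-time; se = rate/√events) — unbiased across 200 replicate
  trials at the published sample sizes (674 and 753) and cross-checked
  against an independent exponential-survival fitter.

These substitutes reproduce the *shape* of the real inputs, not their exact
values. Consequently the published base-case expectations are checked as
tolerance bands, not point equalities: passing tests show the model logic
and parameterisation are right and that conclusions are insensitive to
life-table details, but absolute costs/QALYs would shift slightly with the
real national tables (loadable via CSV, which tightens the comparison).
What the synthetic data do *not* emulate: secular mortality trends, cohort
effects, non-exponential relapse hazards, and any correlation between
baseline rates and treatment effects.

## Numerical choices and degenerate inputs

* Row-stochasticity of every transition matrix holds to 1e-12; the dead
  state is absorbing; the LRR_y1 tunnel has no self-loop.
* Zero total exit rate gives stay probability 1 (no 0/0).
* With all disease rates zero the cohort reproduces the life-table survival
  curve exactly.
* Duplicate cost/QALY points in the frontier are resolved in favour of the
  first-listed arm and flagged.
* Arms not offered to a subgroup (partial-breast in SG2) raise an
  eligibility error rather than silently running.
* Scenario "zero quality of life during treatment" deducts u_ADF ×
  (treatment weeks)/52 per arm (3 weeks for 15F, 1 week for 5F),
  undiscounted at entry — the published description names no mechanism, so
  the simplest course-length deduction is used.
* Problem sizes in the test suite: 10,000 PSA draws for the result checks;
  10⁶-patient microsimulation (3 parameter draws) as the independent oracle
  for the cohort expectation; 10⁵ draws for distributional checks. These
  sizes give Monte-Carlo errors comfortably below the assertion tolerances.

## Known limitations

* The distant hazard ratio for partial-breast radiotherapy was never
  published: the trial-distant-HR scenario runs only for the whole-breast
  subgroup unless a value is supplied, and the published PB-eligible results
  for that scenario are not reproducible.
* Alternative distant-relapse mortality populations (HER2+,
  triple-negative) and the log-normal survival refit ship as structural
  hooks without numbers, for the same reason.
* Reduced organ-at-risk radiation exposure with partial-breast treatment,
  quality-of-life effects of acute skin reactions, and societal costs are
  outside the model's scope.
* The model is a cohort expectation; individual-level simulation exists
  only as a test oracle.
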