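# Methods

## Model structure

The model is a deterministic Markov cohort over 793 states: 24 joint risk
profiles (weight status 0/1/2 × activity 0/1 × fruit 0/1 × vegetable 0/1)
crossed with 33 chronic-disease statuses, plus absorbing death.  States are
enumerated disease-major, then weight, activity, fruit, vegetable
lexicographically, with Dead last (index 792); the order is part of the public
contract because traces, tests and serialized outputs index into it.
Comorbidity is out of scope: a person occupies at most one disease state, and
disease states never revert.

Each cycle applies, in this fixed order: (1) mortality, (2) disease incidence
among the disease-free, (3) the joint risk-factor transition.  The order is a
modelling choice — with annual cycles and the hazard magnitudes involved, the
event-ordering effect is second-order, but it is fixed and documented so runs
are exactly reproducible.  Person-time is credited at start-of-cycle occupancy
with no half-cycle correction; the discount factor is (1+r)^(−t) with t the
years since model entry, so year 0 is undiscounted (this convention reproduces
the $99.26 present value of $50 paid in years 0 and 1 at 1.5%).

Female and male cohorts run separately on sex-specific hazards, incidences and
transitions, and are combined by a configurable mix (default 50/50, the
fraction female).

## Program effects

A program is five odds ratios applied once, to the age-10 joint distribution;
transitions afterwards are unchanged.  The per-factor map multiplies each
category's mass by its odds multiplier within every stratum of the other three
factors and renormalizes to the stratum's original mass, so (a) total
probability and the marginal distribution of the other factors are conserved
to machine precision, and (b) the conditional odds of each category are
multiplied by exactly the stated odds ratio.  The composite applies factors in
the fixed order weight → activity → fruit → vegetable.  The composite is not
proved order-invariant, so the order is configurable and the default
documented.  Zero-mass strata pass through unchanged to avoid 0/0 in the
renormalizer.  The "weight-only" comparison arm is the same model with the
three behavioural odds ratios forced to 1 — which is why a program with null
behavioural effects yields ICER and ROI ratios of exactly 1.000.

## Rates, ratios and standardization

Literature rate ratios referenced to a category (e.g. normal weight) are
standardized to the population: SMR_k = MR_k / Σ P_k MR_k, making the
population-weighted mean exactly 1.  Mortality and incidence effects combine
multiplicatively across dimensions (no synergy/antagonism), and each
dimension's contribution includes the Σ P·SMR denominator, so the operations
accept raw or pre-standardized ratios interchangeably (the division is
idempotent).  The population proportions P_k are user-supplied national
distributions held fixed over age; the synthetic generator uses the initial
distribution's marginals.  Annual rates become per-cycle probabilities via
p = 1 − exp(−rate·t), the standard exponential transform.  Competing incidence
within a cycle allocates the total probability 1 − exp(−Σ_d I*_d t)
proportionally to the per-disease rates, which agrees with per-disease
transforms to second order in the rates.

Incidence back-calculation (`solve_incidence`) fixes one concrete illness–death
balance: constant incidence i, non-diseased mortality m_n derived from the
general-population hazard m and the diseased:non-diseased ratio ρ at the
starting prevalence P_a (m = m_n(1 − P_a + ρP_a)), diseased mortality ρ·m_n,
and linear dynamics N' = −(i+m_n)N, D' = iN − m_d D whose prevalence at the
end of the interval is available in closed form.  Newton–Raphson (numeric
derivative) starts at the crude incidence ΔP/Δt and falls back to bisection on
[0, 10] whenever a step leaves that bracket; convergence is |f| < 1e-10 within
100 iterations.  The implementation is validated against an independent
high-accuracy ODE integration of the same dynamics rather than against any
particular typography of the printed equation.

## Joint transition model

Two-year transitions among the 24 profiles follow a single multinomial logit
whose linear predictor is a sum of terms, each a product of outcome-component
dummies (w1, w2, p1, f1, v1) times at most one covariate (sex, age, current
status dummies).  The default structure has every outcome main effect crossed
with every covariate (40 terms) plus all two- and three-way associations
between outcome components (16 terms); the associations are what make the
model joint.  Stepwise structure selection is deliberately not performed — the
structure is an explicit input.  Age enters linearly on a centered/scaled axis
((age − 50)/50); the panel the model emulates covers ages 12+, so evaluating
at age 10–11 is extrapolation.

Fitting maximizes the exact multinomial log-likelihood (mean-scaled) by
L-BFGS-B with the analytic gradient, optional L2 ridge for separation, and a
hard convergence check (max|grad| < 1e-6 of the mean log-likelihood, else an
exception with diagnostics).  Standard errors come from the inverse observed
information of the total log-likelihood, assembled analytically.

Annualization: the engine's default cycle is 1 year while estimates are
2-yearly, so the per-cycle matrix is the principal matrix square root of the
2-year matrix projected to the nearest valid stochastic matrix (clip negatives,
renormalize rows).  Embeddability of a 2-year matrix is not guaranteed; the
squared projection must reproduce the 2-year matrix within a tolerance or the
operation raises.  A 2-year-cycle mode avoids the root entirely for
sensitivity analyses.

## Outcomes and comparisons

Utility each year is 1 − max(weight decrement, disease decrement) — the
larger of the two decrements, not their sum.  Disease-years are discounted
person-years in any disease state.  ICERs divide the discounted program cost
(only the program cost, not net of savings) by the magnitude of the
incremental effect; the sign (e.g. disease-years *prevented*) is carried
separately.  Savings default to prevented discounted disease-years times a
single flat annual cost ($12,174 per year with chronic disease); a per-disease
cost mode uses each disease's annual cost and defines savings as avoided
discounted health-care costs.  ROI is savings/cost × 100.  Display rounding
(ICERs to whole dollars, ratios to 3 d.p., ROI to whole percent) is applied
only at the presentation layer; raw values are retained in the JSON output.

## Probabilistic sensitivity analysis

Per simulation, parameters are redrawn: beta (moment-matched from the point
value and a coefficient of variation, or from a 95% interval via
`beta_from_ci`) for prevalences and incidences; log-normal with median at the
point estimate for relative risks and mortality rate ratios (reference-category
and unlinked entries, fixed at 1, are never perturbed, preserving the linkage
pattern); normal for transition coefficients; per-cell beta draws renormalized
to the simplex for the 24-cell initial distribution, parameterized by an
effective sample size.  Incidence curves get one multiplicative draw per
disease and sex so the age shape is preserved.  A spec with all dispersions
zero returns the base parameters exactly, collapsing every interval to the
deterministic result.  Intervals are the 2.5th/97.5th percentiles of each
output across draws; ratio intervals are computed ratio-per-draw.  Failed
draws are logged and excluded with a reported count.  Default is 10,000
simulations; the test suite and the acceptance script use 200, with
correspondingly loose expectations, to keep runtimes short.

## Synthetic parameter generator

The generator emulates the *shape* of national inputs, not any country's
values: Gompertz-like life tables (h(a) = h₀·e^{0.09a} + 10⁻⁴, sex-scaled,
monotone in age); an age-10 initial distribution built from plausible child
marginals (68/20/12% weight, 20% meeting activity, ~30–35% meeting fruit and
vegetable recommendations) with Dirichlet jitter (effective sample size 300)
to induce interdependence; sticky transitions (own-status log-odds carryover
≈ 2.2, i.e. most people keep their status over two years); disease incidences
log-uniform in 10⁻⁵–2×10⁻³/year rising with age, capped at 0.05; relative
risks above 1 for overweight/obesity and below 1 for meeting behavioural
recommendations, drawn only where the packaged linkage table has a link (unlinked
factors are exactly 1); mortality ratios for disease 1.1–2.5; utility
decrements 0.02–0.25 (weight: 0.005–0.03 overweight, 0.03–0.08 obese); annual
costs $1,000–15,000.  Generation is a pure function of the seed.

What the generator does **not** emulate: survey weighting, measurement error
in self-reported behaviour, secular trends in incidence, sex-specific disease
exclusions (e.g. ovarian cancer in males), attrition, and comorbidity.  Tests
passing on synthetic parameters therefore demonstrate the correctness and the
qualitative behaviour of the machinery (conservation, monotonicity,
directions of the ICER/ROI ratios), not calibrated magnitudes for any real
population.

## Numerical choices and edge cases

* Probability simplex validation tolerance 1e-9 on input; internal operations
  conserve mass to ~1e-15 and traces are checked at 1e-10 per cycle.
* The null parameter set (unit ratios, zero incidence, zero decrements)
  collapses the model to life-table survival; engine accounting is tested
  against the closed-form discounted life expectancy at 1e-10.
* `icer` with a zero incremental effect raises (undefined) unless the cost is
  also zero; `compare_scenarios` reports infinity for a degenerate arm.
* Parameter-recovery experiments use n = 20,000 panel transitions for the
  full 56-term structure and n = 2,500 vs 10,000 (3 seeds) for the
  sample-size consistency check; these sizes give stable verdicts at modest
  runtime.
* All randomness flows from one top-level seed through named
  `SeedSequence`-derived streams (`fixtures`, `psa`, ...), so stages are
  independently reproducible.

## Known limitations

Single-disease states (no comorbidity accumulation); program effects only at
the starting age; the same transition model in diseased and disease-free
states; P_k standardization weights held fixed over age; annualization by
matrix root is a projection, not an exact embedding; utility decrements
estimated for adults are applied from age 10 up.
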