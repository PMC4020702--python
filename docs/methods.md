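# Methods

## The estimation problem

Harvest rate — the probability that a game animal is killed by a hunter and
retrieved in a given season — is classically estimated from dead recoveries of
reward-tagged animals with a Brownie-parameterized tag-recovery model.  That
model assumes every tagged animal is alive when the first hunting season
opens.  Many species are easiest to capture in winter but are not hunted until
autumn, and mortality over those pre-season months shrinks the expected
recovery rate by the cumulative pre-season survival `S_G`, biasing the harvest
estimator downward by the factor `S_G`.

`jointharvest` removes that bias by estimating `S_G` from a second, independent
data stream: monthly known-fate monitoring of a transmitter-fitted subsample
(Kaplan–Meier staggered-entry design).  Because the streams are independent,
the joint log-likelihood is the sum of the component log-likelihoods, and the
monthly survival rates that enter the known-fate kernel are the *same*
parameters whose product forms `S_G` inside the recovery cells — this is what
makes `S_G` and the harvest rate separately estimable.

## Model components

With reward tags the reporting rate is taken as 1, so the recovery rate equals
the harvest rate `H`; no reporting-rate parameter exists in the package.

1. **Known-fate intervals.**  Each monthly interval `g` contributes the
   binomial kernel `(n_g - d_g - c_g) ln s_g + d_g ln(1 - s_g)` where `n_g`
   animals were monitored, `d_g` died and `c_g` were censored.  Censored
   animals are removed before the survival/death split (censoring assumed
   independent of fate).  Staggered entry is ordinary bookkeeping:
   `n_{g+1} = n_g - d_g - c_g + e_{g+1}`.
2. **Dead-recovery cohorts.**  A cohort of `N_i` animals released before year
   `i` (entry month `g0`) has recovery-year cell probabilities
   `p_ij = S_Gi · H_j · Π_{k=i..j-1} S_k`, `S_Gi = Π_{g=g0..G} s_g`, plus a
   never-recovered complement; the counts are multinomial.  A March cohort
   accumulates fewer monthly terms than a January cohort, which is how unequal
   tagging-to-harvest exposure is handled.
3. **Radio-harvest binomials.**  Seasons with `m_i` transmitter-fitted animals
   available and `h_i` harvested contribute `h_i ln H_ri + (m_i - h_i)
   ln(1 - H_ri)`.  Setting `H_i = H_ri` (the default) lets transmitter animals
   sharpen the harvest estimate; comparing models with and without that
   constraint is an AICc test for transmitter effects on harvest
   (`tag_effect_test`).

All binomial/multinomial constants are dropped, so log-likelihood values are
comparable only within a dataset; AICc differences are unaffected.

## Parameter structures and counting

A `ModelSpec` gives each family — monthly survival `s`, harvest `H`, annual
survival `S`, radio harvest `H_r` — a factor structure over month, year, age,
unit, and tag type, or pins it at a fixed value (monthly survival fixed at 1
recovers the classical model).  Free parameters are enumerated from the
likelihood cells that actually use them, which has two consequences worth
stating:

* the final-year annual survival never appears in any recovery cell, so it is
  excluded from the parameter space rather than estimated or fixed — a
  `J`-year one-age-class recovery design contributes `J` harvest and `J - 1`
  annual-survival parameters;
* radio-harvest levels whose availability is zero in every cell are fixed at 0
  and excluded from `K`.

The `H_i = H_ri` constraint is index aliasing (radio cells resolve in the
harvest family with `tag_type="radio"`), not a penalty, so the constrained
model's `K` drops by exactly the number of aliased harvest parameters.  A
structure whose pre-season survival levels are needed by recovery cohorts but
informed by no known-fate interval is rejected as non-identifiable (`S_G` and
the recovery rate would be confounded).

## Numerical choices

* **Link and optimizer.**  All probabilities are logit-linked; fixed values
  bypass the link.  L-BFGS-B maximizes the joint log-likelihood with its
  *analytic* gradient, assembled through a cell-to-parameter incidence matrix
  (a month appearing twice in a product simply carries multiplicity 2).  The
  analytic gradient is what makes the simulation grids (~15,000 32-parameter
  fits) tractable; it is verified against finite differences in the tests.
* **Starting values and restarts.**  Starts come from the closed forms
  (pooled interval survival `1 - d/n'`, crude harvest `U_ii / (a · S_G)`),
  then up to 5 deterministic jittered restarts (default; the grid engine uses
  2, which the smart start makes sufficient in those designs).  Logit-scale
  bounds of ±12 keep probabilities strictly inside (0, 1); estimates beyond
  ±11 are reported with a boundary flag and no SE.
* **Invalid regions.**  Cell probabilities can transiently sum past 1 during
  optimization (the parameterization does not enforce `H + S ≤ 1`); the
  never-recovered tail is clipped at a tiny positive value so the objective
  stays finite and the gradient points back into the valid region.
* **Standard errors.**  Observed information by central differencing of the
  analytic gradient (step 1e-4), inverted after an eigenvalue rank check;
  singular information is flagged and SEs withheld.  Real-scale SEs use the
  delta method `se_p = p(1-p)·se_logit`; 95% intervals are normal on the link
  scale, back-transformed.  Cumulative survival `S_G = Π s_g` gets a
  first-order delta SE from the link-scale covariance.
* **AICc.**  `-2 lnL + 2K + 2K(K+1)/(n-K-1)` with `n` the total individuals
  released across streams (tag releases plus known-fate entries;
  radio-harvest availability only when no known-fate stream exists, to avoid
  double-counting transmitter animals).  `n` is recorded in the fit report and
  can be overridden.  Ties in ranking break by smaller `K`, then input order.

## What the simulation scenarios emulate

`Scenario` encodes the design study: 3 years, 9 pre-season months, constant
true rates (`s = S_G^{1/9}` per month), and per-year releases over a grid of
0–200 transmitters × 50–600 reward tags.  Transmitter animals pass through 9
monthly Bernoulli survival draws (no censoring); tagged animals draw a
recovery-year fate from the exact model multinomial.  Each
(allocation, replicate) has its own counter-derived RNG stream, so any cell is
reproducible in isolation.

Replicates are fitted with the classical model when no transmitters are
allocated (5 parameters) and otherwise with the joint model (27 monthly
survival + 3 harvest + 2 annual survival = 32 parameters).  Metrics per
allocation-year cell: mean estimate, absolute bias, relative bias
(bias / truth), `CV = 100·SD/mean` over replicates, and
`CV(RMSE) = 100·RMSE/truth`, which satisfies
`CV(RMSE)² = (100·SD₀/truth)² + (100·bias/truth)²` (population SD).  Summary
tables average each cell over replicates first, then summarize across
allocation × year cells; CV(RMSE) is also differenced against the
0-transmitter baseline at the same tag count (negative = joint worse).
Non-convergent fits are excluded with a reported exclusion rate (warning above
10%); in practice exclusions are ≲0.1%.

What the generator deliberately does *not* emulate: censoring and staggered
entry in the grid scenarios (the case-study fixtures exercise both),
age/sex/unit structure in the grids, heterogeneity among individuals, tag
loss, or partial reporting.  Passing grid tests therefore demonstrate
correctness of the estimator under its own assumptions, not robustness to
their violation.

**Problem sizes.**  The shipped study runs the full 7-tag 0-transmitter grid
at 500 replicates and the full 7×7 joint grid at 150 replicates (the package's
own scaling choice; a corner subset of allocations would misweight the
strongly allocation-dependent CV surface, so scaling down in replicates keeps
the grid-average estimand intact).  Monte-Carlo noise on the reported
averages is well inside the quoted tolerances.

## Case-study fixtures

Two synthetic generators emulate the designs the model was built for, with
magnitudes typical of the respective field studies; they are labelled
synthetic and are not the original datasets.

* **turkey**: 3 years, January–March staggered entry, 2 age classes, ~160–170
  adults and ~75–130 juveniles banded per year of which ~30–55 / ~6–15 carry
  transmitters; true pre-season survival ≈0.45 (adult) / 0.51 (juvenile),
  year-varying harvest ≈0.02–0.09, annual survival 0.55.  Transmitter birds
  contribute known-fate data only.
* **deer**: 3 years × 4 management units × 2 age classes, ear-tag cohorts
  (60 adults / 25 juveniles per unit-year) plus transmitter animals (30 / 8)
  that yield both known-fate and radio-harvest streams; monthly survival
  0.9905 / 0.9799 by age, unit-specific harvest 0.111–0.138 shared between tag
  types by default (set `radio_harvest=` truth rates to inject a transmitter
  effect), annual survival 0.70.

## Known limitations

* Confidence intervals are Wald-type on the link scale; no profile-likelihood
  or bootstrap intervals.
* The multinomial does not constrain `H_i + (natural mortality) ≤ 1`
  structurally; absurd truths (e.g. `H + S > 1`) are representable.
* Continuous covariates, multi-state/live-recapture data, and reporting rates
  below 1 are out of scope.
* The AICc effective-n convention varies across software; results sensitive to
  it (small samples, large `K`) should be checked with an explicit `n_eff`.
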