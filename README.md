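# jointharvest

Joint Kaplan–Meier known-fate and Brownie tag-recovery estimation of harvest
and annual survival rates for hunted wildlife.

## The problem

Tag-recovery studies estimate the harvest rate `H_i` (the probability an
animal is shot and retrieved in season `i`) from reward-tag returns, but the
classical dead-recovery model assumes every tagged animal survives from
capture to the season opening.  Game species are often captured in winter and
hunted in autumn, so months of pre-season natural mortality shrink the
expected recovery rate and bias `Ĥ` downward by the cumulative
tagging-to-harvest survival `S_G`.  This package implements a joint model for
wildlife agencies and quantitative ecologists that removes the bias by
estimating `S_G` from monthly known-fate telemetry of a transmitter-fitted
subsample, fitted together with the recovery data in one likelihood.

## The model

For release year `i`, recovery year `j`, pre-season months `g = g0..G`:

```
S_Gi   = Π_g s_g                          cumulative pre-season survival
E[R_ij] = N_i · S_Gi · H_j · Π_{k=i..j-1} S_k   expected recoveries (j ≥ i)
```

The joint log-likelihood is the sum of (1) binomial Kaplan–Meier interval
kernels for the monthly survivals `s_g` (staggered entry supported), (2) the
multinomial over each cohort's recovery year with the cells above, and (3)
optionally a binomial for transmitter-fitted animals harvested in season with
rate `H_ri`.  Reward tags are assumed to give a reporting rate of 1, so the
recovery rate equals `H`.  Setting `H_i = H_ri` pools the two harvest signals;
comparing models with and without that constraint (AICc) tests whether
carrying a visible transmitter changes an animal's chance of being harvested.
Parameter families (`s`, `H`, `S`, `H_r`) can vary by month, year, age class,
management unit, and tag type; fitting is by quasi-Newton maximization on the
logit scale with analytic gradients.  See `docs/methods.md` for details.

## Worked example

```python
import numpy as np
import jointharvest as jh
from jointharvest import estimation

# synthetic dataset emulating a 3-year staggered-entry upland-bird study:
# two age classes banded Jan-Mar, a transmitter subsample, autumn season
data = jh.make_case_study_fixture("turkey", np.random.default_rng(42))

fitted = estimation.fit(jh.turkey_year_spec(), data)   # K = 23 parameters
print(fitted.loglik, fitted.K, fitted.aicc)
# -359.5  23  766.5

for year in (2010, 2011, 2012):
    print(year, round(fitted.value("H", year=year, age="adult",
                                   unit="all", tag_type="band"), 3))
# 2010 0.056   2011 0.072   2012 0.004

sg, se = estimation.cumulative_survival_se(fitted, 1, 9, age="adult")
print(round(sg, 3), round(se, 3))
# 0.413 0.044
```

The harvest-rate estimates recover the generator's truths (0.054, 0.088,
0.022) within sampling error, and the January–September cumulative survival
0.413 (SE 0.044) matches the generating 0.45: with pre-season survival around
45%, a model that ignored it would halve every harvest estimate — refitting
with `monthly_survival=FamilySpec(fixed=1.0)` gives 0.038 instead of 0.072 for
2011.  Model comparison is one call:

```python
constant = estimation.fit(jh.turkey_constant_spec(), data)   # K = 20
print(estimation.compare_models([fitted, constant], ["year", "constant"]))
#      model   K   loglik    AICc  dAICc  weight
#       year  23   -359.5   766.5    0.0    0.98
#   constant  20   -366.5   774.0    7.6    0.02
```

A command-line interface wraps the same library calls:

```
jointharvest fixture --design deer --seed 7 --out deer/
jointharvest fit --data deer/ --spec model.yaml --out fit/
jointharvest tag-effect --data deer/ --spec model.yaml --out tag/
jointharvest simulate --config scenario.yaml --out sim/
```

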