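# valueshift

Does population ageing alone put an expiration date on health-state
value sets? `valueshift` answers that question for EQ-5D-3L time
trade-off (TTO) valuation studies. It fits a Bayesian heteroskedastic
Tobit model with sex/age-specific preference-scale parameters, then
reweights the fitted preference structure with two population
compositions — the one at survey time and a recent one — and gives the
posterior distribution of the difference between the implied value
sets. It is written for health economists and HTA methodologists who
want to stress-test the demographic robustness of a value set, and it
ships a synthetic study generator so the whole pipeline is testable
without access to the (partly restricted) historical survey archives.

## Model

Observed TTO values are left-censored latent normals,

```
TTO_it = TTO*_it  if TTO*_it > -1,  else -1
TTO*_it ~ Normal(mu_it, sigma_it)

mu_it    = b0 + sum_d (b_d2 I_d2,it + b_d3 I_d3,it) * phi_d[cell(i)]
sigma_it = exp(g0 + g1 mu_it + g2 mu_it^2 + g3 mu_it^3 + g4 mu_it^4)
```

with dimensions d in {MO, SC, UA, PD, AD}, level-2/3 indicators I, and
multiplicative scale parameters `phi_d[c]` over sex x age cells
(positive, mean one per dimension for identification). Priors are
Normal(0, 10) on `b` and `g`, and mean-one log-normal (log-sd 0.4,
log-mean -0.08) on the free `phi`. Estimation is a custom
Metropolis-within-Gibbs sampler with slice updates for the constrained
scales and optional antithetically coupled chain pairs; value sets are
monitored as `b_dl * sum_c w_c phi_d[c]` under each composition `w`.
See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
import valueshift as vs
from valueshift.mcmc import MCMCConfig, fit
from valueshift.model import CompiledData
from valueshift.monitor import monitor_valuesets, summarize

truth = vs.default_truth("UK", n_respondents=400, contaminate=False)
dataset = vs.simulate_study(truth, rng=np.random.default_rng(5))
draws = fit(CompiledData.from_dataset(dataset),
            MCMCConfig(n_chains=2, n_burnin=500, n_total=1500, seed=5))
summary = summarize(monitor_valuesets(
    draws,
    vs.load_reference_weights("UK-1997"),
    vs.load_reference_weights("UK-2022"),
))
print(summary[["label", "original_mean", "updated_mean",
               "diff_mean", "diff_lo", "diff_hi"]].round(4).to_string(index=False))
```

prints (`examples/04_reweight_value_sets.py`):

```
label  original_mean  updated_mean  diff_mean  diff_lo  diff_hi
  MO2        -0.0506       -0.0520    -0.0014  -0.0021  -0.0008
  MO3        -0.2999       -0.3081    -0.0082  -0.0110  -0.0053
  SC2        -0.1059       -0.1041     0.0018   0.0006   0.0031
  SC3        -0.2216       -0.2178     0.0038   0.0012   0.0064
  UA2        -0.0714       -0.0726    -0.0012  -0.0022  -0.0003
  UA3        -0.2023       -0.2057    -0.0034  -0.0060  -0.0008
  PD2        -0.0921       -0.0906     0.0015   0.0008   0.0022
  PD3        -0.5041       -0.4962     0.0080   0.0046   0.0114
  AD2        -0.1254       -0.1228     0.0025   0.0015   0.0035
  AD3        -0.3790       -0.3713     0.0077   0.0048   0.0103
```

Each row is one dimension-level decrement: `original_mean` is the
population-weighted utility loss under the 1997 UK composition,
`updated_mean` under the 2022 composition, and the `diff` columns give
the posterior mean and 95% credible interval of their difference.
Differences here are at most ~0.01 in absolute value — an order of
magnitude smaller than the decrements themselves — which is the
substantive finding this kind of analysis produces: 25 years of
demographic change barely move the value set.

The same stages are available as shell commands
(`valueshift simulate | qc | fit | reweight | predict | report | run`),
and `examples/` contains one short script per capability.

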