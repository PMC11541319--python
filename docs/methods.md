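# Methods

## The question the package answers

A value set maps each of the 243 EQ-5D-3L health profiles to a societal
utility anchored at 1 (full health) and 0 (dead). Value sets are built
from time trade-off (TTO) surveys and then used for decades, while the
population they are meant to represent ages. If preferences differ
systematically by sex and age, a shift in the population's sex/age
composition alone could make an old value set obsolete — even with
individual preferences frozen. `valueshift` quantifies exactly that
ceteris-paribus effect: it estimates sex/age-specific preference
structure from TTO data and compares the value set implied by the
population composition at survey time with the one implied by a later
composition.

## Model

For respondent *i* valuing the state in task *t*, the observed TTO
value is a left-censored latent normal:

    TTO_it = TTO*_it  if TTO*_it > -1,   otherwise  -1
    TTO*_it ~ Normal(mu_it, sigma_it)

The mean combines an intercept `b0`, ten dimension-level decrements
`b_1..b_10` (levels 2 and 3 of MO, SC, UA, PD, AD), and multiplicative
scale parameters `phi_d[c]` per dimension *d* and demographic cell *c*
(sex x age band, G = 8 cells by default; any finite labelled cell set
is accepted):

    mu_it = b0 + sum_d (b_d2 I_d2,it + b_d3 I_d3,it) * phi_d[cell(i)]

A cell with `phi_d[c] > 1` weighs dimension *d* more heavily than the
population average. For identification each `phi_d` is positive with
unweighted arithmetic mean 1 over the cells, so the betas carry the
population-average decrements. (The predicate is isolated in
`model.phi_mean_one_ok`; a population-weighted variant would be a
one-line change, but the unweighted mean is the natural reading and the
reweighting step downstream makes the distinction immaterial for the
difference quantity.)

Response noise varies with state severity through a log-linear quartic
in the mean:

    sigma_it = exp(g0 + g1*mu_it + g2*mu_it^2 + g3*mu_it^3 + g4*mu_it^4)

Note `sigma_it` uses the *scaled* mean (including phi), so the variance
is parameter-dependent and is recomputed at every likelihood
evaluation.

Priors: Normal(0, 10) on the intercept, decrements and variance
coefficients — effectively flat at the scale of TTO values. The free
scale parameters get log-normal priors with log-sd 0.4 and log-mean
-0.4^2/2 = -0.08, so the prior expectation is exactly 1 and the prior
is centred on "no demographic preference differences".

## Estimation

A custom Metropolis-within-Gibbs sampler (`mcmc.run_chain`) with a
fixed systematic scan: intercept, the ten decrements and the five
variance coefficients by scalar Gaussian random walks; the scale
parameters by univariate stepping-out/shrinkage slice sampling. The
constraint is parameterized with G-1 free coordinates per dimension and
the last cell defined as `G - sum(others)`; slice support is truncated
where any implied cell would be non-positive, so positivity and the
mean-one constraint hold *exactly* at every draw. Priors are evaluated
on the free coordinates.

Step sizes adapt by Robbins-Monro toward 0.44 acceptance during
burn-in only; the retained chain is time-homogeneous. Defaults are
3 chains, 10,000 burn-in and 30,000 total iterations; tests and the
acceptance script use scaled-down runs (3 x (1,000 + 2,000) at 1,000
respondents), sized so the posterior is still informative about every
monitored parameter.

**Antithetic sampling.** Implemented as antithetically *coupled chain
pairs*: the second chain of a pair is driven by the mirror of the first
chain's random stream (normals negated, acceptance uniforms reflected
to 1-u). Each chain alone is a marginally exact sampler, so correctness
never depends on the coupling; the induced negative correlation lowers
the Monte-Carlo variance of pooled averages. The superficially simpler
alternative — mirroring successive proposal innovations *within* one
chain — measurably breaks stationarity (a random walk over Normal(0,10)
converges to sd ~ 6 instead of 10), which is why the across-chain
construction was chosen. A config flag disables the coupling, giving
fully independent chains.

**Likelihood evaluation.** The likelihood depends on the data only
through per-(state x cell) sufficient statistics: counts, sums and sums
of squares of uncensored values, plus censored counts (each censored
observation contributes a normal-CDF mass at -1). `model.CompiledData`
aggregates a dataset once, after which an evaluation is O(S x G)
(at most 45 x 8 grid cells) instead of O(observations). This is exact
— the tests compare it with a per-observation scalar implementation to
1e-10 — and is what makes the scaled-down MCMC budgets cheap. During
sampling the mean grid is maintained incrementally (a scale-parameter
move touches only two of its columns) and refreshed every 200
iterations against floating-point drift.

**Convergence.** Split-chain potential scale reduction (R-hat) per
parameter, cross-checked against arviz in the test suite. R-hat above
1.05 flags a run as unconverged (warning status; outputs still
written). Parameters with vanishing within-chain variance report NaN.
The weakly identified cubic/quartic variance coefficients mix slowest;
their R-hat is the usual reason short demonstration runs are flagged.

## Respondent quality control

Two sequential exclusion rules, applied before fitting: (1) fewer than
10 completed tasks (strictly fewer: 10 keeps); (2) a positive OLS slope
of the TTO value on the state's misery index (the sum of its five
levels). Slope exactly zero (within 1e-12) is retained — zero is not
positive. A respondent hit by both rules counts only under the first,
so the report's arithmetic matches a sequential accounting. An
undefined slope (all tasks at one misery value, impossible under the
supported designs) retains the respondent with a warning. OLS is used
because no alternative estimator is specified anywhere; the estimator
sits behind `qc.respondent_slope` so a rank-based variant could be
substituted in one place.

## Value-set monitoring

For composition `w`, the population decrement is
`D_dl(w) = b_dl * sum_c w_c phi_d[c]`. Computing this per posterior
draw under the survey-time composition and under a later one gives the
posterior of both value sets and of their difference
(`updated - original`, reported with equal-tailed 2.5/97.5 percentile
intervals, linear interpolation between order statistics). Note some
published tables print the *magnitude change* of a decrement, which is
the negative of this signed difference for negative decrements; the
package reports the raw signed difference and leaves presentation to
the caller. Monitoring is post hoc on stored draws (canonical — it
decouples fitting from weighting); inline per-draw monitors produce
bit-identical values for users who want the quantities tracked during
sampling.

Two exact algebraic facts anchor the interpretation and are asserted
per draw in the tests: with identical weightings every difference is
exactly 0, and if a dimension's scale parameters are constant across
cells its difference is 0 no matter how large the demographic shift.

## Synthetic studies

The generator (`synth`) emulates the structure of the three supported
survey designs: a fixed 17-state panel valued by every respondent, or
per-respondent samples of 12 states from a 45-state pool drawn one per
severity stratum (the pool sorted by misery index and split into 12
consecutive blocks). Stratification mirrors how TTO instruments are
built in practice — every respondent values states across the severity
range — and it keeps each respondent's value-vs-misery slope well
identified, so the QC filter separates planted nonsense responders
from honest ones cleanly; unstratified random 12-state subsets
occasionally span only 3-4 misery levels, whose noisy slopes produce
spurious exclusions. The published designs are not reproduced; the
pools are synthetic stand-ins with matched cardinality, misery-index
span 6-15 and the worst state 33333 included, injectable via
`TruthScenario.design_pool`.
Respondents' cells are drawn i.i.d. from a survey composition (the
packaged "sample" fixtures; no household or quota structure). Latent
values come from the model above with censoring at -1.

Default truths per country style: decrements anchored at the country's
published original value set (e.g. UK PD3 = -0.47), intercept 0.95,
mild heteroskedasticity (sigma from ~0.2 near full health to ~0.4 for
severe states), scale parameters varying by up to +-25% across cells
with exact mean one, and contamination fractions matching the three
surveys' reported exclusion counts (e.g. UK: 82/3395 low completers,
43/3395 positive slopes). Planted nonsense responders are generated by
sign-flipping the decrements, which makes the expected value-misery
slope strictly positive and the QC filter's target unambiguous; low
completers receive 1-9 tasks.

Because the latent model is normal and unbounded above, synthetic
values can exceed 1, which real TTO data cannot. This is deliberate:
parameter-recovery checks are only meaningful when the generator equals
the fitted likelihood. File readers reject values above 1 by default
(real-data hygiene) with an explicit opt-out for model-scale synthetic
data. Passing recovery tests therefore validates the estimation
machinery, not the model's adequacy for real TTO data near full health
(real studies truncate there, a misspecification this package inherits
from the modelling tradition it implements).

## Numerical choices and edge cases

- Censoring status is inferred at read time from value == -1 within
  1e-9 (the censoring map sends all latent values <= -1 to exactly -1).
- Likelihood evaluations return -inf (proposal rejected) when
  |log sigma| exceeds 300; the scalar `scale_sd` raises instead, since
  a user calling it directly has left the sane parameter region.
- Weight tables are accepted in percent or proportion form
  (auto-detected from the total, overridable) and re-normalized to sum
  exactly to 1, so rounded printed tables cannot poison the weighted
  averages.
- Quantiles everywhere use numpy's linear interpolation; summaries are
  invariant to draw order.
- Initialization: least squares of uncensored values on the state
  indicators (computable from the sufficient statistics), log residual
  SD for g0, scale parameters near 1; per-chain jitter overdisperses
  the starting points. Datasets with no uncensored observations cannot
  be initialized and are rejected.
- All randomness flows from one master seed via `SeedSequence`
  spawning; identical seeds give bit-identical draws, summaries and
  pipeline bundles.

## Known limitations

- No respondent-level random effects: repeated tasks by one respondent
  are conditionally independent given the cell. Real TTO panels show
  within-respondent correlation the model ignores.
- No upper censoring at 1 (see above).
- The cubic and quartic variance coefficients are weakly identified on
  TTO-scale data; they mix slowly and mostly matter as a flexibility
  reserve.
- Demographic cells enter only through the scale parameters; education,
  ethnicity or other strata can be passed as custom cell labels, but no
  interaction structure beyond the multiplicative scaling is available.
- The synthetic generator's design pools and truth values are
  plausible, not the historical instruments; conclusions about the real
  surveys require the archived datasets, supplied via the column-mapping
  readers.
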