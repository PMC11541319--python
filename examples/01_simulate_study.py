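"""Simulate a UK-style TTO valuation study and inspect its shape.

Generates 200 respondents with the survey's sex/age composition, each
valuing 12 states sampled from a 45-state pool, with a few planted
excludable respondents, then prints basic descriptives.
"""

import numpy as np

import valueshift as vs

truth = vs.default_truth("UK", n_respondents=200)
dataset = vs.simulate_study(truth, rng=np.random.default_rng(7))

print(f"respondents:        {dataset.n_respondents}")
print(f"observations:       {dataset.n_observations}")
print(f"censoring rate:     {vs.censoring_rate(dataset):.3f}")
print(f"planted low completers / sign-flipped: "
      f"{truth.n_planted_low} / {truth.n_planted_positive}")

# the censoring rate is the fraction of worse-than-dead responses
# recorded exactly at -1, the Tobit mass point; a few percent is
# typical for severe EQ-5D-3L states.
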