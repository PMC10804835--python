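"""Refitting the pairwise model and recovering known parameters.

Generates a synthetic table from a known linear model, forms query/
reference pairs, adds pair-level Gaussian noise and refits by OLS: the
estimates land within a few standard errors of the generating truth.
"""

import numpy as np

import ptmlee as p
from ptmlee.fixtures import FIXTURE_TRUE_MODEL, FixtureSpec, generate_reactions, perturb_pairs
from ptmlee.ptml import PTO_NAMES

reactions = generate_reactions(FixtureSpec(n_reactions=80, seed=23))
pairs = p.generate_pairs(reactions, mode="sample", k=2000, seed=23)
model = p.fit_mlr(perturb_pairs(pairs, noise_sd=5.0, seed=24), model_id="recovery")

print(f"n = {model.stats['n']} pairs, R = {model.stats['R']:.3f}, "
      f"SEE = {model.stats['SEE']:.2f}, F = {model.stats['F']:.0f}")
print(f"\n{'variable':22s}{'true':>10s}{'estimate':>12s}{'SE':>10s}{'z':>8s}")
truth = np.append(FIXTURE_TRUE_MODEL.coefficients, FIXTURE_TRUE_MODEL.e0)
est = np.append(model.coefficients, model.e0)
se = np.array(model.stats["coef_se"])
for name, t, e, s in zip(list(PTO_NAMES) + ["intercept"], truth, est, se):
    print(f"{name:22s}{t:10.3f}{e:12.4f}{s:10.4f}{(e - t) / s:8.2f}")

# |z| stays below ~3 for every coefficient: the OLS machinery recovers the
# generating model at the reported precision.
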