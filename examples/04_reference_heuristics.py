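"""Reference-selection heuristics H1 and H2 over a reference table.

H1 uses the single most similar reference (minimal standardized L1 norm
of the 12 perturbation operators); H2 averages the predictions over all
references.
"""

import numpy as np

import ptmlee as p
from ptmlee.fixtures import FixtureSpec, generate_reactions

reactions = generate_reactions(FixtureSpec(n_reactions=40, seed=7, noise_sd=3.0))
pairs = p.generate_pairs(reactions, mode="sample", k=800, seed=7)
model = p.fit_mlr(pairs, model_id="example_refit")

query, refs = reactions[0], reactions[1:]
h1 = p.select_reference_H1(query, refs, model)
h2 = p.predict_H2(query, refs, model)

print(f"query {query.rxn_id}: observed ee_R = {query.ee_R:+.1f}%")
print(
    f"H1: predicted {h1.ee_R_pred:+.1f}% via most similar reference "
    f"{h1.reference_id} (PTO norm {h1.pto_norm:.3f}, strategy {h1.norm_strategy})"
)
print(f"H2: predicted {h2.ee_R_pred:+.1f}% as mean over {h2.n_references} references")

obs = np.array([x.ee_R for x in reactions])
h1_all = np.array(
    [p.select_reference_H1(x, reactions, model).ee_R_pred for x in reactions]
)
r2 = float(np.corrcoef(obs, h1_all)[0, 1] ** 2)
print(f"\nleave-one-out H1 over all {len(reactions)} reactions: R^2 = {r2:.3f}")

# H1 additionally reports *which* literature reaction it used, which is
# chemical information a reference-free regression cannot give.
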