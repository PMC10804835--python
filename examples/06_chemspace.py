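"""Counting the accessible reaction space.

With the curated dataset's 55 substrates, 53 nucleophiles, 39 catalysts
and 17 solvents, plus the observed condition ranges and practical steps,
the one-factor-at-a-time space factorizes as N_max = N_comb * N_exp.
"""

import ptmlee as p

spec = p.SpaceSpec(
    n_sub=55,
    n_nuc=53,
    n_cat=39,
    n_solv=17,
    grid_T=p.ConditionGrid(-78.0, 66.0, 10.0),
    grid_t=p.ConditionGrid(1.0, 240.0, 1.0),
    grid_load=p.ConditionGrid(2.0, 30.0, 1.0),
)
n_comb, n_exp, n_max = p.count_space(spec)
print(f"molecular combinations  N_comb = {n_comb:,}")
print(f"condition experiments   N_exp  = {n_exp:,}")
print(f"total reaction space    N_max  = {n_max:,}  (~10^{len(str(n_max)) - 1})")

# ~1.9 million molecule combinations x ~96 thousand condition settings:
# a ~10^11 space no lab can screen, which is what makes a fast predictor
# with reference tracing useful.
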