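"""Canonicalizing reactions into the (R)-catalyst frame.

A reaction reported with the (S)-catalyst is mirrored (product CIP label
flipped) so every reaction is expressed as if run with the (R)-catalyst;
the signed excess ee_R then carries all the chirality information.
"""

from ptmlee import ReactionRecord, canonical_ee_R

base = dict(
    rxn_id="demo",
    family="aaa",
    sub_smiles="CCO",
    nuc_smiles="c1cc[nH]c1",
    cat_smiles="OP(=O)(O)O",
    solv_smiles="C1CCOC1",
    prod_smiles="OCCc1cc[nH]c1",
    T_C=25.0,
    t_h=24.0,
    load_pct=20.0,
    source="example",
)

for cat, prod, ee in [("R", "R", 93.0), ("R", "S", 76.1), ("S", "R", 50.0), ("S", "S", 60.0)]:
    rxn = canonical_ee_R(
        ReactionRecord(**base, cat_config=cat, prod_config=prod, ee_pct=ee)
    )
    print(
        f"({cat})-catalyst, ({prod})-product, ee = {ee:5.1f}%  ->  "
        f"ee_R = {rxn.ee_R:+6.1f}%  (mirrored: {rxn.mirrored})"
    )

# Positive ee_R means the (R)-catalyst frame yields the (R)-product; an
# (S)-catalyst run maps onto the mirror-image reaction with opposite sign.
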