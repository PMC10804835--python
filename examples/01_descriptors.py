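"""Markov-chain descriptors of a few small molecules.

Each molecule gets a 5 x 5 block: five atomic properties (valence
electrons Zv, vdW volume, Sanderson electronegativity chi, polarizability
alpha, electron affinity EA) averaged over five atom groups after 1..5
steps of an electronegativity-weighted random walk on the bond graph.
"""

import ptmlee as p

for smiles in ["CCO", "c1cc[nH]c1", "OP(=O)(O)O"]:
    block = p.descriptor_block(p.parse_molecule(smiles))
    print(f"\n{smiles}  (atom table v{block.table_version}, d_max={block.d_max})")
    print(f"  {'':8s}" + "".join(f"{g:>10s}" for g in ("Csat", "Cuns", "Het", "HetNoX", "Tot")))
    for k in ("Zv", "Vvdw", "chi", "alpha", "EA"):
        row = "".join(f"{block.value(k, g):10.4f}" for g in ("Csat", "Cuns", "Het", "HetNoX", "Tot"))
        print(f"  {k:8s}{row}")

# Values are convex combinations of atomic constants: each entry lies
# between the molecule's min and max atomic value of that property; a zero
# column means the group is empty (e.g. no saturated carbon in pyrrole).
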