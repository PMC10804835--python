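import numpy as np
import pytest

import ptmlee as p
from ptmlee.fixtures import FixtureSpec, generate_reactions


@pytest.fixture(scope="session")
def molecule_pool():
    return p.fixture_molecules()


@pytest.fixture(scope="session")
def small_reaction_set():
    """40 noise-free synthetic reactions, fixed seed."""
    return generate_reactions(FixtureSpec(n_reactions=40, seed=7))


@pytest.fixture(scope="session")
def noisy_reaction_set():
    return generate_reactions(FixtureSpec(n_reactions=60, seed=11, noise_sd=5.0))


# ---------------------------------------------------------------------------
# Independent dense-matrix descriptor oracle.  Kept deliberately naive
# (explicit matrix powers, python group scans) and separate from the
# package's iterative propagation path.

_PROP_COL = {"Zv": 0, "Vvdw": 1, "chi": 2, "alpha": 3, "EA": 4}
_HALOGENS = {"F", "Cl", "Br", "I"}


def _atom_rows():
    table = p.default_table()
    return {
        e: tuple(table.value(e, k) for k in ("Zv", "Vvdw", "chi", "alpha", "EA"))
        for e in table.elements
    }


def oracle_matrices(smiles):
    """(Pi, elements, unsaturated flags) from RDKit, dense arithmetic."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    n = mol.GetNumAtoms()
    rows = _atom_rows()
    el = [a.GetSymbol() for a in mol.GetAtoms()]
    uns = [False] * n
    adj = np.eye(n)
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        adj[i, j] = adj[j, i] = 1
        if str(b.GetBondType()) in ("DOUBLE", "TRIPLE", "AROMATIC"):
            uns[i] = uns[j] = True
    for a in mol.GetAtoms():
        if a.GetIsAromatic():
            uns[a.GetIdx()] = True
    chi = np.array([rows[e][2] for e in el])
    weighted = adj * chi[None, :]
    pi = weighted / weighted.sum(axis=1, keepdims=True)
    return pi, el, uns


def oracle_group(el, uns, group):
    idx = []
    for i, e in enumerate(el):
        if group == "Tot":
            idx.append(i)
        elif group == "Csat" and e == "C" and not uns[i]:
            idx.append(i)
        elif group == "Cuns" and e == "C" and uns[i]:
            idx.append(i)
        elif group == "Het" and e != "C":
            idx.append(i)
        elif group == "HetNoX" and e != "C" and e not in _HALOGENS:
            idx.append(i)
    return idx


def oracle_descriptor(smiles, prop, group, d_max=5):
    pi, el, uns = oracle_matrices(smiles)
    rows = _atom_rows()
    pvec = np.array([rows[e][_PROP_COL[prop]] for e in el])
    idx = oracle_group(el, uns, group)
    if not idx:
        return 0.0
    total = 0.0
    for d in range(1, d_max + 1):
        v = np.linalg.matrix_power(pi, d) @ pvec
        total += v[idx].mean()
    return total / d_max
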