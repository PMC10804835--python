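"""Markov-chain average atomic-property descriptors.

A molecule is modelled as a hydrogen-suppressed graph on which a Markov
chain walks: from atom i the walker stays put or steps to a bonded atom,
with probabilities proportional to the Sanderson electronegativity of the
destination atom over the closed neighborhood (self + bonded atoms).  The
descriptor D_k(m)_g averages an atomic property k, propagated d = 1..d_max
steps through the chain, over a named atom group g:

    D_k(m)_g = 1/(d_max * |g|) * sum_{d=1..d_max} sum_{a in g} (Pi^d p_k)_a

with five properties (Zv, Vvdw, chi, alpha, EA) and five groups (saturated
carbons, unsaturated carbons, heteroatoms, non-halogen heteroatoms, all
heavy atoms), giving a 5 x 5 block per molecule.  Every propagated value is
a convex combination of atomic values, so descriptors are bounded by the
per-molecule property range; an empty group contributes 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .atom_data import PROPERTIES, AtomPropertyTable, default_table

GROUPS = ("Csat", "Cuns", "Het", "HetNoX", "Tot")

HALOGENS = frozenset({"F", "Cl", "Br", "I"})

DEFAULT_D_MAX = 5


class SmilesParseError(ValueError):
    """Raised for SMILES strings RDKit cannot parse."""


@dataclass(frozen=True)
class MoleculeGraph:
    """Hydrogen-suppressed heavy-atom graph with atom-group masks."""

    smiles: str
    elements: tuple[str, ...]
    bonds: tuple[tuple[int, int], ...]
    groups: dict[str, np.ndarray] = field(repr=False)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def group_indices(self, group_g: str) -> np.ndarray:
        return np.flatnonzero(self.groups[group_g])


def parse_molecule(
    smiles: str, table: AtomPropertyTable | None = None
) -> MoleculeGraph:
    """Parse SMILES into a heavy-atom graph with group masks.

    Groups: a carbon is unsaturated iff aromatic or incident to a double or
    triple bond, saturated otherwise; heteroatoms are all non-carbons, with
    the non-halogen subset excluding F/Cl/Br/I.
    """
    table = table or default_table()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    if n == 0:
        raise SmilesParseError(f"SMILES has no heavy atoms: {smiles!r}")

    elements = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "*":
            raise SmilesParseError(f"wildcard atom in SMILES: {smiles!r}")
        if sym not in table:
            # surfaces the packaged-table gap immediately, not at descriptor time
            table[sym]
        elements.append(sym)

    unsaturated = np.zeros(n, dtype=bool)
    bonds = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bonds.append((min(i, j), max(i, j)))
        if bond.GetBondType() in (
            Chem.BondType.DOUBLE,
            Chem.BondType.TRIPLE,
            Chem.BondType.AROMATIC,
        ):
            unsaturated[i] = True
            unsaturated[j] = True
    for atom in mol.GetAtoms():
        if atom.GetIsAromatic():
            unsaturated[atom.GetIdx()] = True

    carbon = np.array([e == "C" for e in elements])
    het = ~carbon
    halogen = np.array([e in HALOGENS for e in elements])
    groups = {
        "Csat": carbon & ~unsaturated,
        "Cuns": carbon & unsaturated,
        "Het": het,
        "HetNoX": het & ~halogen,
        "Tot": np.ones(n, dtype=bool),
    }
    return MoleculeGraph(
        smiles=smiles,
        elements=tuple(elements),
        bonds=tuple(sorted(bonds)),
        groups=groups,
    )


def transition_matrix(
    mol: MoleculeGraph, table: AtomPropertyTable | None = None
) -> np.ndarray:
    """Row-stochastic walk matrix over the closed neighborhood.

    Pi[i, j] is proportional to the Sanderson electronegativity of the
    destination atom j, for j = i or j bonded to i, and 0 otherwise.  The
    same chain is shared by all five properties.
    """
    table = table or default_table()
    n = mol.n_atoms
    chi = np.array([table.value(e, "chi") for e in mol.elements])
    adj = np.eye(n, dtype=bool)
    for i, j in mol.bonds:
        adj[i, j] = adj[j, i] = True
    weights = np.where(adj, chi[np.newaxis, :], 0.0)
    return weights / weights.sum(axis=1, keepdims=True)


def property_vector(
    mol: MoleculeGraph, property_k: str, table: AtomPropertyTable | None = None
) -> np.ndarray:
    table = table or default_table()
    return np.array([table.value(e, property_k) for e in mol.elements])


def markov_atom_value(
    mol: MoleculeGraph,
    property_k: str,
    d: int,
    table: AtomPropertyTable | None = None,
) -> np.ndarray:
    """Per-atom property values after d steps of the chain: Pi^d p.

    d = 0 returns the raw atomic property vector.
    """
    if d < 0:
        raise ValueError("topological distance d must be >= 0")
    table = table or default_table()
    v = property_vector(mol, property_k, table)
    if d == 0:
        return v
    pi = transition_matrix(mol, table)
    for _ in range(d):
        v = pi @ v
    return v


def descriptor(
    mol: MoleculeGraph,
    property_k: str,
    group_g: str,
    d_max: int = DEFAULT_D_MAX,
    table: AtomPropertyTable | None = None,
) -> float:
    """Markov-averaged descriptor of one property over one atom group.

    Mean over d = 1..d_max of the group mean of the propagated property;
    0 for an empty group.
    """
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    table = table or default_table()
    idx = mol.group_indices(group_g)
    if idx.size == 0:
        return 0.0
    pi = transition_matrix(mol, table)
    v = property_vector(mol, property_k, table)
    total = 0.0
    for _ in range(d_max):
        v = pi @ v
        total += float(v[idx].mean())
    return total / d_max


@dataclass(frozen=True)
class DescriptorBlock:
    """All 25 property x group descriptors of one molecule."""

    molecule_id: str
    values: dict[tuple[str, str], float]
    d_max: int
    table_version: str

    def value(self, property_k: str, group_g: str) -> float:
        return self.values[(property_k, group_g)]

    def to_dict(self) -> dict[str, float]:
        """Flat mapping with ``<property>_<group>`` keys (CSV column order)."""
        return {
            f"{k}_{g}": self.values[(k, g)] for k in PROPERTIES for g in GROUPS
        }


def descriptor_block(
    mol: MoleculeGraph,
    molecule_id: str | None = None,
    d_max: int = DEFAULT_D_MAX,
    table: AtomPropertyTable | None = None,
) -> DescriptorBlock:
    """Compute the full 5 x 5 descriptor block of a molecule."""
    table = table or default_table()
    pi = transition_matrix(mol, table)
    values: dict[tuple[str, str], float] = {}
    group_idx = {g: mol.group_indices(g) for g in GROUPS}
    for k in PROPERTIES:
        v = property_vector(mol, k, table)
        sums = {g: 0.0 for g in GROUPS}
        for _ in range(d_max):
            v = pi @ v
            for g, idx in group_idx.items():
                if idx.size:
                    sums[g] += float(v[idx].mean())
        for g in GROUPS:
            values[(k, g)] = sums[g] / d_max if group_idx[g].size else 0.0
    return DescriptorBlock(
        molecule_id=molecule_id if molecule_id is not None else mol.smiles,
        values=values,
        d_max=d_max,
        table_version=table.version,
    )


def descriptor_blocks_frame(smiles_list, table=None, d_max=DEFAULT_D_MAX):
    """Descriptor blocks for many SMILES as a pandas DataFrame.

    One row per molecule, 25 named columns ``<property>_<group>``.
    """
    import pandas as pd

    rows = []
    for smi in smiles_list:
        block = descriptor_block(parse_molecule(smi, table), smi, d_max, table)
        rows.append({"smiles": smi, **block.to_dict()})
    return pd.DataFrame(rows)
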