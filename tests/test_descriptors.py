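"""Markov descriptor engine: graphs, chains, group averages."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

import ptmlee as p
from conftest import oracle_descriptor
from ptmlee.atom_data import PROPERTIES
from ptmlee.descriptors import GROUPS, SmilesParseError, property_vector
from ptmlee.atom_data import UnsupportedElementError


class TestParseMolecule:
    @pytest.mark.parametrize(
        "smiles, csat, cuns, het, hetnox",
        [
            ("C", 1, 0, 0, 0),
            ("c1ccccc1", 0, 6, 0, 0),
            ("CO", 1, 0, 1, 1),
            ("CCl", 1, 0, 1, 0),
            ("C=CC", 1, 2, 0, 0),
            ("CC(=O)O", 1, 1, 2, 2),
        ],
    )
    def test_group_masks(self, smiles, csat, cuns, het, hetnox):
        mol = p.parse_molecule(smiles)
        sizes = {g: mol.group_indices(g).size for g in GROUPS}
        assert sizes["Csat"] == csat
        assert sizes["Cuns"] == cuns
        assert sizes["Het"] == het
        assert sizes["HetNoX"] == hetnox
        assert sizes["Tot"] == mol.n_atoms

    def test_group_partition_invariants(self, molecule_pool):
        for smi in molecule_pool:
            mol = p.parse_molecule(smi)
            csat = set(mol.group_indices("Csat"))
            cuns = set(mol.group_indices("Cuns"))
            het = set(mol.group_indices("Het"))
            hetnox = set(mol.group_indices("HetNoX"))
            assert csat.isdisjoint(cuns)
            assert hetnox <= het
            carbons = {i for i, e in enumerate(mol.elements) if e == "C"}
            assert csat | cuns == carbons
            assert het == set(range(mol.n_atoms)) - carbons

    def test_invalid_smiles_names_string(self):
        with pytest.raises(SmilesParseError, match="not-a-smiles"):
            p.parse_molecule("not-a-smiles")

    def test_unsupported_element(self):
        with pytest.raises(UnsupportedElementError):
            p.parse_molecule("[Se]")


class TestTransitionMatrix:
    def test_single_atom(self):
        pi = p.transition_matrix(p.parse_molecule("C"))
        assert pi.shape == (1, 1) and pi[0, 0] == 1.0

    def test_symmetric_diatomic(self):
        pi = p.transition_matrix(p.parse_molecule("CC"))
        np.testing.assert_allclose(pi, 0.5 * np.ones((2, 2)))

    def test_co_hand_arithmetic(self):
        """Rows of CO proportional to destination electronegativities."""
        tab = p.default_table()
        chi_c, chi_o = tab.value("C", "chi"), tab.value("O", "chi")
        pi = p.transition_matrix(p.parse_molecule("CO"))
        np.testing.assert_allclose(pi[0, 1], chi_o / (chi_c + chi_o), rtol=1e-14)
        np.testing.assert_allclose(pi[1, 0], chi_c / (chi_c + chi_o), rtol=1e-14)

    def test_rows_stochastic_and_sparsity(self, molecule_pool):
        for smi in molecule_pool:
            mol = p.parse_molecule(smi)
            pi = p.transition_matrix(mol)
            np.testing.assert_allclose(pi.sum(axis=1), 1.0, atol=1e-12)
            bonded = {frozenset(b) for b in mol.bonds}
            for i in range(mol.n_atoms):
                for j in range(mol.n_atoms):
                    expect = i == j or frozenset((i, j)) in bonded
                    assert (pi[i, j] > 0) == expect


class TestMarkovAtomValue:
    def test_d0_is_raw_property(self):
        mol = p.parse_molecule("CCO")
        np.testing.assert_array_equal(
            p.markov_atom_value(mol, "chi", 0), property_vector(mol, "chi")
        )

    def test_single_atom_stationary(self):
        mol = p.parse_molecule("O")
        for d in (0, 1, 5):
            assert p.markov_atom_value(mol, "alpha", d)[0] == pytest.approx(
                p.default_table().value("O", "alpha")
            )

    def test_matches_matrix_square(self):
        mol = p.parse_molecule("CCO")
        pi = p.transition_matrix(mol)
        expected = np.linalg.matrix_power(pi, 2) @ property_vector(mol, "chi")
        np.testing.assert_allclose(
            p.markov_atom_value(mol, "chi", 2), expected, atol=1e-12
        )

    def test_convexity(self, molecule_pool):
        """Propagated values stay inside the molecule's property range."""
        for smi in molecule_pool[:30]:
            mol = p.parse_molecule(smi)
            for k in PROPERTIES:
                pvec = property_vector(mol, k)
                for d in (1, 3, 5):
                    v = p.markov_atom_value(mol, k, d)
                    assert np.all(v >= pvec.min() - 1e-10)
                    assert np.all(v <= pvec.max() + 1e-10)


class TestDescriptor:
    def test_empty_group_is_zero(self):
        mol = p.parse_molecule("CC")
        assert p.descriptor(mol, "chi", "Het") == 0.0

    def test_symmetric_chain_keeps_value(self):
        mol = p.parse_molecule("CC")
        for k in PROPERTIES:
            assert p.descriptor(mol, k, "Tot") == pytest.approx(
                p.default_table().value("C", k), abs=1e-12
            )

    @pytest.mark.parametrize("group", GROUPS)
    @pytest.mark.parametrize("prop", PROPERTIES)
    def test_cco_matches_oracle(self, prop, group):
        mol = p.parse_molecule("CCO")
        assert p.descriptor(mol, prop, group) == pytest.approx(
            oracle_descriptor("CCO", prop, group), abs=1e-12
        )

    def test_pool_matches_oracle(self, molecule_pool):
        """Dense matrix-power oracle agreement over the whole pool."""
        for smi in molecule_pool:
            mol = p.parse_molecule(smi)
            block = p.descriptor_block(mol)
            for k in PROPERTIES:
                for g in GROUPS:
                    assert block.value(k, g) == pytest.approx(
                        oracle_descriptor(smi, k, g), abs=1e-10
                    ), (smi, k, g)


class TestDescriptorBlock:
    def test_single_carbon(self):
        block = p.descriptor_block(p.parse_molecule("C"))
        tab = p.default_table()
        for k in PROPERTIES:
            assert block.value(k, "Csat") == pytest.approx(tab.value("C", k))
            assert block.value(k, "Het") == 0.0

    def test_benzene_cuns_equals_tot(self):
        block = p.descriptor_block(p.parse_molecule("c1ccccc1"))
        for k in PROPERTIES:
            assert block.value(k, "Csat") == 0.0
            assert block.value(k, "Cuns") == pytest.approx(block.value(k, "Tot"))

    def test_entries_bounded_by_property_range(self, molecule_pool):
        tab = p.default_table()
        for smi in molecule_pool[:40]:
            mol = p.parse_molecule(smi)
            block = p.descriptor_block(mol)
            for k in PROPERTIES:
                vals = [tab.value(e, k) for e in mol.elements]
                for g in GROUPS:
                    if mol.group_indices(g).size:
                        assert min(vals) - 1e-10 <= block.value(k, g) <= max(vals) + 1e-10

    def test_records_table_version(self):
        block = p.descriptor_block(p.parse_molecule("CCO"))
        assert block.table_version == p.default_table().version


@settings(max_examples=25, deadline=None)
@given(st.data())
def test_permutation_invariance(data):
    """Descriptors are identical under atom reordering of the same molecule."""
    pool = p.fixture_molecules()
    smi = data.draw(st.sampled_from(pool[:40]))
    mol = Chem.MolFromSmiles(smi)
    n = mol.GetNumAtoms()
    perm = data.draw(st.permutations(range(n)))
    renumbered = Chem.MolToSmiles(Chem.RenumberAtoms(mol, list(perm)), canonical=False)
    if Chem.MolFromSmiles(renumbered) is None:
        return
    b1 = p.descriptor_block(p.parse_molecule(smi)).to_dict()
    b2 = p.descriptor_block(p.parse_molecule(renumbered)).to_dict()
    for key in b1:
        assert b1[key] == pytest.approx(b2[key], abs=1e-10)


def test_disconnected_components_block_diagonal():
    """Salt-style dotted SMILES equal the per-component computation."""
    combined = p.descriptor_block(p.parse_molecule("CCO.Cl"))
    pi = p.transition_matrix(p.parse_molecule("CCO.Cl"))
    # no cross-component transitions
    assert np.all(pi[:3, 3] == 0) and np.all(pi[3, :3] == 0)
    parts = [p.descriptor_block(p.parse_molecule(s)) for s in ("CCO", "Cl")]
    # Tot descriptor of the union is the atom-count-weighted mean of parts
    for k in PROPERTIES:
        merged = (3 * parts[0].value(k, "Tot") + 1 * parts[1].value(k, "Tot")) / 4
        assert combined.value(k, "Tot") == pytest.approx(merged, abs=1e-10)
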