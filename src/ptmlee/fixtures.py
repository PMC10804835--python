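"""Synthetic reaction tables for testing and parameter-recovery studies.

The generator emulates the *statistical schema* of a curated literature
table — five molecule roles as SMILES, lattice-valued conditions, a signed
enantiomeric excess generated by a known pairwise linear model plus
Gaussian noise — not its actual chemistry.  Molecules come from pools of
small (<= 8 heavy atoms) organics so the dense-matrix descriptor oracle
used in tests stays fast.

Generation picks one baseline reaction and sets every other reaction's
ee_R to the baseline value plus the true model's predicted delta over the
realized perturbation operators plus noise.  Because the perturbation
features are differences of per-reaction feature vectors, pairwise deltas
among generated reactions are exactly linear in the PTOs with intercept 0;
the shipped true model therefore carries e0 = 0, making all 13 fitted
parameters identifiable from pair regression.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .heuristics_mc import DATASET_GRIDS, ConditionGrid, mt19937
from .ptml import BlockCache, LinearEEModel, PTOVector, classic_features
from .reactions import CanonicalReaction, ReactionRecord, canonical_ee_R

#: gentle generating model: realistic sign structure, amplitudes chosen so
#: synthetic ee values rarely leave the physical [-100, 100] range
FIXTURE_TRUE_MODEL = LinearEEModel(
    model_id="fixture_true",
    a=(-0.2, -0.1, 0.05),
    b=(3.0, 5.0, 4.0, 6.0, 8.0, 10.0, 0.5, 2.0, 1.5),
    e0=0.0,
)

_CHAIN_HETERO = ["", "O", "N", "S", "F", "Cl", "Br", "I"]

_EXTRA_SMILES = [
    "C=C", "C=CC", "CC=CC", "C=CCC", "C#C", "C#CC", "CC#CC",
    "C=O", "CC=O", "CCC=O", "CC(=O)C", "CC(=O)O", "COC(=O)C", "CC(=O)N",
    "COC", "CCOC", "CCOCC", "COCC=O", "CN(C)C", "CCNCC", "CNC",
    "C(F)(F)F", "FC(F)(F)C", "ClCCl", "ClC(Cl)Cl", "BrCCBr",
    "OCO", "OCCO", "OCCCO", "OCC(O)C", "NCCN", "NCCO", "SCCS", "CSC", "CS(=O)C",
    "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1", "C1CCCCCC1",
    "C1CO1", "C1CCO1", "C1CCOC1", "C1CCOCC1", "C1CCNC1", "C1CCNCC1",
    "C1CCSC1", "C1CCSCC1", "O1CCOCC1",
    "c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "Oc1ccccc1", "Nc1ccccc1",
    "Fc1ccccc1", "Clc1ccccc1", "Brc1ccccc1", "Sc1ccccc1",
    "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1", "c1cncnc1", "c1cnccn1",
    "Cc1ccncc1", "Cc1ccoc1", "Cc1ccsc1", "Cc1cc[nH]c1",
    "c1cnoc1", "c1cnsc1", "c1cn[nH]c1", "c1ocnc1", "c1scnc1",
    "O=C1CCCC1", "O=C1CCCN1", "O=C1CCCO1", "O=C1CCCCC1",
    "OP(O)O", "OP(=O)(O)O", "OS(=O)(=O)O", "O=S(C)C", "CP(C)C",
    "C[Si](C)C", "O[Si](C)C",
]


def fixture_molecules(n: int | None = None, max_heavy: int = 8) -> list[str]:
    """A deterministic pool of small-molecule canonical SMILES.

    Built combinatorially (alkyl chains x terminal heteroatoms, branched
    variants, plus a curated list of alkenes, carbonyls, rings and
    heteroaromatics), parsed with RDKit, deduplicated by canonical SMILES
    and capped at ``max_heavy`` heavy atoms.
    """
    raw: list[str] = []
    for k in range(1, 7):
        chain = "C" * k
        for het in _CHAIN_HETERO:
            raw.append(chain + het)
    for k in range(2, 5):
        for het in ["O", "N", "Cl"]:
            raw.append("C" * k + f"({het})C")  # branched position
    raw.extend(_EXTRA_SMILES)

    seen: dict[str, None] = {}
    for smi in raw:
        mol = Chem.MolFromSmiles(smi)
        if mol is None or mol.GetNumAtoms() > max_heavy:
            continue
        seen.setdefault(Chem.MolToSmiles(mol), None)
    pool = list(seen)
    if n is not None:
        if n > len(pool):
            raise ValueError(f"pool holds only {len(pool)} molecules")
        pool = pool[:n]
    return pool


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic reaction table."""

    n_reactions: int
    seed: int
    noise_sd: float = 0.0
    true_model: LinearEEModel = FIXTURE_TRUE_MODEL
    pools: dict[str, Sequence[str]] | None = None
    grids: dict[str, ConditionGrid] = field(default_factory=lambda: DATASET_GRIDS)
    base_ee: float = 10.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.n_reactions < 1:
            raise ValueError("need at least one reaction")


class FixtureSpecError(ValueError):
    """The generating model clips most synthetic ee values."""


def default_pools() -> dict[str, list[str]]:
    """Role-specific SMILES pools drawn from the fixture molecule list."""
    pool = fixture_molecules()
    # disjoint-ish slices keep role descriptors varied
    return {
        "sub": pool[0::5],
        "nuc": pool[1::5],
        "cat": pool[2::5],
        "solv": pool[3::5],
        "prod": pool[4::5],
    }


_FAMILY_LETTERS = "abcdefgh"


def generate_reactions(spec: FixtureSpec) -> list[CanonicalReaction]:
    """Generate a synthetic canonical reaction table.

    Deterministic under ``spec.seed``; raises ``FixtureSpecError`` when
    more than half of the generated ee values clip at +-100 (the true
    model is too steep for the realized perturbations).
    """
    rng = mt19937(spec.seed)
    pools = spec.pools or default_pools()
    cache = BlockCache()

    drafts = []
    for i in range(spec.n_reactions):
        roles = {
            role: pools[role][int(rng.integers(0, len(pools[role])))]
            for role in pools
        }
        T = spec.grids["T_C"].values()
        t = spec.grids["t_h"].values()
        load = spec.grids["load_pct"].values()
        fam = "".join(
            _FAMILY_LETTERS[zlib.crc32(roles[role].encode()) % 4]
            for role in ("sub", "nuc", "cat")
        )
        drafts.append(
            ReactionRecord(
                rxn_id=f"fx{i:04d}",
                family=fam,
                sub_smiles=roles["sub"],
                nuc_smiles=roles["nuc"],
                cat_smiles=roles["cat"],
                solv_smiles=roles["solv"],
                prod_smiles=roles["prod"],
                cat_config="R",
                prod_config="R",
                T_C=float(T[int(rng.integers(0, len(T)))]),
                t_h=float(t[int(rng.integers(0, len(t)))]),
                load_pct=float(load[int(rng.integers(0, len(load)))]),
                ee_pct=0.0,
                source="synthetic fixture",
            )
        )

    # per-reaction feature vectors; pair PTOs are their differences
    feats = [
        classic_features(canonical_ee_R(rec), cache(canonical_ee_R(rec)))
        for rec in drafts
    ]
    base = int(rng.integers(0, spec.n_reactions))
    coef = spec.true_model.coefficients

    out = []
    n_clipped = 0
    for i, rec in enumerate(drafts):
        delta = float(coef @ (feats[i] - feats[base])) + spec.true_model.e0
        ee = spec.base_ee + delta
        if spec.noise_sd > 0:
            ee += float(rng.normal(0.0, spec.noise_sd))
        if not -100.0 <= ee <= 100.0:
            n_clipped += 1
            ee = float(np.clip(ee, -100.0, 100.0))
        prod_config = "R" if ee > 0 else ("S" if ee < 0 else "racemic")
        rec = ReactionRecord(
            **{
                **rec.__dict__,
                "prod_config": prod_config,
                "ee_pct": abs(ee),
            }
        )
        out.append(canonical_ee_R(rec))
    if n_clipped > spec.n_reactions / 2:
        raise FixtureSpecError(
            f"{n_clipped}/{spec.n_reactions} synthetic ee values clipped; "
            "the generating model is too steep for these pools/grids"
        )
    return out


def perturb_pairs(cases, noise_sd: float, seed: int):
    """Add iid Gaussian noise to the pair targets (delta ee_R).

    This is the design for parameter-recovery simulations: the OLS
    standard errors assume independent pair-level errors, which holds
    here, whereas noise injected per *reaction* is shared across every
    pair containing that reaction and makes the reported SEs
    anti-conservative.
    """
    from dataclasses import replace as _replace

    rng = mt19937(seed)
    return [
        _replace(c, delta_ee_R=c.delta_ee_R + float(rng.normal(0.0, noise_sd)))
        for c in cases
    ]


# ---------------------------------------------------------------------------
# Frozen worked pair: every intermediate precomputed by the dense-matrix and
# dot-product oracles and stored as a regression fixture.  Regenerate with
# scripts in examples/ if the atom table version changes.

TOY_QUERY = ReactionRecord(
    rxn_id="toy_q",
    family="aaa",
    sub_smiles="CCO",
    nuc_smiles="c1cc[nH]c1",
    cat_smiles="OP(=O)(O)O",
    solv_smiles="C1CCOC1",
    prod_smiles="OCCc1cc[nH]c1",
    cat_config="R",
    prod_config="R",
    T_C=25.0,
    t_h=24.0,
    load_pct=20.0,
    ee_pct=80.0,
    source="frozen toy fixture",
)

TOY_REFERENCE = ReactionRecord(
    rxn_id="toy_r",
    family="aaa",
    sub_smiles="CC(=O)C",
    nuc_smiles="c1ccoc1",
    cat_smiles="OP(O)O",
    solv_smiles="ClCCl",
    prod_smiles="CC(O)Cc1ccoc1",
    cat_config="S",
    prod_config="S",
    T_C=-10.0,
    t_h=48.0,
    load_pct=10.0,
    ee_pct=60.0,
    source="frozen toy fixture",
)

#: PTOVector of (TOY_QUERY, TOY_REFERENCE) precomputed with a dense
#: matrix-power oracle against atom table v1.0; asserted vs live computation
TOY_EXPECTED_PTO: dict[str, float] = {
    "dLoad": 10.0,
    "dT": 35.0,
    "dt": -24.0,
    "d_alpha_cat_Cuns": 0.0,
    "d_alpha_prod_HetNoX": 0.03659576286788302,
    "d_EA_prod_Csat": -0.011206175523885253,
    "d_EA_cat_HetNoX": 0.006055287645899909,
    "d_chi_nuc_Het": -0.17182237000399025,
    "d_chi_cat_HetNoX": 0.009646115564586832,
    "d_V_sub_Tot": -0.5767253833382213,
    "d_Zv_cat_Cuns": 0.0,
    "d_Zv_solv_Cuns": 0.0,
}

#: pairwise prediction (published model) for the toy pair, same oracle
TOY_EXPECTED_PREDICTION: float = 3.9077651977965253


def toy_worked_pair():
    """The frozen toy pair with its precomputed PTOs and prediction."""
    q = canonical_ee_R(TOY_QUERY)
    r = canonical_ee_R(TOY_REFERENCE)
    return q, r, dict(TOY_EXPECTED_PTO), TOY_EXPECTED_PREDICTION
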