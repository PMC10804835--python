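"""Perturbation-theory linear models for enantiomeric excess.

The pairwise model predicts the signed excess of a *query* reaction from a
*reference* reaction with known outcome plus linear corrections in twelve
query-minus-reference perturbation operators (PTOs): three condition deltas
(catalyst loading, temperature, time) and nine Markov-descriptor deltas on
fixed property/role/group slots,

    ee_R(q)_calc = ee_R(r)_obs + sum_k a_k dV_k + sum_k b_k dD_k + e0.

The classic (reference-free) model uses the same twelve slots on raw query
values.  Both published coefficient sets ship verbatim as fixed models; an
OLS refit path reproduces the regression machinery on new pair sets.

The published coefficients were fitted against the original authors'
descriptor implementation, whose exact chain weighting is not public; with
this package's own descriptor engine they define the same functional form
but are not expected to reproduce the printed dataset statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorBlock, descriptor_block, parse_molecule
from .reactions import ROLES, CanonicalReaction

#: the nine descriptor PTO slots as (name, property, role, group)
DESCRIPTOR_SLOTS = (
    ("d_alpha_cat_Cuns", "alpha", "cat", "Cuns"),
    ("d_alpha_prod_HetNoX", "alpha", "prod", "HetNoX"),
    ("d_EA_prod_Csat", "EA", "prod", "Csat"),
    ("d_EA_cat_HetNoX", "EA", "cat", "HetNoX"),
    ("d_chi_nuc_Het", "chi", "nuc", "Het"),
    ("d_chi_cat_HetNoX", "chi", "cat", "HetNoX"),
    ("d_V_sub_Tot", "Vvdw", "sub", "Tot"),
    ("d_Zv_cat_Cuns", "Zv", "cat", "Cuns"),
    ("d_Zv_solv_Cuns", "Zv", "solv", "Cuns"),
)

CONDITION_SLOTS = ("dLoad", "dT", "dt")

PTO_NAMES = CONDITION_SLOTS + tuple(s[0] for s in DESCRIPTOR_SLOTS)


class MissingRoleError(ValueError):
    """A reaction lacks a SMILES for one of its five roles."""


@dataclass(frozen=True)
class PTOVector:
    """The twelve perturbation inputs of the pairwise model."""

    dLoad: float
    dT: float
    dt: float
    d_alpha_cat_Cuns: float
    d_alpha_prod_HetNoX: float
    d_EA_prod_Csat: float
    d_EA_cat_HetNoX: float
    d_chi_nuc_Het: float
    d_chi_cat_HetNoX: float
    d_V_sub_Tot: float
    d_Zv_cat_Cuns: float
    d_Zv_solv_Cuns: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PTO_NAMES])

    def __neg__(self) -> "PTOVector":
        return PTOVector(*(-self.as_array()))


@dataclass(frozen=True)
class LinearEEModel:
    """Fixed-coefficient linear ee model: 3 condition + 9 descriptor terms.

    ``a`` multiplies (dLoad, dT, dt), ``b`` the nine descriptor slots in
    ``DESCRIPTOR_SLOTS`` order, ``e0`` is the intercept.  ``stats`` carries
    whatever fit statistics are known (R, R2, SEE, F, n, coefficient SEs).
    """

    model_id: str
    a: tuple[float, float, float]
    b: tuple[float, ...]
    e0: float
    stats: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.a) != 3 or len(self.b) != 9:
            raise ValueError("model needs 3 condition + 9 descriptor terms")

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([*self.a, *self.b])

    def to_json(self, path) -> None:
        payload = {
            "model_id": self.model_id,
            "a": list(self.a),
            "b": list(self.b),
            "e0": self.e0,
            "stats": self.stats,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LinearEEModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            model_id=payload["model_id"],
            a=tuple(payload["a"]),
            b=tuple(payload["b"]),
            e0=payload["e0"],
            stats=payload.get("stats", {}),
        )


#: published pairwise model (query-minus-reference deltas, raw units)
PAIRWISE_MODEL = LinearEEModel(
    model_id="pairwise_published",
    a=(-0.82, -0.34, 0.21),
    b=(
        -174.37,
        -1534.17,
        -215.98,
        -1747.12,
        -42.49,
        750.76,
        -34.19,
        22.04,
        -12.46,
    ),
    e0=-0.91,
    stats={"n_train": 78732, "R_train": 0.84, "SEE_train": 51.67, "F": 15238.7},
)

#: published classic single-reaction model.  NOTE: its printed scale
#: (e.g. 912.48 per loading %) is implausibly steep; shipped as printed.
CLASSIC_MODEL = LinearEEModel(
    model_id="classic_published",
    a=(912.48, 21.90, -194.76),
    b=(
        -13.21,
        -45.02,
        830.06,
        -0.34,
        0.22,
        -2024.05,
        -178.69,
        -1678.05,
        -34.41,
    ),
    e0=-0.70,
    stats={"n": 332, "R2": 0.74, "SEE": 37.1, "F": 59.2},
)


RoleBlocks = dict[str, DescriptorBlock]


def reaction_blocks(rxn: CanonicalReaction, table=None) -> RoleBlocks:
    """Descriptor blocks for a reaction's five molecule roles."""
    blocks = {}
    for role in ROLES:
        smi = rxn.smiles(role)
        if not smi:
            raise MissingRoleError(f"{rxn.rxn_id}: missing SMILES for {role}")
        blocks[role] = descriptor_block(parse_molecule(smi, table), smi, table=table)
    return blocks


class BlockCache:
    """Memoizes descriptor blocks per reaction id across a pair set."""

    def __init__(self, table=None):
        self._table = table
        self._cache: dict[str, RoleBlocks] = {}

    def __call__(self, rxn: CanonicalReaction) -> RoleBlocks:
        key = rxn.rxn_id
        if key not in self._cache:
            self._cache[key] = reaction_blocks(rxn, self._table)
        return self._cache[key]


def pto_vector(
    q: CanonicalReaction,
    r: CanonicalReaction,
    q_blocks: RoleBlocks | None = None,
    r_blocks: RoleBlocks | None = None,
    table=None,
) -> PTOVector:
    """Query-minus-reference perturbation operators for one pair."""
    q_blocks = q_blocks or reaction_blocks(q, table)
    r_blocks = r_blocks or reaction_blocks(r, table)
    qT, qt, qload = q.conditions
    rT, rt, rload = r.conditions
    deltas = {"dLoad": qload - rload, "dT": qT - rT, "dt": qt - rt}
    for name, prop, role, group in DESCRIPTOR_SLOTS:
        deltas[name] = q_blocks[role].value(prop, group) - r_blocks[role].value(
            prop, group
        )
    return PTOVector(**deltas)


def predict_delta_ee(pto: PTOVector, model: LinearEEModel = PAIRWISE_MODEL) -> float:
    """Predicted ee_R difference (query minus reference), in % points."""
    return float(model.coefficients @ pto.as_array() + model.e0)


@dataclass(frozen=True)
class EEPrediction:
    """Clipped prediction with the raw model output retained."""

    ee_R: float
    raw: float
    clipped: bool
    cip: str  # R | S | racemic
    reference_id: str | None = None


def _finalize(raw: float, reference_id: str | None = None) -> EEPrediction:
    clipped = not -100.0 <= raw <= 100.0
    value = float(np.clip(raw, -100.0, 100.0))
    cip = "R" if value > 0 else ("S" if value < 0 else "racemic")
    return EEPrediction(
        ee_R=value, raw=raw, clipped=clipped, cip=cip, reference_id=reference_id
    )


def predict_ee_from_reference(
    q: CanonicalReaction,
    r: CanonicalReaction,
    model: LinearEEModel = PAIRWISE_MODEL,
    q_blocks: RoleBlocks | None = None,
    r_blocks: RoleBlocks | None = None,
    table=None,
) -> EEPrediction:
    """Pairwise prediction: reference ee_R plus the linear perturbation.

    The sign of the result is the predicted product CIP label: positive
    means (R), negative (S), zero racemic.  Results are clipped to the
    physical range [-100, 100] with the raw value kept alongside.
    """
    pto = pto_vector(q, r, q_blocks, r_blocks, table)
    raw = r.ee_R + predict_delta_ee(pto, model)
    return _finalize(raw, reference_id=r.rxn_id)


def classic_features(q: CanonicalReaction, q_blocks: RoleBlocks | None = None, table=None) -> np.ndarray:
    """Raw (non-delta) feature vector of the classic model, in slot order."""
    q_blocks = q_blocks or reaction_blocks(q, table)
    qT, qt, qload = q.conditions
    feats = [qload, qT, qt]
    for _, prop, role, group in DESCRIPTOR_SLOTS:
        feats.append(q_blocks[role].value(prop, group))
    return np.array(feats)


def predict_ee_classic(
    q: CanonicalReaction,
    model: LinearEEModel = CLASSIC_MODEL,
    q_blocks: RoleBlocks | None = None,
    table=None,
) -> EEPrediction:
    """Reference-free prediction from the query's own conditions/descriptors."""
    raw = float(model.coefficients @ classic_features(q, q_blocks, table) + model.e0)
    return _finalize(raw)


@dataclass(frozen=True)
class PairedCase:
    """One query/reference pair with its PTOs and observed delta ee_R."""

    query: CanonicalReaction
    reference: CanonicalReaction
    pto: PTOVector
    delta_ee_R: float


def generate_pairs(
    reactions: Sequence[CanonicalReaction],
    mode: str = "all",
    k: int | None = None,
    seed: int | None = None,
    table=None,
) -> list[PairedCase]:
    """Ordered query/reference pairs (q != r) over a reaction set.

    mode="all" yields all n*(n-1) ordered pairs; mode="sample" draws k of
    them uniformly without replacement, reproducibly under ``seed``.
    """
    n = len(reactions)
    if n < 2:
        raise ValueError("need at least two reactions to form pairs")
    index_pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    if mode == "sample":
        if k is None:
            raise ValueError("mode='sample' requires k")
        if k > len(index_pairs):
            raise ValueError(
                f"requested {k} pairs but only {len(index_pairs)} exist"
            )
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(index_pairs), size=k, replace=False)
        index_pairs = [index_pairs[i] for i in chosen]
    elif mode != "all":
        raise ValueError(f"unknown pair-generation mode: {mode!r}")

    cache = BlockCache(table)
    cases = []
    for i, j in index_pairs:
        q, r = reactions[i], reactions[j]
        cases.append(
            PairedCase(
                query=q,
                reference=r,
                pto=pto_vector(q, r, cache(q), cache(r)),
                delta_ee_R=q.ee_R - r.ee_R,
            )
        )
    return cases


def _design_matrix(cases: Sequence[PairedCase]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([c.pto.as_array() for c in cases])
    y = np.array([c.delta_ee_R for c in cases])
    return X, y


class SingularDesignError(ValueError):
    """The regression design matrix is rank deficient."""


def fit_mlr(
    cases: Sequence[PairedCase] | None = None,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    model_id: str = "refit",
) -> LinearEEModel:
    """Ordinary-least-squares refit of the 12-term linear model.

    Accepts either a list of paired cases (pairwise form, target delta
    ee_R) or an explicit design matrix/target (classic form).  Reports R,
    R2, SEE (residual standard error), F and per-coefficient SE/t/p.
    """
    import statsmodels.api as sm

    if cases is not None:
        X, y = _design_matrix(cases)
    if X is None or y is None:
        raise ValueError("provide cases or an explicit X, y")
    if len(y) < 20:
        raise ValueError("need at least 20 cases to fit")
    Xc = sm.add_constant(X, prepend=False, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        sds = X.std(axis=0)
        degenerate = [PTO_NAMES[i] for i in np.flatnonzero(sds == 0)]
        raise SingularDesignError(
            "design matrix is rank deficient"
            + (f"; constant columns: {degenerate}" if degenerate else "")
        )
    res = sm.OLS(y, Xc).fit()
    coef = res.params
    stats = {
        "n": int(res.nobs),
        "R2": float(res.rsquared),
        "R": float(np.sqrt(max(res.rsquared, 0.0))),
        "SEE": float(np.sqrt(res.mse_resid)),
        "F": float(res.fvalue),
        "p_model": float(res.f_pvalue),
        "coef_se": [float(v) for v in res.bse],
        "coef_t": [float(v) for v in res.tvalues],
        "coef_p": [float(v) for v in res.pvalues],
    }
    return LinearEEModel(
        model_id=model_id,
        a=tuple(coef[:3]),
        b=tuple(coef[3:12]),
        e0=float(coef[12]),
        stats=stats,
    )


def fit_report(model: LinearEEModel) -> pd.DataFrame:
    """Coefficient table (name, coeff, SE, t, p) mirroring published layout."""
    names = list(PTO_NAMES) + ["intercept"]
    coeffs = list(model.coefficients) + [model.e0]
    se = model.stats.get("coef_se", [np.nan] * 13)
    t = model.stats.get("coef_t", [np.nan] * 13)
    p = model.stats.get("coef_p", [np.nan] * 13)
    return pd.DataFrame(
        {"variable": names, "coeff": coeffs, "SE": se, "t": t, "p_level": p}
    )
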