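"""Reference-selection heuristics and Monte-Carlo condition enrichment.

The pairwise model gives a different prediction for every choice of
reference reaction, so a heuristic collapses them to one number per query:

* H1 — pick the single reference with minimal overall perturbation (the
  most similar reaction) and use its prediction.  "Minimal" is measured by
  a norm over the 12 PTO components; the default standardizes each
  component by its SD over all candidate pairs and takes the L1 norm, so
  heterogeneous units (degC, hours, descriptor units) compare fairly.
  Alternative norms (L2, coefficient-weighted absolute model delta) are
  pluggable and recorded in the result.
* H2 — average the predictions over every available reference.

Enrichment clones existing reactions and resamples only their conditions
(T, t, loading) on the dataset's min/step/max grids with a seeded
Mersenne-Twister stream; structures, descriptors and ee_R are copied
unchanged, on the grounds that condition changes of one grid step do not
measurably move the enantiomeric excess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .ptml import (
    BlockCache,
    LinearEEModel,
    PAIRWISE_MODEL,
    PTOVector,
    predict_delta_ee,
    pto_vector,
)
from .reactions import CanonicalReaction


class ReferenceSelectionError(ValueError):
    """No usable reference reactions were supplied."""


class EnrichmentPlanError(ValueError):
    """An enrichment plan names a family absent from the data."""


@dataclass(frozen=True)
class HeuristicResult:
    """Outcome of one heuristic prediction for one query."""

    query_id: str
    heuristic: str  # H1 | H2
    ee_R_pred: float
    cip_pred: str
    reference_id: str | None = None  # H1
    n_references: int | None = None  # H2
    pto_norm: float | None = None  # H1: norm of the winning pair
    norm_strategy: str | None = None
    per_reference: tuple[float, ...] | None = None  # H2, optional
    clipped: bool = False


def _standardized_l1(ptos: np.ndarray, _model: LinearEEModel) -> np.ndarray:
    sd = ptos.std(axis=0)
    sd[sd == 0] = 1.0  # constant component carries no ranking information
    return np.abs(ptos / sd).sum(axis=1)


def _standardized_l2(ptos: np.ndarray, _model: LinearEEModel) -> np.ndarray:
    sd = ptos.std(axis=0)
    sd[sd == 0] = 1.0
    return np.sqrt(((ptos / sd) ** 2).sum(axis=1))


def _model_weighted(ptos: np.ndarray, model: LinearEEModel) -> np.ndarray:
    """|predicted delta ee| contribution of each pair, intercept excluded."""
    return np.abs(ptos @ model.coefficients)


NORM_STRATEGIES: dict[str, Callable[[np.ndarray, LinearEEModel], np.ndarray]] = {
    "std_l1": _standardized_l1,
    "std_l2": _standardized_l2,
    "model_delta": _model_weighted,
}


def _candidate_ptos(
    q: CanonicalReaction,
    refs: Sequence[CanonicalReaction],
    cache: BlockCache,
) -> tuple[list[CanonicalReaction], list[PTOVector]]:
    kept, ptos = [], []
    for r in refs:
        if r.rxn_id == q.rxn_id:
            continue  # leave-self-out
        kept.append(r)
        ptos.append(pto_vector(q, r, cache(q), cache(r)))
    if not kept:
        raise ReferenceSelectionError(
            f"no reference reactions available for query {q.rxn_id}"
        )
    return kept, ptos


def select_reference_H1(
    q: CanonicalReaction,
    refs: Sequence[CanonicalReaction],
    model: LinearEEModel = PAIRWISE_MODEL,
    norm: str = "std_l1",
    cache: BlockCache | None = None,
) -> HeuristicResult:
    """Minimal-perturbation single-reference prediction.

    Ties on the norm break to the lowest reference id so results are
    deterministic regardless of input order.
    """
    cache = cache or BlockCache()
    kept, ptos = _candidate_ptos(q, refs, cache)
    scores = NORM_STRATEGIES[norm](np.array([p.as_array() for p in ptos]), model)
    order = sorted(range(len(kept)), key=lambda i: (scores[i], kept[i].rxn_id))
    best = order[0]
    r = kept[best]
    pred = r.ee_R + predict_delta_ee(ptos[best], model)
    clipped = not -100.0 <= pred <= 100.0
    value = float(np.clip(pred, -100.0, 100.0))
    return HeuristicResult(
        query_id=q.rxn_id,
        heuristic="H1",
        ee_R_pred=value,
        cip_pred="R" if value > 0 else ("S" if value < 0 else "racemic"),
        reference_id=r.rxn_id,
        pto_norm=float(scores[best]),
        norm_strategy=norm,
        clipped=clipped,
    )


def predict_H2(
    q: CanonicalReaction,
    refs: Sequence[CanonicalReaction],
    model: LinearEEModel = PAIRWISE_MODEL,
    cache: BlockCache | None = None,
    keep_per_reference: bool = False,
) -> HeuristicResult:
    """All-references average prediction (unclipped per-reference values)."""
    cache = cache or BlockCache()
    kept, ptos = _candidate_ptos(q, refs, cache)
    preds = [r.ee_R + predict_delta_ee(p, model) for r, p in zip(kept, ptos)]
    mean = float(np.mean(preds))
    clipped = not -100.0 <= mean <= 100.0
    value = float(np.clip(mean, -100.0, 100.0))
    return HeuristicResult(
        query_id=q.rxn_id,
        heuristic="H2",
        ee_R_pred=value,
        cip_pred="R" if value > 0 else ("S" if value < 0 else "racemic"),
        n_references=len(kept),
        per_reference=tuple(preds) if keep_per_reference else None,
        clipped=clipped,
    )


@dataclass(frozen=True)
class ConditionGrid:
    """Lattice of admissible values: min + k*step, clamped at max."""

    min: float
    max: float
    step: float

    def __post_init__(self):
        if self.min > self.max:
            raise ValueError("grid min exceeds max")
        if self.step <= 0:
            raise ValueError("grid step must be positive")

    @property
    def n_max(self) -> int:
        """Largest multiplier; ceil makes the max clamp reachable."""
        return math.ceil((self.max - self.min) / self.step)

    def values(self) -> np.ndarray:
        """All lattice points min + k*step that do not exceed max."""
        ks = np.arange(math.floor((self.max - self.min) / self.step + 1e-9) + 1)
        return self.min + ks * self.step


#: condition grids of the curated dataset (T degC, t h, loading mol%)
DATASET_GRIDS = {
    "T_C": ConditionGrid(-78.0, 66.0, 10.0),
    "t_h": ConditionGrid(1.0, 240.0, 1.0),
    "load_pct": ConditionGrid(2.0, 30.0, 1.0),
}


def mc_condition_value(grid: ConditionGrid, rng: np.random.Generator) -> float:
    """One Monte-Carlo draw: min + u*step with integer u in {0..n_max},
    clamped to the grid maximum."""
    u = int(rng.integers(0, grid.n_max + 1))
    raw = grid.min + u * grid.step
    return min(raw, grid.max)


def mt19937(seed: int) -> np.random.Generator:
    """The Mersenne-Twister (MT19937) stream used for all MC sampling."""
    return np.random.Generator(np.random.MT19937(seed))


def enrich_dataset(
    reactions: Sequence[CanonicalReaction],
    plan: dict[str, int],
    seed: int,
    grids: dict[str, ConditionGrid] | None = None,
) -> list[CanonicalReaction]:
    """Append MC-resampled clones per family.

    ``plan`` maps family code -> number of synthetic records to add.  Each
    clone copies a family member's structures and ee_R and redraws T, t and
    loading on the grids.  Synthetic ids are suffixed ``_mc<i>`` and their
    records carry ``source='synthetic MC'``.
    """
    grids = grids or DATASET_GRIDS
    by_family: dict[str, list[CanonicalReaction]] = {}
    for rxn in reactions:
        by_family.setdefault(rxn.family, []).append(rxn)
    unknown = sorted(set(plan) - set(by_family))
    if unknown:
        raise EnrichmentPlanError(f"plan names unknown families: {unknown}")

    rng = mt19937(seed)
    out = list(reactions)
    for family in sorted(plan):
        members = by_family[family]
        for i in range(plan[family]):
            parent = members[int(rng.integers(0, len(members)))]
            rec = replace(
                parent.record,
                rxn_id=f"{parent.rxn_id}_mc{i}",
                T_C=mc_condition_value(grids["T_C"], rng),
                t_h=mc_condition_value(grids["t_h"], rng),
                load_pct=mc_condition_value(grids["load_pct"], rng),
                source="synthetic MC",
            )
            out.append(
                CanonicalReaction(record=rec, ee_R=parent.ee_R, mirrored=parent.mirrored)
            )
    return out


def family_abundances(reactions: Sequence[CanonicalReaction]) -> dict[str, float]:
    """Relative family abundances in percent."""
    counts: dict[str, int] = {}
    for rxn in reactions:
        counts[rxn.family] = counts.get(rxn.family, 0) + 1
    n = len(reactions)
    return {fam: 100.0 * c / n for fam, c in counts.items()}
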