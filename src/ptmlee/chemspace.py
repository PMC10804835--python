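"""Chemical-space enumeration and screening runs.

The accessible reaction space factorizes into molecular combinations times
condition settings:

    N_max = N(Sub)*N(Nuc)*N(Cat)*N(Solv) * prod_k Range(V_k)/Step(V_k)
          = N_comb * N_exp

Three screening modes mirror how the predictor is used in practice:
similarity search (predict queries against a reference table and report
the most similar reference), conditions scan (fixed molecules, lattice of
T/t/loading), and structural scan (cartesian product of molecule
libraries at fixed conditions).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .heuristics_mc import (
    BlockCache,
    ConditionGrid,
    HeuristicResult,
    predict_H2,
    select_reference_H1,
)
from .ptml import LinearEEModel, PAIRWISE_MODEL
from .reactions import CanonicalReaction, ReactionRecord, canonical_ee_R

REPORT_COLUMNS = [
    "query_id",
    "mode",
    "heuristic",
    "model_id",
    "ee_pred",
    "cip_pred",
    "ref_id",
    "ref_source",
    "pto_norm",
    "clipped",
    "error",
]


class GridError(ValueError):
    """A condition grid is degenerate or outside server limits."""


class ScanCapError(ValueError):
    """A structural scan exceeds the configured safety cap."""


@dataclass(frozen=True)
class SpaceSpec:
    """Counts of molecule options per role plus the three condition grids."""

    n_sub: int
    n_nuc: int
    n_cat: int
    n_solv: int
    grid_T: ConditionGrid
    grid_t: ConditionGrid
    grid_load: ConditionGrid

    def __post_init__(self):
        for name in ("n_sub", "n_nuc", "n_cat", "n_solv"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def count_space(spec: SpaceSpec) -> tuple[int, int, int]:
    """(N_comb, N_exp, N_max) of a reaction space.

    Per-condition experiment counts range/step are kept at full precision
    and only the final N_exp product is rounded, so fractional counts
    (e.g. a 144-degree range on a 10-degree step) do not truncate early.
    """
    n_comb = spec.n_sub * spec.n_nuc * spec.n_cat * spec.n_solv
    n_exp_exact = 1.0
    for grid in (spec.grid_T, spec.grid_t, spec.grid_load):
        if grid.step <= 0:
            raise GridError("condition grid step must be positive")
        n_exp_exact *= (grid.max - grid.min) / grid.step
    n_exp = round(n_exp_exact)
    return n_comb, n_exp, n_comb * n_exp


#: server-side scan limits for the conditions scan (T degC, t h, load mol%)
SCAN_GRID_LIMITS = {
    "T_C": ConditionGrid(-78.0, 70.0, 20.0),
    "t_h": ConditionGrid(0.5, 72.0, 1.0),
    "load_pct": ConditionGrid(2.0, 5.0, 1.0),
}

#: default fixed conditions of the conditions scan
SCAN_DEFAULTS = {"T_C": 25.0, "t_h": 0.5, "load_pct": 2.0}


def _predict_one(
    q: CanonicalReaction,
    refs: Sequence[CanonicalReaction],
    heuristic: str,
    model: LinearEEModel,
    cache: BlockCache,
) -> HeuristicResult:
    if heuristic == "H1":
        return select_reference_H1(q, refs, model, cache=cache)
    if heuristic == "H2":
        return predict_H2(q, refs, model, cache=cache)
    raise ValueError(f"unknown heuristic: {heuristic!r}")


def _ref_source(refs: Sequence[CanonicalReaction], ref_id: str | None) -> str:
    if ref_id is None:
        return ""
    for r in refs:
        if r.rxn_id == ref_id:
            return r.record.source
    return ""


def run_similarity(
    queries: Sequence[CanonicalReaction | ReactionRecord],
    refs: Sequence[CanonicalReaction],
    heuristic: str = "H1",
    model: LinearEEModel = PAIRWISE_MODEL,
) -> pd.DataFrame:
    """Predict each query against the reference table.

    Unusable queries (e.g. unparsable SMILES) yield a row with the error
    message instead of aborting the batch; an empty reference set aborts.
    """
    if not refs:
        raise ReferenceSetEmptyError("reference set is empty")
    cache = BlockCache()
    rows = []
    for q in queries:
        if isinstance(q, ReactionRecord):
            q = canonical_ee_R(q)
        row = {
            "query_id": q.rxn_id,
            "mode": "similarity",
            "heuristic": heuristic,
            "model_id": model.model_id,
        }
        try:
            res = _predict_one(q, refs, heuristic, model, cache)
            row.update(
                ee_pred=res.ee_R_pred,
                cip_pred=res.cip_pred,
                ref_id=res.reference_id or "",
                ref_source=_ref_source(refs, res.reference_id),
                pto_norm=res.pto_norm,
                clipped=res.clipped,
                error="",
            )
        except Exception as exc:  # per-row failure, run continues
            row.update(
                ee_pred=float("nan"),
                cip_pred="",
                ref_id="",
                ref_source="",
                pto_norm=float("nan"),
                clipped=False,
                error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


class ReferenceSetEmptyError(ValueError):
    pass


def run_conditions_scan(
    template: CanonicalReaction,
    refs: Sequence[CanonicalReaction],
    grids: dict[str, ConditionGrid] | None = None,
    heuristic: str = "H1",
    model: LinearEEModel = PAIRWISE_MODEL,
) -> pd.DataFrame:
    """Predict over a lattice of conditions for fixed molecules.

    Grids must sit inside the server limits; the returned frame has one
    row per (T, t, load) lattice point plus the scan columns, and the
    best setting is the row maximizing |ee_pred|.
    """
    grids = grids or SCAN_GRID_LIMITS
    for key, grid in grids.items():
        lim = SCAN_GRID_LIMITS[key]
        if grid.min < lim.min or grid.max > lim.max:
            raise GridError(
                f"{key} grid [{grid.min}, {grid.max}] outside server limits "
                f"[{lim.min}, {lim.max}]"
            )
    cache = BlockCache()
    rows = []
    for T in grids["T_C"].values():
        for t in grids["t_h"].values():
            for load in grids["load_pct"].values():
                rec = replace(
                    template.record,
                    rxn_id=f"{template.rxn_id}_T{T}_t{t}_L{load}",
                    T_C=float(T),
                    t_h=float(t),
                    load_pct=float(load),
                )
                q = CanonicalReaction(rec, template.ee_R, template.mirrored)
                res = _predict_one(q, refs, heuristic, model, cache)
                rows.append(
                    {
                        "query_id": q.rxn_id,
                        "mode": "conditions-scan",
                        "heuristic": heuristic,
                        "model_id": model.model_id,
                        "T_C": float(T),
                        "t_h": float(t),
                        "load_pct": float(load),
                        "ee_pred": res.ee_R_pred,
                        "cip_pred": res.cip_pred,
                        "ref_id": res.reference_id or "",
                        "clipped": res.clipped,
                    }
                )
    frame = pd.DataFrame(rows)
    frame.attrs["best"] = frame.iloc[frame["ee_pred"].abs().idxmax()].to_dict()
    return frame


def run_structural_scan(
    libraries: dict[str, Sequence[str]],
    template: CanonicalReaction,
    refs: Sequence[CanonicalReaction],
    heuristic: str = "H1",
    model: LinearEEModel = PAIRWISE_MODEL,
    cap: int = 10000,
) -> pd.DataFrame:
    """Cartesian product of per-role SMILES libraries at fixed conditions.

    ``libraries`` maps roles (sub/nuc/cat/solv/prod) to SMILES lists;
    roles not listed keep the template's molecule.  Refuses requests whose
    combination count exceeds ``cap``.
    """
    roles = sorted(libraries)
    pools = [list(libraries[r]) for r in roles]
    n_comb = 1
    for p in pools:
        n_comb *= len(p)
    if n_comb > cap:
        raise ScanCapError(
            f"structural scan of {n_comb} combinations exceeds cap {cap}"
        )
    rows = []
    queries = []
    for combo in itertools.product(*pools):
        fields = {f"{role}_smiles": smi for role, smi in zip(roles, combo)}
        rec = replace(
            template.record,
            rxn_id=template.rxn_id + "_" + "_".join(combo),
            **fields,
        )
        queries.append(CanonicalReaction(rec, template.ee_R, template.mirrored))
    frame = run_similarity(queries, refs, heuristic, model)
    frame["mode"] = "structural-scan"
    return frame


def write_report(frame: pd.DataFrame, csv_path, json_path=None, header: dict | None = None) -> None:
    """Write a report as CSV (with provenance header comments) and JSON."""
    with open(csv_path, "w", encoding="utf-8") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        frame.to_csv(fh, index=False)
    if json_path is not None:
        payload = {"header": header or {}, "rows": frame.to_dict(orient="records")}
        import json as _json

        with open(json_path, "w", encoding="utf-8") as fh:
            _json.dump(payload, fh, indent=2, default=float)
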