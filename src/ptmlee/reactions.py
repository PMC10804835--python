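"""Reaction records, chirality canonicalization and table I/O.

Each record describes one catalytic enantioselective reaction: five molecule
roles (substrate, nucleophile, catalyst, solvent, product), the catalyst and
product CIP configurations, the operating conditions (temperature in deg C,
time in hours, catalyst loading in mol%) and the observed enantiomeric
excess in percent.

All modelling happens in the (R)-catalyst frame.  A reaction run with the
(S)-catalyst is mirrored — its product label flipped R<->S — and the signed
excess ee_R is then +ee for an (R)-product, -ee for an (S)-product and 0 for
a racemate.  The mirror step encodes the empirical symmetry that swapping
the catalyst's chirality inverts the product configuration at unchanged
magnitude, and lets achiral topological descriptors carry no chirality at
all: every bit of stereochemical information lives in the sign of ee_R.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CSV_COLUMNS = [
    "rxn_id",
    "family",
    "sub_smiles",
    "nuc_smiles",
    "cat_smiles",
    "solv_smiles",
    "prod_smiles",
    "cat_config",
    "prod_config",
    "T_C",
    "t_h",
    "load_pct",
    "ee_pct",
    "source",
]

ROLES = ("sub", "nuc", "cat", "solv", "prod")

# warn-only physical bounds of the curated literature set
T_WARN_BOUNDS = (-78.0, 66.0)


class SchemaError(ValueError):
    """Reaction CSV is missing required columns."""


class ValidationError(ValueError):
    """A reaction record violates a hard invariant."""


class CompoundCodeError(ValueError):
    """A compound code does not follow the Xyznn scheme."""


@dataclass(frozen=True)
class ReactionRecord:
    """One literature reaction as reported."""

    rxn_id: str
    family: str
    sub_smiles: str
    nuc_smiles: str
    cat_smiles: str
    solv_smiles: str
    prod_smiles: str
    cat_config: str  # R | S
    prod_config: str  # R | S | racemic
    T_C: float
    t_h: float
    load_pct: float
    ee_pct: float
    source: str = ""

    def __post_init__(self):
        if self.t_h <= 0:
            raise ValidationError(f"{self.rxn_id}: reaction time must be > 0")
        if self.load_pct <= 0:
            raise ValidationError(f"{self.rxn_id}: catalyst loading must be > 0")
        if not 0 <= self.ee_pct <= 100:
            raise ValidationError(
                f"{self.rxn_id}: observed ee must lie in [0, 100]"
            )
        if self.cat_config not in ("R", "S"):
            raise ValidationError(
                f"{self.rxn_id}: catalyst configuration must be R or S"
            )
        if self.prod_config not in ("R", "S", "racemic"):
            raise ValidationError(
                f"{self.rxn_id}: product configuration must be R, S or racemic"
            )
        if self.prod_config == "racemic" and self.ee_pct != 0:
            raise ValidationError(
                f"{self.rxn_id}: racemic product with nonzero ee"
            )

    def smiles(self, role: str) -> str:
        return getattr(self, f"{role}_smiles")


@dataclass(frozen=True)
class CanonicalReaction:
    """A reaction expressed in the (R)-catalyst frame with signed ee_R."""

    record: ReactionRecord
    ee_R: float
    mirrored: bool

    @property
    def rxn_id(self) -> str:
        return self.record.rxn_id

    @property
    def family(self) -> str:
        return self.record.family

    @property
    def conditions(self) -> tuple[float, float, float]:
        """(T_C, t_h, load_pct)."""
        r = self.record
        return (r.T_C, r.t_h, r.load_pct)

    def smiles(self, role: str) -> str:
        return self.record.smiles(role)


def canonical_ee_R(rec: ReactionRecord) -> CanonicalReaction:
    """Express a reaction in the (R)-catalyst frame.

    If the catalyst was (S), mirror the reaction (flip the product label);
    then ee_R = +ee for (R)-product, -ee for (S)-product, 0 for racemic.
    """
    prod = rec.prod_config
    mirrored = rec.cat_config == "S"
    if mirrored:
        if prod == "R":
            prod = "S"
        elif prod == "S":
            prod = "R"
        rec = replace(rec, cat_config="R", prod_config=prod)
    if prod == "racemic":
        ee_r = 0.0
    elif prod == "R":
        ee_r = rec.ee_pct
    else:
        ee_r = -rec.ee_pct
    return CanonicalReaction(record=rec, ee_R=ee_r, mirrored=mirrored)


def canonicalize(records: Iterable[ReactionRecord]) -> list[CanonicalReaction]:
    return [canonical_ee_R(r) for r in records]


def load_reaction_table(path) -> list[ReactionRecord]:
    """Load and validate a reaction CSV (schema ``CSV_COLUMNS``)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns and c != "rxn_id"]
    if missing:
        raise SchemaError(f"reaction table missing columns: {missing}")
    records = []
    for i, row in frame.iterrows():
        rid = row["rxn_id"] if "rxn_id" in frame.columns and row.get("rxn_id") else str(i)
        try:
            records.append(
                ReactionRecord(
                    rxn_id=rid,
                    family=row["family"],
                    sub_smiles=row["sub_smiles"],
                    nuc_smiles=row["nuc_smiles"],
                    cat_smiles=row["cat_smiles"],
                    solv_smiles=row["solv_smiles"],
                    prod_smiles=row["prod_smiles"],
                    cat_config=row["cat_config"],
                    prod_config=row["prod_config"],
                    T_C=float(row["T_C"]),
                    t_h=float(row["t_h"]),
                    load_pct=float(row["load_pct"]),
                    ee_pct=float(row["ee_pct"]),
                    source=row.get("source", ""),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return records


def write_reaction_table(reactions: Sequence, path) -> None:
    """Write records (or canonical reactions) back to the CSV schema."""
    rows = []
    for r in reactions:
        rec = r.record if isinstance(r, CanonicalReaction) else r
        rows.append({c: getattr(rec, c) for c in CSV_COLUMNS})
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


@dataclass(frozen=True)
class ConditionStats:
    """Per-condition summary: n, mean, sd, min, max, range, step, n_expr."""

    condition: str
    n: int
    mean: float
    sd: float
    min: float
    max: float
    range: float
    step: float

    @property
    def n_expr(self) -> float:
        """Number of distinguishable settings, range / step."""
        return self.range / self.step


DEFAULT_STEPS = {"T_C": 10.0, "t_h": 1.0, "load_pct": 1.0}


def condition_stats(
    records: Sequence[ReactionRecord | CanonicalReaction],
    steps: dict[str, float] | None = None,
) -> dict[str, ConditionStats]:
    """Summary statistics of T, t and loading over a reaction table.

    SD is the sample (n-1) standard deviation; the step (minimal change a
    chemist would make) comes from configuration, defaulting to 10 degC for
    T and 1 for time and loading.
    """
    if not records:
        raise ValueError("need at least one record")
    steps = {**DEFAULT_STEPS, **(steps or {})}
    out = {}
    for cond in ("T_C", "t_h", "load_pct"):
        vals = np.array(
            [
                getattr(r.record if isinstance(r, CanonicalReaction) else r, cond)
                for r in records
            ],
            dtype=float,
        )
        out[cond] = ConditionStats(
            condition=cond,
            n=len(vals),
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            min=float(vals.min()),
            max=float(vals.max()),
            range=float(vals.max() - vals.min()),
            step=steps[cond],
        )
    return out


_CODE_RE = re.compile(r"^(S|Nu|F|Cat)(?P<rest>[0-9a-z]+)$")


def family_letter(compound_code: str) -> str:
    """Family letter of an Xyznn compound code.

    The code starts with a role prefix (S, Nu, F/Cat), followed by the
    structural family letter, an optional sub-family letter and an ID
    number; some legacy codes interleave digits before the family letter,
    so the first lowercase letter after the prefix is taken.
    """
    m = _CODE_RE.match(compound_code)
    if not m:
        raise CompoundCodeError(f"malformed compound code: {compound_code!r}")
    for ch in m.group("rest"):
        if ch.isalpha():
            return ch
    raise CompoundCodeError(
        f"compound code has no family letter: {compound_code!r}"
    )


def family_code(sub_code: str, nuc_code: str, cat_code: str) -> str:
    """Concatenate the substrate, nucleophile and catalyst family letters."""
    return (
        family_letter(sub_code) + family_letter(nuc_code) + family_letter(cat_code)
    )


def catalogue_families(reactions: Sequence[CanonicalReaction]) -> pd.DataFrame:
    """Per-family counts and mean ee_R split by canonical product config.

    Columns: family, n_reacc, n_R, n_S, mean_ee_R_Rprod (>= 0 by
    construction), mean_ee_R_Sprod (<= 0), sorted by descending n_reacc.
    """
    rows = {}
    for rxn in reactions:
        fam = rxn.family
        entry = rows.setdefault(fam, {"R": [], "S": []})
        if rxn.ee_R > 0:
            entry["R"].append(rxn.ee_R)
        elif rxn.ee_R < 0:
            entry["S"].append(rxn.ee_R)
        else:
            entry.setdefault("rac", []).append(0.0)
    table = []
    for fam, entry in rows.items():
        n_r, n_s = len(entry["R"]), len(entry["S"])
        n_rac = len(entry.get("rac", []))
        table.append(
            {
                "family": fam,
                "n_reacc": n_r + n_s + n_rac,
                "n_R": n_r,
                "n_S": n_s,
                "mean_ee_R_Rprod": float(np.mean(entry["R"])) if n_r else np.nan,
                "mean_ee_R_Sprod": float(np.mean(entry["S"])) if n_s else np.nan,
            }
        )
    return (
        pd.DataFrame(table)
        .sort_values("n_reacc", ascending=False)
        .reset_index(drop=True)
    )
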