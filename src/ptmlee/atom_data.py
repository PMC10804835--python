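"""Packaged atomic property table.

Five atomic properties drive the Markov-chain descriptors: valence-electron
count (Zv), van der Waals volume (Vvdw, A^3), Sanderson electronegativity
(chi), static dipole polarizability (alpha, A^3) and electron affinity
(EA, eV).  Values are standard literature constants shipped as a versioned
CSV so every descriptor block can record which table produced it.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import pandas as pd

PROPERTIES = ("Zv", "Vvdw", "chi", "alpha", "EA")

TABLE_VERSION = "1.0"


class UnsupportedElementError(KeyError):
    """Raised when a molecule contains an element absent from the table."""


@dataclass(frozen=True)
class AtomProperties:
    """The five property values for one element."""

    element: str
    Zv: float
    Vvdw: float
    chi: float
    alpha: float
    EA: float

    def __getitem__(self, key: str) -> float:
        if key not in PROPERTIES:
            raise KeyError(key)
        return getattr(self, key)


class AtomPropertyTable:
    """Element symbol -> five atomic properties.

    The default table covers H, B, C, N, O, F, Si, P, S, Cl, Br, I.
    """

    def __init__(self, frame: pd.DataFrame, version: str = TABLE_VERSION):
        self.version = version
        self._rows: dict[str, AtomProperties] = {}
        for rec in frame.itertuples(index=False):
            self._rows[rec.element] = AtomProperties(
                element=rec.element,
                Zv=float(rec.Zv),
                Vvdw=float(rec.Vvdw),
                chi=float(rec.chi),
                alpha=float(rec.alpha),
                EA=float(rec.EA),
            )
        self._validate()

    def _validate(self) -> None:
        for sym, row in self._rows.items():
            if row.Vvdw <= 0 or row.alpha <= 0 or row.chi <= 0:
                raise ValueError(
                    f"invalid atomic parameters for {sym}: "
                    "Vvdw, alpha and chi must be positive"
                )

    def __contains__(self, element: str) -> bool:
        return element in self._rows

    def __getitem__(self, element: str) -> AtomProperties:
        try:
            return self._rows[element]
        except KeyError:
            raise UnsupportedElementError(
                f"element {element!r} is not in atom property table "
                f"v{self.version}"
            ) from None

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self._rows)

    def value(self, element: str, property_k: str) -> float:
        return self[element][property_k]


@functools.lru_cache(maxsize=1)
def default_table() -> AtomPropertyTable:
    """Load the packaged versioned atom property table."""
    ref = resources.files("ptmlee.data").joinpath("atom_properties.csv")
    with ref.open("r", encoding="utf-8") as fh:
        frame = pd.read_csv(fh, comment="#")
    return AtomPropertyTable(frame)
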