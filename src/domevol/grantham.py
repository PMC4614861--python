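"""Grantham physicochemical distance and alignment-aware GV/GD scores.

Grantham's distance between two amino acids is a quadratic form over three
side-chain properties — composition c (atomic weight ratio of non-carbon
elements), polarity p and molecular volume v:

    D(x, y) = rho * sqrt(alpha*(c_x-c_y)^2 + beta*(p_x-p_y)^2 + gamma*(v_x-v_y)^2)

with alpha = 1.833, beta = 0.1018, gamma = 0.000399. The scale rho is fixed
by the convention that the mean of all 190 unordered pair distances is 100;
we derive it from that constraint at construction rather than hard-coding it.

The alignment-aware extension scores a missense substitution against the
residues observed at its alignment column: GV (Grantham variation) is the
quadratic form over the per-property ranges spanned by the observed residues,
and GD (Grantham deviation) measures how far the substituting residue falls
outside those ranges (0 if inside all three). An invariant column gives
GV = 0 and GD equal to the plain Grantham distance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from .io import DomevolError

#: (composition, polarity, volume) per residue, Grantham (1974).
PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0), "R": (0.65, 10.5, 124.0), "L": (0.0, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5), "T": (0.71, 8.6, 61.0), "A": (0.0, 8.1, 31.0),
    "V": (0.0, 5.9, 84.0), "G": (0.74, 9.0, 3.0), "I": (0.0, 5.2, 111.0),
    "F": (0.0, 5.2, 132.0), "Y": (0.20, 6.2, 136.0), "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0), "Q": (0.89, 10.5, 85.0), "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0), "D": (1.38, 13.0, 54.0), "E": (0.92, 12.3, 83.0),
    "M": (0.0, 5.7, 105.0), "W": (0.13, 5.4, 170.0),
}

ALPHA, BETA, GAMMA = 1.833, 0.1018, 0.000399


@dataclass(frozen=True)
class GranthamTable:
    properties: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(PROPERTIES)
    )
    alpha: float = ALPHA
    beta: float = BETA
    gamma: float = GAMMA
    rho: float = field(default=0.0)

    def __post_init__(self) -> None:
        if len(self.properties) != 20:
            raise DomevolError("Grantham table needs exactly 20 residues")
        if self.rho == 0.0:
            # scale so the mean over all 190 unordered pairs is exactly 100
            mean_raw = sum(
                self._raw(a, b)
                for a, b in itertools.combinations(self.properties, 2)
            ) / 190.0
            object.__setattr__(self, "rho", 100.0 / mean_raw)

    def _raw(self, a: str, b: str) -> float:
        ca, pa, va = self.properties[a]
        cb, pb, vb = self.properties[b]
        return math.sqrt(
            self.alpha * (ca - cb) ** 2
            + self.beta * (pa - pb) ** 2
            + self.gamma * (va - vb) ** 2
        )

    def distance(self, a: str, b: str) -> float:
        for aa in (a, b):
            if aa not in self.properties:
                raise DomevolError(f"unknown residue {aa!r}")
        return self.rho * self._raw(a, b)


DEFAULT_TABLE = GranthamTable()


def grantham_distance(aa1: str, aa2: str, table: GranthamTable | None = None) -> float:
    """Grantham distance between two amino acids (0 on the diagonal; the
    published matrix ranges from 5 for Leu/Ile to 215 for Cys/Trp)."""
    return (table or DEFAULT_TABLE).distance(aa1.upper(), aa2.upper())


def distance_matrix(table: GranthamTable | None = None) -> "pd.DataFrame":
    """The full 20x20 Grantham matrix as a DataFrame."""
    import pandas as pd

    table = table or DEFAULT_TABLE
    aas = sorted(table.properties)
    return pd.DataFrame(
        [[table.distance(a, b) for b in aas] for a in aas], index=aas, columns=aas
    )


def gvgd(
    column_residues: str | list[str],
    alt_aa: str,
    table: GranthamTable | None = None,
) -> tuple[float, float]:
    """(GV, GD) for a substitution scored against an alignment column.

    `column_residues` is the multiset of residues observed at the column
    (gaps/X must already be removed). GV is the quadratic form over the
    observed per-property ranges; GD uses, per property, the deviation of the
    substituting residue from the observed [min, max] interval (0 inside).
    """
    table = table or DEFAULT_TABLE
    residues = [r.upper() for r in column_residues]
    if not residues:
        raise DomevolError("empty column")
    for aa in residues + [alt_aa.upper()]:
        if aa not in table.properties:
            raise DomevolError(f"unknown residue {aa!r}")
    props = [table.properties[r] for r in residues]
    lo = [min(p[k] for p in props) for k in range(3)]
    hi = [max(p[k] for p in props) for k in range(3)]
    coeffs = (table.alpha, table.beta, table.gamma)
    gv = table.rho * math.sqrt(
        sum(c * (h - l) ** 2 for c, l, h in zip(coeffs, lo, hi))
    )
    alt = table.properties[alt_aa.upper()]
    dev = [
        0.0 if lo[k] <= alt[k] <= hi[k] else min(abs(alt[k] - lo[k]), abs(alt[k] - hi[k]))
        for k in range(3)
    ]
    gd = table.rho * math.sqrt(sum(c * d**2 for c, d in zip(coeffs, dev)))
    return gv, gd
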