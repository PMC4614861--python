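"""Dickerson-style rate-vs-divergence-time analysis.

Each lineage comparison contributes one point: the mean pairwise divergence
(changes per 100 sites) between two groups of sequences, plotted at the
divergence time of the two lineages. A through-origin least-squares fit gives
the substitution rate (changes per 100 sites per MY); its reciprocal is the
unit evolutionary period (UEP), the number of MY per 1% sequence change.
Conserved reference proteins (histone H4, cytochrome c) supply baselines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Alignment, DomevolError
from .pairwise import pairwise_p_distance

_PKG_DATA = Path(__file__).parent / "data"


@dataclass(frozen=True)
class LineageComparison:
    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    mya: float

    def __post_init__(self) -> None:
        if self.mya < 0:
            raise DomevolError(f"{self.name!r}: divergence time must be >= 0")
        if not self.group_a or not self.group_b:
            raise DomevolError(f"{self.name!r}: groups must be nonempty")
        if set(self.group_a) & set(self.group_b):
            raise DomevolError(f"{self.name!r}: groups must be disjoint")


@dataclass
class DivergenceConfig:
    comparisons: list[LineageComparison]
    reference_zero: str = ""

    @classmethod
    def from_json(cls, path: str | Path) -> "DivergenceConfig":
        with open(path) as fh:
            raw = json.load(fh)
        comps = [
            LineageComparison(
                c["name"], tuple(c["group_a"]), tuple(c["group_b"]), float(c["mya"])
            )
            for c in raw["comparisons"]
        ]
        return cls(comps, raw.get("reference_zero", ""))


def default_divergence_config() -> DivergenceConfig:
    """Shipped lineage comparisons and divergence times for the TRPM8 set."""
    return DivergenceConfig.from_json(_PKG_DATA / "divergence_times.json")


@dataclass
class RateCurve:
    points: pd.DataFrame  # columns: name, mya, changes_per_100
    slope: float  # changes per 100 sites per MY
    label: str = ""

    @property
    def uep(self) -> float:
        """Unit evolutionary period: MY per 1% change (1/slope)."""
        if self.slope <= 0:
            return np.inf
        return 1.0 / self.slope

    @property
    def residuals(self) -> np.ndarray:
        return (
            self.points["changes_per_100"] - self.slope * self.points["mya"]
        ).to_numpy()


def lineage_pair_change(
    msa: Alignment,
    group_a: list[str],
    group_b: list[str],
    *,
    correction: str | None = None,
) -> float:
    """Mean changes per 100 sites over all cross pairs A x B (pairwise
    deletion; raw p-distance by default, 'poisson' correction optional)."""
    if not group_a or not group_b:
        raise DomevolError("groups must be nonempty")
    vals = []
    for a in group_a:
        for b in group_b:
            if a == b:
                continue
            p, compared = pairwise_p_distance(
                msa[a].residues, msa[b].residues
            )
            if compared == 0:
                raise DomevolError(f"no comparable columns for ({a!r}, {b!r})")
            if correction == "poisson":
                p = -np.log(1.0 - p)
            vals.append(100.0 * p)
    if not vals:
        raise DomevolError("empty cross-pair set")
    return float(np.mean(vals))


def rate_points(
    msa: Alignment, config: DivergenceConfig, *, correction: str | None = None
) -> pd.DataFrame:
    """One (MYA, mean changes/100) point per configured lineage comparison."""
    rows = []
    for comp in config.comparisons:
        change = lineage_pair_change(
            msa, list(comp.group_a), list(comp.group_b), correction=correction
        )
        rows.append({"name": comp.name, "mya": comp.mya, "changes_per_100": change})
    return pd.DataFrame(rows)


def fit_rate_curve(points: pd.DataFrame, label: str = "") -> RateCurve:
    """Through-origin least squares: slope = sum(t*y) / sum(t^2)."""
    if len(points) < 2:
        raise DomevolError("need at least 2 points")
    t = points["mya"].to_numpy(dtype=float)
    y = points["changes_per_100"].to_numpy(dtype=float)
    if np.all(t == 0):
        raise DomevolError("all divergence times are zero")
    slope = float(np.sum(t * y) / np.sum(t * t))
    return RateCurve(points.reset_index(drop=True), max(slope, 0.0), label=label)


def baseline_compare(
    target: RateCurve, baselines: dict[str, RateCurve]
) -> pd.DataFrame:
    """Rank the target against baseline curves by fitted slope (most conserved
    first) and report each curve's slope, UEP and rank."""
    rows = [{"label": target.label or "target", "slope": target.slope, "uep": target.uep}]
    for name, curve in baselines.items():
        rows.append({"label": name, "slope": curve.slope, "uep": curve.uep})
    df = pd.DataFrame(rows).sort_values("slope", kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
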