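"""Per-region conservation scoring and across-region heterogeneity testing.

A region's score is the set of all pairwise divergences (changes per 100
sites, pairwise deletion) computed over the alignment columns the region
spans on the reference. Lower scores mean stronger conservation. Rate
heterogeneity across regions is assessed with a Kruskal-Wallis rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import GAP, Alignment, DomevolError, RegionMap, ref_to_column
from .pairwise import pairwise_p_distance

#: Dayhoff's six physicochemical groups, used to call a two-state column
#: "conservative" (both states in one group) rather than "variable".
DAYHOFF_GROUPS = (
    set("AGPST"),
    set("DENQ"),
    set("HKR"),
    set("ILMV"),
    set("FWY"),
    set("C"),
)


@dataclass
class RegionScore:
    name: str
    divergences: np.ndarray  # all pairwise changes-per-100-sites in the region
    n_rows: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.divergences))

    @property
    def median(self) -> float:
        return float(np.median(self.divergences))


@dataclass
class HeterogeneityResult:
    statistic: float  # Kruskal-Wallis H, tie-corrected
    pvalue: float
    group_sizes: dict[str, int] = field(default_factory=dict)


def extract_region(msa: Alignment, region_map: RegionMap, name: str) -> Alignment:
    """Sub-alignment spanning a named region's columns on the reference.

    Rows that are entirely gaps within the slice are dropped with a warning.
    """
    region = region_map[name]
    ref = msa[region_map.reference_id]
    ungapped_len = len(ref.ungapped)
    if region.end > ungapped_len:
        raise DomevolError(
            f"region {name!r} ({region.start}-{region.end}) outside reference "
            f"length {ungapped_len}"
        )
    c0 = ref_to_column(msa, region_map.reference_id, region.start)
    c1 = ref_to_column(msa, region_map.reference_id, region.end)
    sub = msa.slice_columns(range(c0, c1 + 1))
    keep = [r for r in sub if set(r.residues) != {GAP}]
    if len(keep) < len(sub.records):
        dropped = [r.id for r in sub if set(r.residues) == {GAP}]
        warnings.warn(f"region {name!r}: dropped all-gap row(s) {dropped}")
    if len(keep) < 2:
        raise DomevolError(f"region {name!r}: fewer than 2 usable rows")
    return Alignment(keep)


def score_regions(msa: Alignment, region_map: RegionMap) -> list[RegionScore]:
    """Score every region; result is ranked by mean divergence ascending
    (most conserved first). Regions with < 2 usable rows are skipped with a
    warning."""
    scores: list[RegionScore] = []
    for region in region_map:
        try:
            sub = extract_region(msa, region_map, region.name)
        except DomevolError as exc:
            warnings.warn(f"skipping region {region.name!r}: {exc}")
            continue
        divs = []
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                p, compared = pairwise_p_distance(
                    sub.records[i].residues, sub.records[j].residues
                )
                if compared > 0:
                    divs.append(100.0 * p)
        if not divs:
            warnings.warn(f"skipping region {region.name!r}: no comparable pairs")
            continue
        scores.append(RegionScore(region.name, np.asarray(divs), len(sub)))
    scores.sort(key=lambda s: s.mean)
    return scores


def kruskal_wallis_regions(scores: list[RegionScore]) -> HeterogeneityResult:
    """Tie-corrected Kruskal-Wallis H across region divergence distributions,
    p from chi-square with k-1 degrees of freedom."""
    if len(scores) < 2:
        raise DomevolError("need at least 2 regions")
    groups = [s.divergences for s in scores]
    for s in scores:
        if len(s.divergences) < 2:
            raise DomevolError(f"region {s.name!r} has fewer than 2 values")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        warnings.warn("all divergence values identical across regions; p = 1")
        return HeterogeneityResult(0.0, 1.0, {s.name: len(s.divergences) for s in scores})
    h, p = stats.kruskal(*groups)
    return HeterogeneityResult(
        float(h), float(p), {s.name: len(s.divergences) for s in scores}
    )


def classify_column(column: str) -> str:
    """Conservation class of an alignment column (gaps ignored):
    'invariant' (one residue state), 'conservative' (all states within one
    Dayhoff group) or 'variable'."""
    states = {ch for ch in column if ch != GAP}
    if not states:
        return "not alignable"
    if len(states) == 1:
        return "invariant"
    if any(states <= grp for grp in DAYHOFF_GROUPS):
        return "conservative"
    return "variable"


def site_report(
    msa: Alignment, reference_id: str, positions: list[int]
) -> "pd.DataFrame":
    """Per-position table of the aligned residue of every record plus a
    conservation class, for functionally important sites (PTM sites etc.)."""
    import pandas as pd

    rows = []
    for pos in positions:
        col = ref_to_column(msa, reference_id, pos)
        column = msa.column(col)
        entry: dict[str, object] = {
            "position": pos,
            "column": col,
            "class": classify_column(column),
        }
        for rec, ch in zip(msa.records, column):
            entry[rec.id] = ch
        rows.append(entry)
    return pd.DataFrame(rows)
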