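"""Global pairwise alignment, percent identity and p-distance matrices.

Percent identity is reported on the 0-100 scale; distances default to
"changes per 100 sites" so that region scores, rate curves and distance
matrices share one unit system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix

from .io import GAP, Alignment, DomevolError, SequenceRecord

IDENTITY_MODES = ("both-residue-columns", "shorter-sequence", "alignment-length")


@dataclass(frozen=True)
class IdentityResult:
    id_a: str
    id_b: str
    percent_identity: float
    n_compared: int
    mode: str


def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[Alignment, float]:
    """Optimal global alignment of two records under an affine-gap scheme.

    Returns a 2-row Alignment and the alignment score. Defaults (BLOSUM62,
    open 10, extend 0.5) approximate the common protein-aligner settings.
    """
    aligner = _aligner(matrix, gap_open, gap_extend)
    best = aligner.align(a.ungapped, b.ungapped)[0]
    row_a, row_b = str(best[0]), str(best[1])
    aln = Alignment(
        [
            SequenceRecord(a.id, row_a, species=a.species, source=a.source),
            SequenceRecord(b.id, row_b, species=b.species, source=b.source),
        ]
    )
    return aln, float(best.score)


def alignment_score(a: SequenceRecord, b: SequenceRecord, **kwargs) -> float:
    """Score of the optimal global alignment (no traceback)."""
    aligner = _aligner(
        kwargs.get("matrix", "BLOSUM62"),
        kwargs.get("gap_open", 10.0),
        kwargs.get("gap_extend", 0.5),
    )
    return float(aligner.score(a.ungapped, b.ungapped))


def percent_identity(
    pair: Alignment, mode: str = "both-residue-columns"
) -> IdentityResult:
    """Percent identity of a 2-row alignment.

    mode 'both-residue-columns' (default): denominator = columns where neither
    row is a gap; 'shorter-sequence': ungapped length of the shorter row;
    'alignment-length': all columns.
    """
    if len(pair) != 2:
        raise DomevolError("percent_identity needs exactly 2 rows")
    if mode not in IDENTITY_MODES:
        raise DomevolError(f"unknown mode {mode!r}; expected one of {IDENTITY_MODES}")
    ra, rb = pair.records
    matches = 0
    both = 0
    for x, y in zip(ra.residues, rb.residues):
        if x != GAP and y != GAP:
            both += 1
            if x == y:
                matches += 1
    if mode == "both-residue-columns":
        denom = both
    elif mode == "shorter-sequence":
        denom = min(len(ra.ungapped), len(rb.ungapped))
    else:
        denom = pair.ncols
    if denom == 0:
        raise DomevolError(f"no comparable columns for {ra.id!r} vs {rb.id!r}")
    return IdentityResult(ra.id, rb.id, 100.0 * matches / denom, denom, mode)


def msa_percent_identity(
    msa: Alignment, id_a: str, id_b: str, mode: str = "both-residue-columns"
) -> IdentityResult:
    """Identity of two members computed within a jointly aligned family MSA."""
    return percent_identity(Alignment([msa[id_a], msa[id_b]]), mode=mode)


def pairwise_p_distance(
    a: str, b: str, *, pairwise_deletion: bool = True
) -> tuple[float, int]:
    """(fraction of differing sites, number of compared sites) for two rows.

    With pairwise deletion, columns where either row is a gap are skipped.
    """
    diff = 0
    compared = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            if pairwise_deletion:
                continue
            diff += x != y
            compared += 1
            continue
        compared += 1
        if x != y:
            diff += 1
    if compared == 0:
        return np.nan, 0
    return diff / compared, compared


def p_distance_matrix(
    msa: Alignment,
    *,
    pairwise_deletion: bool = True,
    scale: str = "per100",
    correction: str | None = None,
) -> DistanceMatrix:
    """All-pairs p-distance over an MSA.

    scale: 'fraction' or 'per100' (changes per 100 sites, the default).
    correction: None (raw) or 'poisson' (-ln(1 - p), multiple-hit corrected).
    """
    if scale not in {"fraction", "per100"}:
        raise DomevolError(f"unknown scale {scale!r}")
    if correction not in {None, "poisson"}:
        raise DomevolError(f"unknown correction {correction!r}")
    n = len(msa)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p, compared = pairwise_p_distance(
                msa.records[i].residues,
                msa.records[j].residues,
                pairwise_deletion=pairwise_deletion,
            )
            if compared == 0:
                raise DomevolError(
                    f"no comparable columns for pair "
                    f"({msa.records[i].id!r}, {msa.records[j].id!r})"
                )
            if correction == "poisson":
                if p >= 1.0:
                    raise DomevolError(
                        "Poisson correction undefined at p = 1 for pair "
                        f"({msa.records[i].id!r}, {msa.records[j].id!r})"
                    )
                p = -np.log(1.0 - p)
            vals[i, j] = vals[j, i] = p * (100.0 if scale == "per100" else 1.0)
    return DistanceMatrix(vals, ids=msa.ids)
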