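"""Column conservation and mutual-information coupling networks over an MSA.

The pipeline mirrors the published MISTIC-style convention: sequences are
weighted by single-linkage clustering at 62% identity, column pair frequencies
are pseudocounted (lambda = 0.05) over the 20-letter alphabet with gaps
excluded, MI is in nats, and significance comes from a within-column
permutation null summarized as a z-score. Edges with z above a cutoff
(default 6.5) are tiered into the top 5%, the 70th-95th percentile band, and
the rest; a position's cumulative MI (cMI) is its summed above-cutoff z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .io import AMINO_ACIDS, GAP, Alignment, DomevolError

#: Robinson & Robinson (1991) amino-acid background frequencies.
BACKGROUND = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def encode(msa: Alignment) -> np.ndarray:
    """(n_rows, n_cols) int8 matrix; 0..19 for canonical residues, -1 for
    gaps and X (excluded from all counts)."""
    out = np.full((len(msa), msa.ncols), -1, dtype=np.int8)
    for r, rec in enumerate(msa.records):
        for c, ch in enumerate(rec.residues):
            out[r, c] = _AA_INDEX.get(ch, -1)
    return out


def sequence_weights(msa: Alignment, identity_threshold: float = 0.62) -> np.ndarray:
    """Redundancy weights: single-linkage clusters at >= threshold pairwise
    identity (over columns where both rows have residues); each sequence gets
    1 / (its cluster size), so weights sum to the number of clusters."""
    enc = encode(msa)
    n = len(msa)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            both = (enc[i] >= 0) & (enc[j] >= 0)
            nb = int(both.sum())
            if nb == 0:
                continue
            ident = float((enc[i][both] == enc[j][both]).sum()) / nb
            if ident >= identity_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    roots = [find(i) for i in range(n)]
    sizes = {r: roots.count(r) for r in set(roots)}
    return np.array([1.0 / sizes[r] for r in roots])


def retained_columns(msa: Alignment, min_occupancy: float = 0.5) -> np.ndarray:
    """1-based alignment columns whose non-gap occupancy is >= threshold."""
    enc = encode(msa)
    occ = (enc >= 0).mean(axis=0)
    return np.flatnonzero(occ >= min_occupancy) + 1


def _joint_counts(enc: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted pair counts: result[c1*20+a, c2*20+b] = sum_r w_r over rows
    with residue a at c1 and b at c2 (rows gapped in either column drop out)."""
    n_rows, n_cols = enc.shape
    aw = np.zeros((n_cols * 20, n_rows))
    a1 = np.zeros((n_cols * 20, n_rows))
    rows = np.arange(n_rows)
    for c in range(n_cols):
        ok = enc[:, c] >= 0
        idx = c * 20 + enc[ok, c].astype(int)
        aw[idx, rows[ok]] = weights[ok]
        a1[idx, rows[ok]] = 1.0
    return aw @ a1.T


def _mi_from_joint(joint: np.ndarray, n_cols: int, pseudocount: float) -> np.ndarray:
    """Symmetric (n_cols, n_cols) MI matrix in nats from stacked joint counts."""
    mi = np.zeros((n_cols, n_cols))
    j4 = joint.reshape(n_cols, 20, n_cols, 20)
    chunk = max(1, int(2e7 // (n_cols * 400)))
    for lo in range(0, n_cols, chunk):
        hi = min(lo + chunk, n_cols)
        m = j4[lo:hi].transpose(0, 2, 1, 3) + pseudocount  # (b, n_cols, 20, 20)
        tot = m.sum(axis=(2, 3), keepdims=True)
        p = m / tot
        pi = p.sum(axis=3)
        pj = p.sum(axis=2)
        h_ij = -xlogy(p, p).sum(axis=(2, 3))
        h_i = -xlogy(pi, pi).sum(axis=2)
        h_j = -xlogy(pj, pj).sum(axis=2)
        mi[lo:hi] = h_i + h_j - h_ij
    np.fill_diagonal(mi, 0.0)
    return mi


def mi_matrix(
    msa: Alignment,
    weights: np.ndarray | None = None,
    pseudocount: float = 0.05,
    min_occupancy: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw MI (nats) over retained columns.

    Returns (mi, columns) where columns are the retained 1-based alignment
    columns and mi[i, j] couples columns[i] with columns[j].
    """
    cols = retained_columns(msa, min_occupancy)
    if len(cols) < 2:
        raise DomevolError("fewer than 2 columns pass the occupancy filter")
    if weights is None:
        weights = sequence_weights(msa)
    enc = encode(msa)[:, cols - 1]
    joint = _joint_counts(enc, weights)
    return _mi_from_joint(joint, len(cols), pseudocount), cols


def mi_zscores(
    msa: Alignment,
    n_permutations: int = 100,
    seed: int = 0,
    weights: np.ndarray | None = None,
    pseudocount: float = 0.05,
    min_occupancy: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Permutation z-scores for all retained column pairs.

    The null permutes residues independently within each column (preserving
    every column's composition while destroying covariation);
    z = (MI - mean_null) / sd_null, with z = 0 wherever sd_null = 0.
    Returns (z, mi, columns). Deterministic for a fixed seed.
    """
    if n_permutations < 20:
        raise DomevolError("need at least 20 permutations")
    cols = retained_columns(msa, min_occupancy)
    if len(cols) < 2:
        raise DomevolError("fewer than 2 columns pass the occupancy filter")
    if weights is None:
        weights = sequence_weights(msa)
    enc = encode(msa)[:, cols - 1]
    n_cols = len(cols)
    mi = _mi_from_joint(_joint_counts(enc, weights), n_cols, pseudocount)

    rng = np.random.default_rng(seed)
    mean = np.zeros_like(mi)
    m2 = np.zeros_like(mi)
    perm = np.empty_like(enc)
    for k in range(1, n_permutations + 1):
        for c in range(n_cols):
            order = rng.permutation(enc.shape[0])
            perm[:, c] = enc[order, c]
        null = _mi_from_joint(_joint_counts(perm, weights), n_cols, pseudocount)
        delta = null - mean
        mean += delta / k
        m2 += delta * (null - mean)
    sd = np.sqrt(m2 / (n_permutations - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (mi - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    np.fill_diagonal(z, 0.0)
    return z, mi, cols


def cumulative_mi(z: np.ndarray, threshold: float = 6.5) -> np.ndarray:
    """cMI_i = sum_j z_ij over pairs with z_ij > threshold."""
    above = np.where(z > threshold, z, 0.0)
    np.fill_diagonal(above, 0.0)
    return above.sum(axis=1)


def classify_edges(
    z: np.ndarray, threshold: float = 6.5, columns: np.ndarray | None = None
) -> pd.DataFrame:
    """Edges with z > threshold, ranked by z and tiered: top 5% -> 'top5',
    the 70th-95th percentile band -> 'mid', remainder -> 'rest'."""
    n = z.shape[0]
    if columns is None:
        columns = np.arange(1, n + 1)
    iu, ju = np.triu_indices(n, k=1)
    keep = z[iu, ju] > threshold
    edges = pd.DataFrame(
        {"i": columns[iu[keep]], "j": columns[ju[keep]], "z": z[iu, ju][keep]}
    ).sort_values("z", ascending=False, kind="stable").reset_index(drop=True)
    m = len(edges)
    if m == 0:
        edges["tier"] = pd.Series(dtype=str)
        return edges
    rank = np.arange(1, m + 1)
    n_top = max(1, int(np.floor(0.05 * m)))
    n_mid_end = int(np.floor(0.30 * m))
    tier = np.where(rank <= n_top, "top5", np.where(rank <= n_mid_end, "mid", "rest"))
    edges["tier"] = tier
    return edges


def column_conservation(
    msa: Alignment,
    background: dict[str, float] | None = None,
    weights: np.ndarray | None = None,
    pseudocount: float = 0.05,
    min_occupancy: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column Kullback-Leibler divergence (nats) of the weighted residue
    composition from a background distribution (Robinson-Robinson default).

    Returns (kl, columns) over retained columns.
    """
    if background is None:
        background = BACKGROUND
    q = np.array([background[aa] for aa in AMINO_ACIDS], dtype=float)
    if not np.isclose(q.sum(), 1.0, atol=1e-3):
        raise DomevolError("background frequencies must sum to 1")
    q = q / q.sum()
    cols = retained_columns(msa, min_occupancy)
    if weights is None:
        weights = sequence_weights(msa)
    enc = encode(msa)[:, cols - 1]
    kl = np.zeros(len(cols))
    for k in range(len(cols)):
        counts = np.zeros(20)
        col = enc[:, k]
        ok = col >= 0
        np.add.at(counts, col[ok].astype(int), weights[ok])
        counts += pseudocount
        f = counts / counts.sum()
        kl[k] = float(np.sum(xlogy(f, f / q)))
    return kl, cols


@dataclass
class CouplingResult:
    """Full coupling analysis: raw MI, permutation z, cMI, tiered edges and
    per-column conservation, all indexed by retained alignment columns."""

    columns: np.ndarray
    mi: np.ndarray
    z: np.ndarray
    cmi: np.ndarray
    conservation: np.ndarray
    edges: pd.DataFrame
    threshold: float

    def per_column_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": self.columns,
                "conservation": self.conservation,
                "cmi": self.cmi,
            }
        )


def couple(
    msa: Alignment,
    n_permutations: int = 100,
    seed: int = 0,
    threshold: float = 6.5,
    pseudocount: float = 0.05,
    min_occupancy: float = 0.5,
    identity_threshold: float = 0.62,
    threshold_on: str = "zscore",
) -> CouplingResult:
    """One-shot coupling analysis of an MSA.

    threshold_on: 'zscore' (default) applies the cutoff to permutation
    z-scores; 'raw' applies it to raw MI in nats.
    """
    if threshold_on not in {"zscore", "raw"}:
        raise DomevolError(f"unknown threshold_on {threshold_on!r}")
    weights = sequence_weights(msa, identity_threshold)
    z, mi, cols = mi_zscores(
        msa,
        n_permutations=n_permutations,
        seed=seed,
        weights=weights,
        pseudocount=pseudocount,
        min_occupancy=min_occupancy,
    )
    score = z if threshold_on == "zscore" else mi
    cmi = cumulative_mi(score, threshold)
    edges = classify_edges(score, threshold, cols)
    cons, _ = column_conservation(
        msa, weights=weights, pseudocount=pseudocount, min_occupancy=min_occupancy
    )
    return CouplingResult(cols, mi, z, cmi, cons, edges, threshold)
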