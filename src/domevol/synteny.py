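"""Gene-neighborhood (synteny) conservation around an anchor gene.

Each genome is an ordered table of signed gene symbols. Conservation of a
neighborhood is quantified as the longest common subsequence (LCS) of signed
symbols between a reference window and each genome's window around the same
anchor; the reverse-complemented window (order reversed, strands flipped) is
also tested and the better score taken, so a wholesale inversion of the locus
does not count as loss of synteny.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import DomevolError

#: a signed gene: (SYMBOL, strand) with strand in {+, -}
SignedGene = tuple[str, str]


@dataclass
class GeneOrderTable:
    """Ordered genes of one genome: DataFrame with columns
    symbol, chrom, start, strand; sorted by (chrom, start), symbols upper-cased."""

    genome: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"symbol", "chrom", "start", "strand"}
        if not required.issubset(self.table.columns):
            raise DomevolError(f"gene table needs columns {sorted(required)}")
        bad = set(self.table["strand"]) - {"+", "-"}
        if bad:
            raise DomevolError(f"invalid strand value(s) {sorted(bad)}")
        df = self.table.copy()
        df["symbol"] = df["symbol"].str.upper()
        df["chrom"] = df["chrom"].astype(str)
        self.table = df.sort_values(["chrom", "start"], kind="stable").reset_index(
            drop=True
        )


def load_gene_table(path, genome: str) -> GeneOrderTable:
    """Read a TSV/BED-like gene table (chrom, start[, end], strand, symbol)."""
    df = pd.read_csv(path, sep="\t")
    return GeneOrderTable(genome, df)


def neighborhood(
    table: GeneOrderTable, anchor: str, k: int = 5
) -> list[SignedGene] | None:
    """Window of up to 2k+1 signed symbols centered on the anchor, truncated
    at chromosome ends. None if the anchor is absent (reported, not fatal)."""
    anchor = anchor.upper()
    df = table.table
    hits = df.index[df["symbol"] == anchor]
    if len(hits) == 0:
        return None
    pos = int(hits[0])
    chrom = df.loc[pos, "chrom"]
    same = df[df["chrom"] == chrom].reset_index()
    local = same.index[same["index"] == pos][0]
    lo = max(0, local - k)
    hi = min(len(same), local + k + 1)
    return [
        (row.symbol, row.strand) for row in same.iloc[lo:hi].itertuples()
    ]


@dataclass
class AdjacencyResult:
    syntenic: bool
    adjacent: bool = False
    orientation: str | None = None  # head-to-tail | head-to-head | tail-to-tail
    intervening: int | None = None


def adjacency(table: GeneOrderTable, gene_a: str, gene_b: str) -> AdjacencyResult:
    """Are two genes adjacent on the same chromosome, and how do they face?

    Orientation for the upstream/downstream ordered pair (a before b):
    (+,+) or (-,-) -> head-to-tail (tandem); (-,+) -> head-to-head
    (divergent); (+,-) -> tail-to-tail (convergent).
    """
    df = table.table
    ia = df.index[df["symbol"] == gene_a.upper()]
    ib = df.index[df["symbol"] == gene_b.upper()]
    if len(ia) == 0 or len(ib) == 0:
        raise DomevolError(f"gene(s) missing from {table.genome}")
    ia, ib = int(ia[0]), int(ib[0])
    if df.loc[ia, "chrom"] != df.loc[ib, "chrom"]:
        return AdjacencyResult(syntenic=False)
    first, second = (ia, ib) if df.loc[ia, "start"] <= df.loc[ib, "start"] else (ib, ia)
    chrom = df.loc[first, "chrom"]
    between = df[
        (df["chrom"] == chrom)
        & (df["start"] > df.loc[first, "start"])
        & (df["start"] < df.loc[second, "start"])
    ]
    n_between = len(between)
    s1, s2 = df.loc[first, "strand"], df.loc[second, "strand"]
    if s1 == s2:
        orient = "head-to-tail"
    elif (s1, s2) == ("-", "+"):
        orient = "head-to-head"
    else:
        orient = "tail-to-tail"
    return AdjacencyResult(
        syntenic=True,
        adjacent=n_between == 0,
        orientation=orient,
        intervening=n_between,
    )


def _lcs(a: list[SignedGene], b: list[SignedGene]) -> int:
    """Length of the longest common subsequence of signed genes."""
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[m]


def reverse_complement_window(window: list[SignedGene]) -> list[SignedGene]:
    flip = {"+": "-", "-": "+"}
    return [(sym, flip[s]) for sym, s in reversed(window)]


def block_score(
    reference_window: list[SignedGene], other: list[SignedGene]
) -> int:
    """Signed LCS between two windows; the reverse-complement of `other` is
    also tested and the better score returned (orientation-sensitive but
    inversion-tolerant)."""
    if not reference_window or not other:
        return 0
    return max(
        _lcs(reference_window, other),
        _lcs(reference_window, reverse_complement_window(other)),
    )


def conserved_block(
    reference_window: list[SignedGene],
    other_windows: dict[str, list[SignedGene] | None],
) -> pd.DataFrame:
    """Per-genome block score and shared gene set against a reference window.

    Genomes whose window is None (anchor absent) score 0 with anchor_found
    False — an 'unknown' state, not evidence of loss.
    """
    ref_syms = {sym for sym, _ in reference_window}
    rows = []
    for genome, window in other_windows.items():
        if window is None:
            rows.append(
                {
                    "genome": genome,
                    "anchor_found": False,
                    "block_score": 0,
                    "shared_genes": "",
                }
            )
            continue
        score = block_score(reference_window, window)
        shared = sorted(ref_syms & {sym for sym, _ in window})
        rows.append(
            {
                "genome": genome,
                "anchor_found": True,
                "block_score": score,
                "shared_genes": ",".join(shared),
            }
        )
    return pd.DataFrame(rows)


def synteny_report(
    tables: dict[str, GeneOrderTable],
    reference_genome: str,
    anchor: str,
    partner: str | None = None,
    k: int = 5,
) -> pd.DataFrame:
    """End-to-end neighborhood comparison across genomes.

    Emits per genome: anchor presence, block score against the reference
    genome's window, shared genes, and (when `partner` is given) whether
    anchor and partner are adjacent and in which orientation. Genomes where
    the partner is absent get partner_state 'unknown'.
    """
    if reference_genome not in tables:
        raise DomevolError(f"reference genome {reference_genome!r} missing")
    ref_window = neighborhood(tables[reference_genome], anchor, k)
    if ref_window is None:
        raise DomevolError(f"anchor {anchor!r} absent from reference genome")
    windows = {g: neighborhood(t, anchor, k) for g, t in tables.items()}
    report = conserved_block(ref_window, windows)
    if partner is not None:
        states, orients = [], []
        for genome in report["genome"]:
            try:
                adj = adjacency(tables[genome], anchor, partner)
            except DomevolError:
                states.append("unknown")
                orients.append(None)
                continue
            if not adj.syntenic:
                states.append("not syntenic")
            elif adj.adjacent:
                states.append("adjacent")
            else:
                states.append(f"separated by {adj.intervening}")
            orients.append(adj.orientation)
        report["partner_state"] = states
        report["partner_orientation"] = orients
    return report
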