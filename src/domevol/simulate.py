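"""Synthetic-data generators with known ground truth for every pipeline stage.

The sequence simulator evolves proteins along a tree under a 20-state
Jukes-Cantor-like model: at each site, substitution events arrive as a
Poisson process with rate = base_rate x (the site's region multiplier) per
unit branch length, and the replacement residue is drawn uniformly from the
other 19 (optionally biased toward physicochemically close residues). No
indels are simulated, so the alignment is trivially columnar and region
coordinates on the root are alignment coordinates. Planted covarying column
pairs evolve as locked states: the partner column is a fixed residue
permutation of its driver, so every substitution in the driver is mirrored
by a compensating change.

All generators take a mandatory seed and are deterministic given it (one
numpy Generator per call; no global state).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grantham import DEFAULT_TABLE
from .io import AMINO_ACIDS, Alignment, DomevolError, Region, RegionMap, SequenceRecord
from .phylo import parse_newick
from .synteny import GeneOrderTable, SignedGene
from .variants import TIERS, VariantRecord

# ---------------------------------------------------------------------------
# trees


def clock_tree(n_leaves: int, depth: float, seed: int) -> "TreeNode":
    """Ultrametric pure-birth (Yule-like) tree with `n_leaves` tips labelled
    t1..tn and root-to-tip distance exactly `depth`. Split times are spread
    evenly over (0, 0.85*depth) with +/-20% jitter, keeping every internal
    branch long enough to be statistically resolvable; the topology (which
    lineage splits) is random."""
    from skbio import TreeNode

    if n_leaves < 2:
        raise DomevolError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    if n_leaves > 2:
        spacing = 0.85 * depth / (n_leaves - 1)
        base = spacing * np.arange(1, n_leaves - 1)
        extra = np.sort(base + rng.uniform(-0.2, 0.2, size=n_leaves - 2) * spacing)
    else:
        extra = np.array([])
    root = TreeNode()
    # active lineages as (node, birth_time); root "splits" at time 0
    active: list[tuple[TreeNode, float]] = [(root, 0.0)]
    for st in np.concatenate([[0.0], extra]):
        k = int(rng.integers(len(active)))
        node, birth = active.pop(k)
        node.length = None if node is root else st - birth
        for _ in range(2):
            child = TreeNode()
            node.append(child)
            active.append((child, st))
    for i, (node, birth) in enumerate(active):
        node.name = f"t{i + 1}"
        node.length = depth - birth
    return root


def two_leaf_tree(t: float) -> "TreeNode":
    """Two tips separated by total branch length t."""
    return parse_newick(f"(a:{t / 2},b:{t / 2});")


# ---------------------------------------------------------------------------
# MSA simulation


def uniform_region_map(
    n_sites: int, n_regions: int, reference_id: str = "root"
) -> RegionMap:
    """Partition 1..n_sites into n_regions contiguous, equal-as-possible
    named regions R01..Rk."""
    bounds = np.linspace(0, n_sites, n_regions + 1).astype(int)
    regions = [
        Region(f"R{i + 1:02d}", int(bounds[i]) + 1, int(bounds[i + 1]))
        for i in range(n_regions)
    ]
    return RegionMap(reference_id, regions)


@dataclass
class MsaSim:
    alignment: Alignment
    site_rates: np.ndarray  # per-site rate multiplier (ground truth)
    region_map: RegionMap | None
    multipliers: dict[str, float] | None
    covarying_pairs: list[tuple[int, int]] = field(default_factory=list)
    pair_maps: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)


def _replacement_matrix(mode: str) -> np.ndarray:
    """Row-stochastic replacement distribution given a substitution event."""
    if mode == "uniform":
        m = np.full((20, 20), 1.0 / 19.0)
    elif mode == "grantham":
        d = np.array(
            [
                [DEFAULT_TABLE.distance(a, b) for b in AMINO_ACIDS]
                for a in AMINO_ACIDS
            ]
        )
        m = np.exp(-d / 100.0)
    else:
        raise DomevolError(f"unknown replacement mode {mode!r}")
    np.fill_diagonal(m, 0.0)
    return m / m.sum(axis=1, keepdims=True)


def simulate_msa(
    tree,
    n_sites: int,
    rate: float,
    seed: int,
    region_map: RegionMap | None = None,
    multipliers: dict[str, float] | None = None,
    covarying_pairs: list[tuple[int, int]] | None = None,
    replacement: str = "uniform",
) -> MsaSim:
    """Evolve a protein alignment along `tree` (newick string or TreeNode).

    `region_map`/`multipliers` impose per-region rate multipliers (sites not
    covered by any region evolve at multiplier 1; overlapping regions are an
    error here, unlike in scoring). `covarying_pairs` are 1-based site pairs
    locked through a random residue bijection.
    """
    if isinstance(tree, str):
        tree = parse_newick(tree)
    rng = np.random.default_rng(seed)
    site_mult = np.ones(n_sites)
    if region_map is not None:
        if multipliers is None:
            raise DomevolError("region_map given without multipliers")
        covered = np.zeros(n_sites, dtype=bool)
        for region in region_map:
            if region.end > n_sites:
                raise DomevolError(f"region {region.name!r} beyond n_sites")
            sl = slice(region.start - 1, region.end)
            if covered[sl].any():
                raise DomevolError("overlapping regions in simulation rate map")
            covered[sl] = True
            site_mult[sl] = multipliers[region.name]
    pairs = [tuple(p) for p in (covarying_pairs or [])]
    drivers = {}
    pair_maps: dict[tuple[int, int], np.ndarray] = {}
    for i, j in pairs:
        if not (1 <= i <= n_sites and 1 <= j <= n_sites) or i == j:
            raise DomevolError(f"bad covarying pair ({i}, {j})")
        perm = rng.permutation(20)
        pair_maps[(i, j)] = perm
        drivers[j] = (i, perm)

    repl = _replacement_matrix(replacement)
    root_seq = rng.integers(0, 20, size=n_sites)
    for j, (i, perm) in drivers.items():
        root_seq[j - 1] = perm[root_seq[i - 1]]

    seqs: dict[int, np.ndarray] = {id(tree): root_seq}
    for node in tree.preorder(include_self=False):
        parent_seq = seqs[id(node.parent)]
        child = parent_seq.copy()
        t = node.length or 0.0
        if t > 0 and rate > 0:
            n_subs = rng.poisson(rate * site_mult * t)
            for site in np.flatnonzero(n_subs):
                state = child[site]
                for _ in range(n_subs[site]):
                    state = rng.choice(20, p=repl[state])
                child[site] = state
        for j, (i, perm) in drivers.items():
            child[j - 1] = perm[child[i - 1]]
        seqs[id(node)] = child

    records = []
    for tip in tree.tips():
        seq = seqs[id(tip)]
        records.append(
            SequenceRecord(tip.name, "".join(AMINO_ACIDS[k] for k in seq))
        )
    records.sort(key=lambda r: r.id)
    return MsaSim(
        Alignment(records), site_mult, region_map, multipliers, pairs, pair_maps
    )


def expected_p_distance(rate: float, t: float) -> float:
    """Closed-form expected p-distance between two sequences separated by
    total branch length t under the 20-state uniform-replacement model:
    (19/20) * (1 - exp(-(20/19) * rate * t))."""
    return (19.0 / 20.0) * (1.0 - np.exp(-(20.0 / 19.0) * rate * t))


# ---------------------------------------------------------------------------
# variant tables


def _deterministic_counts(n: int, fractions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n among len(fractions) bins."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.min() < 0 or not np.isclose(fractions.sum(), 1.0, atol=1e-6):
        raise DomevolError("fractions must be nonnegative and sum to 1")
    raw = n * fractions
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts), kind="stable")
    for k in range(n - counts.sum()):
        counts[order[k % len(counts)]] += 1
    return counts


#: default per-residue enrichment: cytoplasmic N-terminal domain twice as
#: variant-dense as the membrane and C-terminal parts (human-polymorphism-like)
DEFAULT_ENRICHMENT = (((1, 692), 2.0), ((693, 977), 1.0), ((978, 1104), 1.0))


def simulate_missense_table(
    n: int,
    tier_mix: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1),
    seed: int = 0,
    enrichment=DEFAULT_ENRICHMENT,
    sift_cutoff: float = 0.05,
    polyphen_cutoff: float = 0.5,
    gd_cutoff: float = 65.0,
) -> tuple[list[VariantRecord], list[str]]:
    """Missense variant table with planted damaging-vote tiers.

    tier_mix gives the fraction of records with 0/1/2/3 damaging predictors;
    counts are apportioned deterministically so recovered tier counts are
    exact. Scores are sampled strictly on the damaging or benign side of the
    cutoffs (with a safety margin). Positions follow the per-residue
    `enrichment` spec ((start, end), weight). Returns (records, true_tiers).
    """
    rng = np.random.default_rng(seed)
    counts = _deterministic_counts(n, np.asarray(tier_mix))
    tier_of = np.repeat(np.arange(4), counts)
    rng.shuffle(tier_of)

    spans = [(s, e, w) for (s, e), w in enrichment]
    weights = np.array([(e - s + 1) * w for s, e, w in spans], dtype=float)
    weights /= weights.sum()
    aa = list(AMINO_ACIDS)
    records: list[VariantRecord] = []
    truths: list[str] = []
    margin = 0.1
    for k in range(n):
        span = spans[rng.choice(len(spans), p=weights)]
        pos = int(rng.integers(span[0], span[1] + 1))
        ref = aa[rng.integers(20)]
        alt = aa[rng.integers(20)]
        while alt == ref:
            alt = aa[rng.integers(20)]
        which = rng.permutation(3)[: tier_of[k]]  # which predictors vote damaging
        sift = (
            rng.uniform(0, sift_cutoff * (1 - margin))
            if 0 in which
            else rng.uniform(sift_cutoff * (1 + margin), 1)
        )
        polyphen = (
            rng.uniform(min(polyphen_cutoff * (1 + margin), 1.0), 1)
            if 1 in which
            else rng.uniform(0, polyphen_cutoff * (1 - margin))
        )
        gd = (
            rng.uniform(gd_cutoff * (1 + margin), 215)
            if 2 in which
            else rng.uniform(0, gd_cutoff * (1 - margin))
        )
        records.append(
            VariantRecord(
                protein_position=pos,
                ref_aa=ref,
                alt_aa=alt,
                variant_class="SNP",
                consequence="missense_variant",
                sift=round(float(sift), 4),
                polyphen=round(float(polyphen), 4),
                gd=round(float(gd), 2),
            )
        )
        truths.append(TIERS[tier_of[k]])
    return records, truths


#: stated-world composition of a full gene-variant catalogue: dominant SNP
#: class and intron-heavy consequence spectrum typical of a 1000-genomes-scale
#: survey of a large intron-rich channel gene
DEFAULT_CLASS_MIX = {"SNP": 0.858, "insertion": 0.06, "deletion": 0.036, "SNV": 0.0335, "substitution": 0.0125}
DEFAULT_CONSEQUENCE_MIX = {
    "intron_variant": 0.607,
    "NMD_transcript_variant": 0.214,
    "downstream_gene_variant": 0.145,
    "missense_variant": 0.034,
}


def simulate_variant_catalog(
    n: int,
    class_mix: dict[str, float] | None = None,
    consequence_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[VariantRecord], pd.Series, pd.Series]:
    """Variant catalogue with exact (largest-remainder) class and consequence
    counts, for tally testing. Returns (records, true_class_counts,
    true_consequence_counts)."""
    rng = np.random.default_rng(seed)
    class_mix = class_mix or DEFAULT_CLASS_MIX
    consequence_mix = consequence_mix or DEFAULT_CONSEQUENCE_MIX
    cls_names = list(class_mix)
    con_names = list(consequence_mix)
    cls_counts = _deterministic_counts(n, np.array([class_mix[c] for c in cls_names]) / sum(class_mix.values()))
    con_counts = _deterministic_counts(n, np.array([consequence_mix[c] for c in con_names]) / sum(consequence_mix.values()))
    classes = np.repeat(cls_names, cls_counts)
    cons = np.repeat(con_names, con_counts)
    rng.shuffle(classes)
    rng.shuffle(cons)
    aa = list(AMINO_ACIDS)
    records = []
    for k in range(n):
        ref = aa[rng.integers(20)]
        alt = aa[rng.integers(20)]
        while alt == ref:
            alt = aa[rng.integers(20)]
        records.append(
            VariantRecord(
                protein_position=int(rng.integers(1, 1105)),
                ref_aa=ref,
                alt_aa=alt,
                variant_class=str(classes[k]),
                consequence=str(cons[k]),
            )
        )
    return (
        records,
        pd.Series(cls_counts, index=cls_names),
        pd.Series(con_counts, index=con_names),
    )


# ---------------------------------------------------------------------------
# gene orders

#: the vertebrate TRPM8 locus: a tetrad and a dyad of flanking genes around
#: the head-to-tail TRPM8-SPP2 pair
DEFAULT_LOCUS: list[SignedGene] = [
    ("ATG16L1", "+"),
    ("USP40", "+"),
    ("HEATR7B1", "+"),
    ("HJURP", "-"),
    ("TRPM8", "+"),
    ("SPP2", "+"),
    ("ARL4C", "-"),
    ("AGAP1", "+"),
]


def simulate_gene_orders(
    n_genomes: int,
    shuffle_rate: float,
    seed: int,
    window: list[SignedGene] | None = None,
    invert_only: bool = False,
) -> tuple[list[SignedGene], dict[str, GeneOrderTable]]:
    """Copy a reference window into each genome, then corrupt it locally.

    Corruption: Binomial(len(window), shuffle_rate) operations per genome,
    each either an adjacent transposition or a segment inversion (order
    reversed, strands flipped). `invert_only=True` restricts to inversions,
    which an orientation-aware, inversion-tolerant block score should ignore
    when they span the whole window. Returns (reference_window, tables).
    """
    if not 0 <= shuffle_rate <= 1:
        raise DomevolError("shuffle_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    window = list(window or DEFAULT_LOCUS)
    flip = {"+": "-", "-": "+"}
    tables: dict[str, GeneOrderTable] = {}
    for g in range(n_genomes):
        genes = list(window)
        n_ops = rng.binomial(len(genes), shuffle_rate)
        for _ in range(n_ops):
            if invert_only or rng.random() < 0.5:
                lo = int(rng.integers(0, len(genes)))
                hi = int(rng.integers(lo + 1, len(genes) + 1))
                seg = [(sym, flip[s]) for sym, s in reversed(genes[lo:hi])]
                genes[lo:hi] = seg
            else:
                k = int(rng.integers(0, len(genes) - 1))
                genes[k], genes[k + 1] = genes[k + 1], genes[k]
        tables[f"genome{g + 1}"] = GeneOrderTable(
            f"genome{g + 1}",
            pd.DataFrame(
                {
                    "symbol": [sym for sym, _ in genes],
                    "chrom": "chr1",
                    "start": np.arange(len(genes)) * 1000 + 1,
                    "strand": [s for _, s in genes],
                }
            ),
        )
    return window, tables
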