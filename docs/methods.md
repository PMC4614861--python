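# Methods

This note documents the models, conventions and design choices behind
domevol, in the package's own terms. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Sequences, alignments and coordinates

Residues are the 20 canonical letters plus `X`; `B/Z/U/J/O` fold into `X`
with a warning, `.` normalizes to `-`, and `-` is the only gap character.
All user-facing coordinates are 1-based inclusive, the convention of
published domain tables (the shipped TRPM8 map says "Pore region 886-954"
and means exactly that on the human reference). `ref_to_column` /
`column_to_ref` convert between ungapped reference positions and alignment
columns; they are mutually inverse on non-gap columns, which the suite
asserts on 1,000 random gapped fixtures.

The shipped TRPM8 domain map has 28 named regions. Regions may overlap and
nest (the TRP-box inside the TRP-domain inside the C-terminus); scoring
treats every region independently, so overlaps are reported, never merged.
Two pairs of rows in the source table share a name and are disambiguated by
their coordinates ("TRP-domain (990-1025)" vs "(993-1016)", and the two
C-terminal coiled-coil spans).

## Pairwise identity and distance

Percent identity defaults to the `both-residue-columns` denominator
(columns where neither row is gapped) because family identities are
computed inside a joint MSA that includes fragmented members; the
`shorter-sequence` and `alignment-length` denominators are available. For
Table-style family comparisons, identities are taken pairwise within the
family MSA rather than from independent pairwise alignments; published
values are matched to ±1.5 percentage points to absorb aligner and
denominator ambiguity.

p-distances use pairwise deletion (not complete deletion) because real
manifests include fragmented sequences; the default scale is changes per
100 sites so region scores, rate curves and NJ branch lengths share one
unit. Poisson correction −ln(1−p) is optional and always ≥ the raw
distance.

Global pairwise alignment is affine-gap dynamic programming (BLOSUM62,
open 10, extend 0.5 by default) via Biopython's `PairwiseAligner`; the
suite checks its scores against exhaustive enumeration of all alignments
for sequences ≤ 6 residues.

## Region conservation and heterogeneity

A region's score is the full set of pairwise divergences (changes per 100
sites) over its alignment columns; the mean is the headline number (lower =
more conserved) and the median is emitted alongside, since which summary a
bar plot uses is often unstated in published figures. Heterogeneity across
regions is a tie-corrected Kruskal–Wallis H on the pooled divergence
distributions with p from χ²(k−1). Per-site reports classify columns as
invariant / conservative / variable, with "conservative" meaning all
observed states fall in one Dayhoff group (configurable; the underlying
study named no grouping).

## Rate-vs-time (Dickerson) analysis

Each configured lineage comparison contributes the mean p-distance ×100
over all cross pairs A×B at one divergence time; the fit is least squares
through the origin (slope = Σty/Σt²), because zero time must mean zero
divergence. UEP = 1/slope. Divergence times are user configuration: the
shipped default file anchors the comparisons this family is known for
(amphibian/fish ≈ 390 MYA, birds/reptiles ≈ 150 MYA, ray-finned loss
≈ 450 MYA) and fills the undated ones with standard timetree values
(non-human primates 30 MYA, mammalian radiation 100 MYA, amphibian/amniote
360 MYA). Raw p-distance is the default to match the "changes per 100
amino acids" convention; the Poisson option removes multiple-hit
saturation, which matters above ~100 MY at typical channel-protein rates
(~3.5% downward slope bias at rT = 0.1).

## Coupling network

Conventions mirror the MISTIC server's published method: single-linkage
sequence clustering at 62% identity with weight 1/cluster-size; columns
retained at ≥ 50% non-gap occupancy; joint 20×20 frequencies with
pseudocount λ = 0.05 and gaps excluded; MI in nats. Raw plug-in MI carries
a finite-sample bias of roughly (19·19)/(2n) nats, so raw values are never
thresholded by default; instead a within-column permutation null (which
preserves each column's composition and hence the bias) yields
z = (MI − μ_null)/σ_null, deterministic under a fixed seed, with z = 0
flagged where σ_null = 0. The published cutoff "MI greater than 6.5" is
interpreted as this z-score (the server reports z-like scores); a raw-MI
threshold mode exists behind `threshold_on="raw"`. Edges above the cutoff
are ranked and tiered top-5% / 70th–95th percentile / rest; cMI is a
column's summed above-cutoff z. Column conservation is the KL divergence
of the weighted column composition from a background (Robinson–Robinson
frequencies by default, where tryptophan's rarity q ≈ 0.013 makes
invariant-W columns score highest).

## Grantham distance, GV and GD

The distance is the classical quadratic form over side-chain composition,
polarity and volume with α = 1.833, β = 0.1018, γ = 0.000399. The scale ρ
is derived at construction from the defining constraint that the 190
unordered pair distances average 100, rather than hard-coded; the resulting
matrix reproduces the published values (Leu–Ile 5 through Cys–Trp 215).
GV applies the same form to the per-property ranges observed at an
alignment column; GD measures the substituting residue's deviation from
those ranges (zero inside), so an invariant column degenerates to the plain
pair distance and a substitution inside the observed envelope scores 0.

## Variant triage

Damaging votes: SIFT ≤ 0.05 and PolyPhen ≥ 0.5 (the tools' conventional
cutoffs) and GD ≥ 65 — the classical "radical substitution" boundary,
chosen because the source analysis never states its GD cutoff; all three
are configurable and absent scores count as non-votes. The vote count maps
to tiers none/one/two/three (the green/blue/red triage classes), and the
mapping is monotone: making any score more damaging never lowers the tier.
GD is computed alignment-aware against the family MSA column; positions
that cannot be mapped fall back to sequence-only scoring (GV = 0, GD =
plain Grantham distance). Consequence types are free strings following the
Ensembl vocabulary, not an enum. Published 1000-genomes tallies are not
reproducible from a desk (consortium data plus annotation-version drift),
so the triage stack is validated by exact recovery of planted tier
compositions instead.

## Synteny

Gene neighborhoods are windows of up to 2k+1 signed symbols (default k = 5)
centered on an anchor, truncated at chromosome ends. Conservation is the
longest common subsequence of signed symbols against the reference window,
with the reverse-complemented window (order reversed, strands flipped) also
tested and the better score taken — a wholesale inversion of the locus is
not loss of synteny. Adjacency orientation follows strand pairs in
positional order: equal strands are head-to-tail, (−,+) head-to-head,
(+,−) tail-to-tail. Symbol matching is exact after case normalization;
ortholog mapping must be resolved upstream. A genome where the partner gene
is simply absent reports "unknown", not absence of synteny.

## Tree surrogate

Bayesian inference is out of scope; neighbor joining on the p-distance
matrix (negative branches clamped to 0) serves for topology checks and
newick export, and externally produced trees can be read in. Robinson–
Foulds is the count of non-trivial bipartitions present in exactly one
tree; the suite cross-checks it against an independent implementation.

## The simulator: what it emulates, and what it does not

`simulate_msa` evolves sequences along a tree under a 20-state
Jukes–Cantor-like model: per site, substitutions arrive as a Poisson
process with rate = base_rate × region multiplier per unit branch length;
replacements are uniform over the other 19 residues (a Grantham-biased
mode exists). The expected p-distance between leaves at separation T has
the closed form (19/20)(1 − e^(−(20/19)rT)), which the suite checks
against simulation. Covarying pairs are locked through a fixed residue
bijection — the strongest possible coevolution signal. `clock_tree` builds
ultrametric trees with split times spread evenly (±20% jitter) over
(0, 0.85·depth), so internal branches stay statistically resolvable;
that choice is what makes "NJ recovers the topology from a few hundred
sites" a fair benchmark. No indels are simulated (published analyses here
operate on a fixed MSA; indels would confound alignment inference), no
among-site rate variation beyond the region multipliers, no codon
structure, and locked pairs have no noise — so a green simulation test
establishes that the estimators recover the stated signal, not that real
alignments are this clean.

Variant and gene-order generators apportion planted compositions by
largest remainder, so recovered counts are exact, not merely close;
predictor scores are sampled with a 10% safety margin away from the vote
cutoffs. The default missense positional enrichment is 2:1 for the
N-terminal domain over the rest, mirroring the human-polymorphism pattern
reported for this channel family. All generators take a mandatory seed and
are byte-reproducible given it.

## Numerical and procedural notes

- MI matrices are computed by blocked matrix products over one-hot
  encodings; permutation nulls accumulate mean and variance by Welford's
  method (about 0.7 s per permutation at 200 columns × 50 rows).
- Through-origin slope recovery at 6 time points / 1,000 sites has ~3–5%
  sampling error; the 10% recovery tolerance is about two standard errors,
  with Poisson correction removing the systematic part.
- Tie-breaking: epitope scans return the smallest start among equal-match
  windows; edge tiering ranks by z descending with stable sort.
- Degenerate inputs fail loudly and specifically: ragged alignments list
  offending ids, pairs with no comparable columns are named, σ_null = 0 is
  flagged rather than divided by.

## Known limitations

Real published identity values depend on the original aligner's gap
placement; the ±1.5-point tolerance covers this but exact reproduction of
an external server's output is not guaranteed. The coupling stack does not
correct for phylogenetic relatedness beyond sequence weighting, so deep
tree structure can inflate z-scores on real families. The synteny module
formalizes what was originally a browser inspection; it does not chain
blocks genome-wide or infer orthology.
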