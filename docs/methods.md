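# Methods

This note documents the models, parameter choices and numerical conventions
behind `mybtrace`, and what its synthetic benchmarks do and do not
demonstrate about real data.

## The synthetic-data model

Each of `n_ancestral_subfamilies` subfamilies is founded by a single gene
lineage at its origin node of the species tree (the root by default; with
probability `origin_spread` a uniformly chosen internal node, emulating
lineage-specific subfamily emergence). From its origin the subfamily evolves
under a linear birth–death process — per-lineage duplication rate λ
(`dup_rate`, default 0.3) and loss rate μ (`loss_rate`, default 0.1), both
per unit branch length — simulated exactly by Gillespie sampling along every
branch, so the complete event list is available as truth. Lineages alive at
the tips are emitted as genes. With λ = μ = 0 every tip carries exactly one
gene per subfamily; the expected population after time *t* is
e<sup>(λ−μ)t</sup>, which the test suite checks against 10,000 Monte-Carlo
replicates.

**Sequences.** A gene's protein is N-flank + R2 repeat + R3 repeat +
C-flank; the two 53-column repeats are adjacent, as in real R2R3-MYBs.
Substitutions accumulate along the gene tree at `repeat_divergence`
(default 0.2) per column per unit branch length; a substituted column is
replaced by one of the other 19 residues uniformly. There is no indel
evolution inside repeats, so alignment columns remain identifiable by
construction (the anchor-pinned aligner still handles indels for imported
data). Three structural features shape the sequence landscape:

* **Anchors.** The three tryptophans per repeat (columns 6, 26, 45) are
  exempt from ordinary substitution; at emission each is retained with
  probability `w_anchor_conservation` (default 1.0) or replaced by F, the
  substitution the family actually tolerates.
* **Slow columns.** A fixed 40% of non-anchor columns (the same set in both
  repeats) evolve at 5% of the family rate, standing in for helix-packing
  residues. They keep within-family identity high at any depth.
* **Subfamily stems.** Every subfamily founder is separated from the shipped
  consensus by a private stem of `subfamily_stem_length` (default 12) time
  units. Fast columns therefore saturate *between* subfamilies while staying
  informative *within* them — the regime of real 2R-MYB data, where
  subfamilies are ancient, internally conserved, and sit on an essentially
  unresolved deep backbone. Without this separation, "subfamily" would not
  be an identifiable concept in the simulation at all.

Out-group genes (one per species by default) evolve the same way from the
CDC5 consensus pair with no birth–death events. Decoys — proteins with no
repeat, one repeat, or two repeats whose anchors are destroyed — are added
at `decoy_fraction` of the family size (count rounded half-to-even) and
recorded in truth. CDS sequences are fixed-table back-translations; no
nucleotide-level model is attempted.

**Introns.** Each subfamily is assigned a pattern from `intron_catalog`
(cyclically by index). The default catalog plants 12 patterns over 17 unique
(domain column, phase) sites, including an intronless pattern and two
patterns that are single-loss derivatives of the largest one. An intron at
(column *c*, phase *p*) is placed after coding base 3(pos−1)+p of the CDS,
where pos is the protein position of column *c*. Random flank introns
(probability `flank_intron_prob` = 0.2 per gene, outside the domain) are
planted as noise and recorded. Gene models are written as GFF3
gene/mRNA/CDS features with populated phase columns, on either strand,
1-based inclusive coordinates.

**Genome layout.** Realized duplication events are typed
tandem/segmental/dispersed with probabilities
(`tandem_fraction`, `segmental_fraction`, remainder). Per species, tandem
events chain their surviving representatives into arrays whose members are
separated by 0 or 1 filler genes; *all other* adjacent placements are padded
with ≥ 2 fillers, so the planted arrays are exactly the maximal clusters
under the ≤ 1-intervening-gene rule. Segmental pairs are written as anchor
rows of synteny blocks (with flanking filler anchors); synteny is
intra-species. Ordinal positions are 1-based and contiguous per chromosome.

**True per-node counts.** `node_counts[v]` is the number of subfamilies
alive on the branch entering node *v* that leave at least one emitted gene
in *v*'s clade — a *survival-conditioned, subfamily-lineage* count. This
granularity is deliberate: it is the quantity that presence-based min/max
estimators can bound. Gene-copy counts would not be bracketed (a pre-node
duplication yields two copies where the maximum rule counts one subfamily),
nor would lineages that go extinct without sampled descendants (invisible
to any estimator). With single origins per subfamily, min ≤ true ≤ max is a
theorem, and the suite verifies it over 200 simulations.

## Repeat scanning

The scanner slides a 53-column window and scores each position with a
positional profile whose per-column residue sets come from the four shipped
consensi (MYB R2/R3, CDC5 repeat 1/2) and whose weights reflect column
conservation: anchors 3.0 (W only), slow columns 2.0, fast columns 0.5 —
the same position-specific weighting any profile scanner uses. A window is
a candidate when its score reaches `threshold` (default 60% of the profile
self-score) **and** ≥ 2 of its 3 anchor residues are W. Non-overlapping
repeats are chosen greedily best-score-first (ties to the leftmost start);
on short sequences this provably matches exhaustive optimal placement, which
the suite checks by dynamic programming. Repeats with gaps ≤ `max_gap`
(default 20 aa — plant R2–R3 linkers are short) chain into the architecture
class; a 2-repeat protein whose identity to the CDC5 pair exceeds its
identity to the MYB pair is ATYPICAL_CDC5. Rejections carry machine-readable
reasons (`no_repeat`, `too_few_anchors`, `non-adjacent`,
`wrong_repeat_count`, `low_similarity`).

At the default simulation settings (stem 12, divergence 0.2) the scanner
recovers roughly 85–100% of planted family genes depending on depth — the
residual rejects mimic the partial/diverged sequences a real survey also
discards — and ≥ 95% precision and recall at divergence ≤ 0.1, which the
acceptance benchmark (500 planted proteins, 100 decoys) asserts.

## Alignment and distances

Domains are aligned by pinning the three located anchors of each repeat to
fixed columns and aligning the four inter-anchor segments to the consensus
segments by global pairwise alignment (match +1, mismatch 0, linear gap −1;
ties resolve to the first, leftmost-gap alignment). Anchor location prefers
W residues near the expected spacing, with a penalty of 3 offset units for
a non-W position, so single insertions shift anchors correctly while
substituted anchors stay put. Segments whose length equals the reference
are mapped diagonally — between pinned anchors an equal length means no
indel, and this preserves exact column identity for generator output (a
saturated segment could otherwise "gain" spurious gap pairs under the cheap
gap cost). p-distances divide mismatches by shared ungapped columns
(pairwise deletion) or by columns ungapped everywhere (complete deletion);
a pair with zero shared columns is an error, and bootstrap replicates that
trigger it are dropped (error if > 10% drop).

## Trees and subfamilies

Neighbor joining follows Saitou–Nei with the standard Q-criterion. Two
determinism rules: equal-Q ties choose the lexicographically smallest pair
of cluster keys (a cluster's key is its smallest tip label), and negative
branch estimates are clamped to zero with the deficit moved to the sibling
so the joined pair's distance is preserved. Bootstrap supports are
percentages of replicates whose NJ tree contains the same bipartition;
bipartitions are canonicalised as the side not containing the smallest
label, making them comparable across rootings. The tree is rooted on the
edge separating the atypical (CDC5-like) out-group, which must be
monophyletic.

Subfamilies are **maximal supported clades**: preorder traversal accepts the
first node with support ≥ `min_support` (default 50), tip count ≥
`min_size` (default 2) and stem branch ≥ `min_stem_length` (default 0.05
p-distance units), skipping its descendants; remaining in-group tips are
orphans. The stem-length condition exists because a reproducible out-group
attachment can give > 50% support to the near-zero "spine" edge subtending
everything except the subfamily nearest the attachment point; ancient
lineages sit on long stems, spine artifacts do not. The root and its two
children (whose edge *is* the out-group split) never qualify. This
automatic delimitation is the package's operationalization of what is
usually a partly manual step, and is labelled as such in the report
metadata.

## Intron patterns

Only introns whose affected codon lies inside the R2R3 domain are compared;
flanking regions are too variable to align. An intron is keyed by the
alignment column of the codon containing the splice point (phase 1/2) or
immediately following it (phase 0) — both reduce to ⌊upstream/3⌋+1 — which
makes pattern identity robust to gap columns. Pattern identity is exact
column-and-phase equality (`column_tolerance` 0 by default; a tolerance is
available for imported noisy MSAs). Ids a, b, c, … are assigned by
descending membership, ties by lexicographic site list. Two event counts
are reported: the site-level minimum under a single-gain assumption
(= unique-site count) and the pattern-level count of non-intronless
patterns not derivable by loss from any other pattern. Both are reported
because no single rule reduces one to the other.

## Ancestral counts and duplications

Presence is at species level; gene-tree reconciliation is deliberately not
attempted. At node *v*: min = #subfamilies present in ≥ 2 distinct child
subtrees (their own MRCA lies at or above *v*, assuming each subfamily
arose once); max = #subfamilies present anywhere in *v*'s clade. At a tip,
min = max = the observed subfamily count. Orphans are excluded and counted
separately. Both rules are pluggable functions.

Tandem clustering links family members on one chromosome with ≤
`max_intervening` (default 1) non-family genes between them — family
members never count as intervening, which is what lets arrays of three to
six genes chain into one cluster — and takes connected components.
Segmental calls are synteny anchors whose two genes are both family
members; a gene can be both tandem and segmental and is reported with both
flags. Rates are per species: family size, tandem genes, segmental genes,
dispersed genes, and the segmental percentage.

## What the benchmarks show — and what they do not

Passing tests demonstrate internal correctness (oracle equality for
p-distances, NJ consistency on additive matrices, exact round-trips of
planted intron sites and duplications, bracket validity of the ancestral
bounds) and end-to-end recoverability under the simulator's assumptions:
no indels inside repeats, site-independent substitution, one intron pattern
per subfamily, single subfamily origins, and clean synteny files. Real data
violate all of these to some degree — alignment error, pattern mixing
within subfamilies (observed in real 2R-MYBs among the most similar
patterns), convergent losses, incomplete synteny — so the benchmarks bound
algorithmic error, not biological error. The import paths (external MSAs,
arbitrary GFF3/synteny files) exist so the same machinery can be applied to
real genomes.

## Problem sizes and runtime

Default experiments are sized for a laptop: 10 subfamilies × 8 species
(~100 genes), bootstrap 200 for the end-to-end run (the stage is cached on
a content hash of alignment + parameters, since it dominates runtime), 100
random trees for the NJ check, 200 simulations for the ancestral-bound
check, and a 600-protein scanner benchmark. Everything is seeded through a
single integer; identical config + seed reproduces every output file
byte-for-byte.
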