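"""Synthetic R2R3-MYB family generator with known ground truth.

Every downstream stage of the pipeline (repeat scanning, domain alignment,
tree building, intron typing, ancestral-count bounds, duplication calling) is
exercised on data produced here, so the generator records complete truth:
which gene belongs to which subfamily and species, which intron sites were
planted, which duplications were realized as tandem arrays or segmental
pairs, and how many subfamily lineages were alive at every node of the
species tree.

Model
-----
Each ancestral subfamily is founded at its origin node of the species tree
(the root by default) and evolves independently under a linear birth-death
process with per-lineage duplication rate ``dup_rate`` and loss rate
``loss_rate``, simulated exactly (Gillespie) along every branch.  Lineages
surviving to the tips are emitted as genes.  Protein sequences consist of two
adjacent 53-aa repeats (R2, R3) derived from the shipped consensus, evolved
along the gene tree by per-column substitution; there is no indel evolution
inside repeats, so domain alignment columns stay identifiable by
construction.  Intron patterns — sets of (domain column, phase) sites — are
assigned per subfamily from a catalog and planted into single-gene GFF3
models.  Chromosome layouts realize duplication events as tandem arrays
(0 or 1 intervening filler genes), segmental pairs (written as synteny-block
anchors), or dispersed copies.

Per-node "true family counts" are at subfamily-lineage granularity,
conditioned on survival: the number of subfamilies alive on the branch
entering a node that leave at least one emitted gene in that node's clade.
This is the quantity the min/max ancestral estimators bound; lineages that
go extinct without sampled descendants are invisible to any estimator and
are excluded on purpose.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from ._profiles import (
    AMINO_ACIDS,
    ANCHOR_OFFSETS,
    CDC5_R1,
    CDC5_R2,
    MYB_R2,
    MYB_R3,
    REPEAT_LENGTH,
)

DOMAIN_LENGTH = 2 * REPEAT_LENGTH  # R2 + R3, adjacent

#: Anchor offsets within the R2R3 domain (0-based).
DOMAIN_ANCHOR_OFFSETS = tuple(ANCHOR_OFFSETS) + tuple(
    REPEAT_LENGTH + o for o in ANCHOR_OFFSETS
)

#: Default 8-species tree with named internal nodes; root-to-tip depth 1.0.
DEFAULT_SPECIES_TREE = (
    "(((sp1:0.4,sp2:0.4)n4:0.3,(sp3:0.4,sp4:0.4)n5:0.3)n2:0.3,"
    "((sp5:0.4,sp6:0.4)n6:0.3,(sp7:0.4,sp8:0.4)n7:0.3)n3:0.3)root;"
)

#: Default intron-pattern catalog: 12 patterns over 17 unique
#: (domain column, phase) sites.  Pattern 0 has two sites; patterns 1 and 2
#: each retain one of them (derivable by single loss); pattern 3 is
#: intronless; the rest are rarer multi-site patterns.
DEFAULT_INTRON_CATALOG: tuple[frozenset, ...] = tuple(
    frozenset(s)
    for s in [
        {(33, 1), (91, 2)},            # a
        {(33, 1)},                     # b
        {(91, 2)},                     # c
        set(),                         # d (intronless)
        {(10, 0), (60, 1)},            # e
        {(22, 2)},                     # f
        {(47, 0), (78, 1), (99, 2)},   # g
        {(15, 1)},                     # h
        {(5, 0), (40, 2), (70, 0), (95, 1)},  # i
        {(55, 0)},                     # j
        {(83, 2)},                     # k
        {(28, 0), (66, 2)},            # l
    ]
)

# Fixed back-translation table (one codon per residue).
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

OUTGROUP_SUBFAMILY = "CDC5"


@dataclass
class SimulationConfig:
    """Parameters of one synthetic-family simulation.

    Rates are events per lineage per unit branch length; probabilities are
    per event.  The same config and seed always produce byte-identical
    output files.
    """

    species_tree: str = DEFAULT_SPECIES_TREE
    n_ancestral_subfamilies: int = 10
    dup_rate: float = 0.3
    loss_rate: float = 0.1
    repeat_divergence: float = 0.2
    subfamily_stem_length: float = 12.0
    w_anchor_conservation: float = 1.0
    intron_catalog: Sequence[frozenset] = DEFAULT_INTRON_CATALOG
    tandem_fraction: float = 0.3
    segmental_fraction: float = 0.3
    decoy_fraction: float = 0.15
    origin_spread: float = 0.0
    n_outgroup_per_species: int = 1
    flank_intron_prob: float = 0.2
    intron_length: int = 120
    n_chromosomes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("birth/death rates must be non-negative")
        if not (np.isfinite(self.dup_rate) and np.isfinite(self.loss_rate)):
            raise ValueError("birth/death rates must be finite")
        if self.subfamily_stem_length < 0:
            raise ValueError("subfamily_stem_length must be non-negative")
        for name in (
            "repeat_divergence",
            "w_anchor_conservation",
            "tandem_fraction",
            "segmental_fraction",
            "decoy_fraction",
            "origin_spread",
            "flank_intron_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tandem_fraction + self.segmental_fraction > 1.0 + 1e-12:
            raise ValueError("tandem_fraction + segmental_fraction must be <= 1")
        for pat in self.intron_catalog:
            for col, phase in pat:
                if phase not in (0, 1, 2):
                    raise ValueError(f"intron phase must be 0/1/2, got {phase}")
                if not 1 <= col <= DOMAIN_LENGTH:
                    raise ValueError(
                        f"pattern column {col} outside domain length {DOMAIN_LENGTH}"
                    )


class _GeneNode:
    """Node of a per-subfamily gene tree (duplication or speciation point)."""

    __slots__ = ("parent", "length", "children", "gene_id", "seq")

    def __init__(self, parent: Optional["_GeneNode"] = None):
        self.parent = parent
        self.length = 0.0  # time span since parent node
        self.children: list[_GeneNode] = []
        self.gene_id: Optional[str] = None  # set for emitted tip genes
        self.seq = None
        if parent is not None:
            parent.children.append(self)


@dataclass
class SyntheticTruth:
    """Complete ground truth of one simulation.

    ``genes`` has one row per emitted gene (family, outgroup and decoy);
    ``node_counts`` maps species-tree node labels to the number of subfamily
    lineages alive at that node with surviving emitted descendants.
    """

    config: SimulationConfig
    genes: pd.DataFrame
    node_counts: dict[str, int]
    dup_pairs: pd.DataFrame  # event_id, type, species, gene_a, gene_b
    tandem_clusters: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)
    segmental_pairs: list[tuple[str, str]] = field(default_factory=list)
    intron_sites: dict[str, tuple] = field(default_factory=dict)
    noise_introns: dict[str, list] = field(default_factory=dict)
    proteins: dict[str, str] = field(default_factory=dict)
    cds: dict[str, str] = field(default_factory=dict)
    gene_order: Optional[pd.DataFrame] = None
    synteny: Optional[pd.DataFrame] = None
    # internal: per-subfamily gene-tree founders (not serialized)
    _founders: dict = field(default_factory=dict, repr=False)

    @property
    def family_gene_ids(self) -> list[str]:
        g = self.genes
        return list(g.loc[g["kind"] == "family", "gene_id"])

    def pattern_of_subfamily(self, subfamily: str) -> int:
        rows = self.genes.loc[self.genes["subfamily"] == subfamily, "pattern_id"]
        return int(rows.iloc[0])


def parse_species_tree(newick: str) -> dendropy.Tree:
    """Parse a Newick species tree, keeping internal node labels."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"malformed Newick: {exc}") from exc
    if len(tree.leaf_nodes()) < 1:
        raise ValueError("malformed Newick: no leaves parsed")
    return tree


def _node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label if node.label else f"_internal_{id(node)}"


# ---------------------------------------------------------------------------
# simulate_family_evolution
# ---------------------------------------------------------------------------

def _evolve_branch(genes_in, t, lam, mu, rng, dup_sink):
    """Exact birth-death simulation of a set of lineages along one branch.

    Returns the lineages alive at the bottom of the branch.  Duplication
    events append ``(continuing_node, new_node)`` to ``dup_sink``.
    """
    out = []
    tot = lam + mu
    stack = list(genes_in)
    rem_stack = [t] * len(stack)
    while stack:
        g = stack.pop()
        rem = rem_stack.pop()
        while True:
            if tot <= 0.0:
                g.length += rem
                out.append(g)
                break
            wait = rng.exponential(1.0 / tot)
            if wait >= rem:
                g.length += rem
                out.append(g)
                break
            g.length += wait
            rem -= wait
            if rng.random() < lam / tot:
                cont = _GeneNode(parent=g)
                new = _GeneNode(parent=g)
                dup_sink.append((cont, new))
                stack.append(new)
                rem_stack.append(rem)
                g = cont
            else:
                break  # loss: lineage ends here
    return out


def simulate_family_evolution(config: SimulationConfig) -> SyntheticTruth:
    """Evolve ancestral subfamilies along the species tree.

    Each subfamily starts from one founder lineage at its origin node and
    undergoes independent linear birth-death evolution; lineages surviving to
    the tips become emitted genes.  Truth records gene->subfamily/species
    maps, per-node family counts, and per-species realized duplication pairs
    typed tandem/segmental/dispersed.
    """
    tree = parse_species_tree(config.species_tree)
    rng = np.random.default_rng(config.seed)
    lam, mu = config.dup_rate, config.loss_rate

    internal_nonroot = [
        n for n in tree.preorder_node_iter() if not n.is_leaf() and n.parent_node
    ]
    root = tree.seed_node

    # subfamily origin nodes
    subfamilies = [f"S{i + 1}" for i in range(config.n_ancestral_subfamilies)]
    origins: dict[str, dendropy.Node] = {}
    for sf in subfamilies:
        if internal_nonroot and rng.random() < config.origin_spread:
            origins[sf] = internal_nonroot[rng.integers(len(internal_nonroot))]
        else:
            origins[sf] = root
    outgroup_cfg = config.n_outgroup_per_species > 0
    if outgroup_cfg:
        origins[OUTGROUP_SUBFAMILY] = root

    gene_rows = []
    dup_rows = []
    founders = {}
    alive_at: dict[str, set] = {}        # subfamily -> node labels alive
    emitted_at: dict[str, dict] = {}     # subfamily -> tip label -> [genes]
    serial_by_species: dict[str, int] = {}
    event_serial = 0

    sf_list = subfamilies + ([OUTGROUP_SUBFAMILY] if outgroup_cfg else [])
    for sf_idx, sf in enumerate(sf_list):
        is_og = sf == OUTGROUP_SUBFAMILY
        founder = _GeneNode()
        founders[sf] = founder
        alive: set = set()
        tips: dict[str, list] = {}
        dup_events: list[tuple] = []  # (event_idx, cont, new)

        def descend(sp_node, genes_here, sf=sf, alive=alive, tips=tips,
                    dup_events=dup_events, is_og=is_og):
            nonlocal event_serial
            if not genes_here:
                return
            alive.add(_node_label(sp_node))
            if sp_node.is_leaf():
                tips.setdefault(sp_node.taxon.label, []).extend(genes_here)
                return
            for child in sp_node.child_nodes():
                entering = []
                for g in genes_here:
                    entering.append(_GeneNode(parent=g))
                sink: list = []
                blen = child.edge.length or 0.0
                use_lam = 0.0 if is_og else lam
                use_mu = 0.0 if is_og else mu
                survivors = _evolve_branch(entering, blen, use_lam, use_mu, rng, sink)
                for cont, new in sink:
                    dup_events.append((cont, new))
                descend(child, survivors, sf=sf, alive=alive, tips=tips,
                        dup_events=dup_events, is_og=is_og)

        descend(origins[sf], [founder])
        alive_at[sf] = alive
        emitted_at[sf] = tips

        pattern_id = sf_idx % max(len(config.intron_catalog), 1)
        # emit genes at tips in tree order
        for leaf in tree.leaf_node_iter():
            sp = leaf.taxon.label
            for g in tips.get(sp, []):
                serial = serial_by_species.get(sp, 0) + 1
                serial_by_species[sp] = serial
                g.gene_id = f"{sp}_g{serial:04d}"
                gene_rows.append(
                    dict(
                        gene_id=g.gene_id,
                        species=sp,
                        subfamily=sf,
                        kind="outgroup" if is_og else "family",
                        pattern_id=pattern_id if config.intron_catalog else -1,
                        domain_start=-1,
                        chromosome="",
                        ordinal=-1,
                    )
                )

        # realized duplication pairs per species
        desc_cache: dict[int, dict[str, list[str]]] = {}

        def desc_by_species(node: _GeneNode) -> dict[str, list[str]]:
            key = id(node)
            if key in desc_cache:
                return desc_cache[key]
            res: dict[str, list[str]] = {}
            if node.gene_id is not None:
                sp = node.gene_id.split("_g")[0]
                res.setdefault(sp, []).append(node.gene_id)
            for ch in node.children:
                for sp, ids in desc_by_species(ch).items():
                    res.setdefault(sp, []).extend(ids)
            for ids in res.values():
                ids.sort()
            desc_cache[key] = res
            return res

        tf, sg = config.tandem_fraction, config.segmental_fraction
        for cont, new in dup_events:
            u = rng.random()
            if u < tf:
                ev_type = "tandem"
            elif u < tf + sg:
                ev_type = "segmental"
            else:
                ev_type = "dispersed"
            da, db = desc_by_species(cont), desc_by_species(new)
            for sp in sorted(set(da) & set(db)):
                event_serial += 1
                dup_rows.append(
                    dict(
                        event_id=f"E{event_serial:05d}",
                        type=ev_type,
                        species=sp,
                        gene_a=da[sp][0],
                        gene_b=db[sp][0],
                    )
                )

    # per-node truth counts: subfamily alive at node & >=1 emitted gene in clade
    node_counts: dict[str, int] = {}
    clade_tips = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            clade_tips[node] = {node.taxon.label}
        else:
            s = set()
            for c in node.child_nodes():
                s |= clade_tips[c]
            clade_tips[node] = s
    for node in tree.preorder_node_iter():
        label = _node_label(node)
        count = 0
        for sf in sf_list:
            if label in alive_at[sf] and any(
                sp in clade_tips[node] and emitted_at[sf].get(sp)
                for sp in emitted_at[sf]
            ):
                count += 1
        node_counts[label] = count

    genes = pd.DataFrame(
        gene_rows,
        columns=[
            "gene_id", "species", "subfamily", "kind",
            "pattern_id", "domain_start", "chromosome", "ordinal",
        ],
    )
    dup_pairs = pd.DataFrame(
        dup_rows, columns=["event_id", "type", "species", "gene_a", "gene_b"]
    )
    return SyntheticTruth(
        config=config,
        genes=genes,
        node_counts=node_counts,
        dup_pairs=dup_pairs,
        _founders=founders,
    )


# ---------------------------------------------------------------------------
# emit_sequences
# ---------------------------------------------------------------------------

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
_AA_INDEX = {a: i for i, a in enumerate(_AA)}


def _seq_to_idx(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX[c] for c in seq], dtype=np.int64)


def _idx_to_seq(idx: np.ndarray) -> str:
    return "".join(_AA[idx])


_NON_ANCHOR = np.array(
    [i for i in range(DOMAIN_LENGTH) if i not in DOMAIN_ANCHOR_OFFSETS]
)

# Structurally constrained positions evolve at 5% of the family rate
# (helix-packing residues in real repeats); the remainder are free to
# saturate over deep time.  The slow set is repeat-local so both repeats
# share one column-conservation pattern.
from ._profiles import SLOW_COLUMNS as _REPEAT_SLOW

_SLOW_FACTOR = 0.05
_COLUMN_RATE = np.ones(DOMAIN_LENGTH)
for _i in _REPEAT_SLOW:
    _COLUMN_RATE[_i] = _SLOW_FACTOR
    _COLUMN_RATE[_i + REPEAT_LENGTH] = _SLOW_FACTOR
del _i


def _mutate(idx: np.ndarray, t: float, rate: float, rng) -> np.ndarray:
    """Substitute non-anchor columns with prob 1-exp(-rate*mult*t) each."""
    out = idx.copy()
    if rate <= 0.0 or t <= 0.0:
        return out
    p = 1.0 - np.exp(-rate * t * _COLUMN_RATE[_NON_ANCHOR])
    hit = _NON_ANCHOR[rng.random(_NON_ANCHOR.size) < p]
    if hit.size:
        shift = rng.integers(1, 20, size=hit.size)
        out[hit] = (out[hit] + shift) % 20
    return out


def _random_protein(length: int, rng) -> str:
    return _idx_to_seq(rng.integers(0, 20, size=length))


def emit_sequences(truth: SyntheticTruth, config: SimulationConfig,
                   decoy_fraction: Optional[float] = None) -> None:
    """Emit protein and CDS sequences for every gene, plus decoys.

    Family genes evolve from the MYB R2+R3 consensus along their gene tree;
    outgroup genes evolve from the CDC5 consensus.  Anchor tryptophans are
    retained with probability ``w_anchor_conservation`` (substituted to F
    otherwise).  A ``decoy_fraction`` of non-family proteins (no repeat, a
    single repeat, or repeats with dead anchors) is appended and recorded in
    the truth gene table.  CDS sequences are fixed-table back-translations.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if decoy_fraction is None:
        decoy_fraction = config.decoy_fraction
    myb_root = _seq_to_idx(MYB_R2 + MYB_R3)
    cdc5_root = _seq_to_idx(CDC5_R1 + CDC5_R2)
    rate = config.repeat_divergence
    w_idx = _AA_INDEX["W"]
    f_idx = _AA_INDEX["F"]

    domain_starts: dict[str, int] = {}

    order = {g: i for i, g in enumerate(truth.genes["gene_id"])}
    sf_of_founder = sorted(truth._founders)
    for sf in sf_of_founder:
        founder = truth._founders[sf]
        if sf == OUTGROUP_SUBFAMILY:
            root_seq = cdc5_root
        else:
            # each subfamily is an anciently diverged lineage: its founder
            # carries a characteristic stem of divergence from the consensus
            root_seq = _mutate(
                myb_root, config.subfamily_stem_length, rate, rng
            )
        stack = [(founder, root_seq)]
        emitted = []
        while stack:
            node, seq = stack.pop()
            seq = _mutate(seq, node.length, rate, rng)
            if node.gene_id is not None:
                emitted.append((order[node.gene_id], node.gene_id, seq))
            for ch in node.children:
                stack.append((ch, seq))
        for _, gid, seq in sorted(emitted):
            seq = seq.copy()
            for off in DOMAIN_ANCHOR_OFFSETS:
                if rng.random() < config.w_anchor_conservation:
                    seq[off] = w_idx
                else:
                    seq[off] = f_idx
            nflank = int(rng.integers(10, 41))
            cflank = int(rng.integers(40, 121))
            prot = (
                _random_protein(nflank, rng)
                + _idx_to_seq(seq)
                + _random_protein(cflank, rng)
            )
            truth.proteins[gid] = prot
            domain_starts[gid] = nflank + 1

    # decoys
    n_family = int((truth.genes["kind"] == "family").sum())
    n_decoys = _round_half_even(decoy_fraction * n_family)
    species = sorted(truth.genes["species"].unique())
    decoy_rows = []
    kinds = ("decoy_random", "decoy_single", "decoy_deadanchor")
    serials = {
        sp: int(
            truth.genes.loc[truth.genes["species"] == sp, "gene_id"]
            .str.extract(r"_g(\d+)$")[0].astype(int).max()
        )
        for sp in species
    }
    for i in range(n_decoys):
        kind = kinds[i % 3]
        sp = species[i % len(species)]
        serials[sp] += 1
        gid = f"{sp}_g{serials[sp]:04d}"
        if kind == "decoy_random":
            prot = _random_protein(int(rng.integers(150, 301)), rng)
            dstart = -1
        elif kind == "decoy_single":
            nf, cf = int(rng.integers(10, 41)), int(rng.integers(40, 121))
            prot = _random_protein(nf, rng) + MYB_R2 + _random_protein(cf, rng)
            dstart = -1
        else:  # two adjacent repeats, 2 of 3 anchors killed in each
            dom = list(MYB_R2 + MYB_R3)
            for base in (0, REPEAT_LENGTH):
                for off in ANCHOR_OFFSETS[:2]:
                    dom[base + off] = "L"
            nf, cf = int(rng.integers(10, 41)), int(rng.integers(40, 121))
            prot = _random_protein(nf, rng) + "".join(dom) + _random_protein(cf, rng)
            dstart = nf + 1
        truth.proteins[gid] = prot
        decoy_rows.append(
            dict(gene_id=gid, species=sp, subfamily="DECOY", kind=kind,
                 pattern_id=-1, domain_start=dstart, chromosome="", ordinal=-1)
        )

    if decoy_rows:
        truth.genes = pd.concat(
            [truth.genes, pd.DataFrame(decoy_rows)], ignore_index=True
        )
    truth.genes["domain_start"] = [
        domain_starts.get(g, ds)
        for g, ds in zip(truth.genes["gene_id"], truth.genes["domain_start"])
    ]
    for gid, prot in truth.proteins.items():
        truth.cds[gid] = "".join(_CODON[a] for a in prot)


def _round_half_even(x: float) -> int:
    return int(round(x))


# ---------------------------------------------------------------------------
# layout_genome
# ---------------------------------------------------------------------------

def layout_genome(truth: SyntheticTruth, config: SimulationConfig) -> None:
    """Place genes on chromosomes and realize duplication geometry.

    Tandem-typed duplication pairs are chained into arrays whose members are
    separated by 0 or 1 filler genes; all other gene placements are separated
    by at least two fillers, so tandem truth is exactly recoverable under the
    <=1-intervening-gene rule.  Segmental pairs are written as anchor rows of
    synteny blocks (with flanking filler anchors).  Fills ``gene_order``,
    ``synteny``, ``tandem_clusters``, ``segmental_pairs`` and the chromosome/
    ordinal columns of the truth gene table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes = truth.genes
    order_rows = []
    synteny_rows = []
    truth.tandem_clusters = {}
    truth.segmental_pairs = []
    block_serial = 0
    filler_of_gene: dict[str, list[str]] = {}

    for sp in sorted(genes["species"].unique()):
        sub = genes[genes["species"] == sp]
        ids = list(sub["gene_id"])
        family_ids = set(sub.loc[sub["kind"] == "family", "gene_id"])
        dp = truth.dup_pairs
        dp_sp = dp[(dp["species"] == sp)] if len(dp) else dp

        # union-find over realized tandem pairs (family genes only)
        parent = {g: g for g in ids}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

        if len(dp_sp):
            for _, row in dp_sp[dp_sp["type"] == "tandem"].iterrows():
                if row["gene_a"] in family_ids and row["gene_b"] in family_ids:
                    union(row["gene_a"], row["gene_b"])

        comps: dict[str, list[str]] = {}
        for g in ids:
            comps.setdefault(find(g), []).append(g)
        entities = []
        for root in sorted(comps):
            members = sorted(comps[root])
            entities.append(members)
        if len(entities) > 1:
            entities = [entities[i] for i in rng.permutation(len(entities))]

        # lay out chromosomes
        n_chrom = max(1, config.n_chromosomes)
        chrom_seqs: list[list[tuple[str, bool]]] = [[] for _ in range(n_chrom)]
        filler_serial = 0

        def filler(ci):
            nonlocal filler_serial
            filler_serial += 1
            chrom_seqs[ci].append((f"{sp}_f{filler_serial:04d}", False))

        for ci in range(n_chrom):
            for _ in range(int(rng.integers(1, 4))):
                filler(ci)
        for k, ent in enumerate(entities):
            ci = k % n_chrom
            for j, g in enumerate(ent):
                if j > 0:
                    for _ in range(int(rng.integers(0, 2))):  # 0 or 1 filler
                        filler(ci)
                chrom_seqs[ci].append((g, True))
            for _ in range(int(rng.integers(2, 7))):
                filler(ci)
            if len(ent) > 1 and all(g in family_ids for g in ent):
                truth.tandem_clusters.setdefault(sp, []).append(tuple(ent))

        chrom_of: dict[str, str] = {}
        ordinal_of: dict[str, int] = {}
        for ci, seq in enumerate(chrom_seqs):
            chrom = f"{sp}_chr{ci + 1}"
            for pos, (g, is_gene) in enumerate(seq, start=1):
                order_rows.append(
                    dict(gene_id=g, species=sp, chromosome=chrom, ordinal=pos)
                )
                chrom_of[g] = chrom
                ordinal_of[g] = pos
                if is_gene:
                    prev = seq[pos - 2][0] if pos >= 2 else None
                    filler_of_gene[g] = (
                        [prev] if prev and prev.startswith(f"{sp}_f") else []
                    )

        mask = genes["species"] == sp
        genes.loc[mask, "chromosome"] = genes.loc[mask, "gene_id"].map(chrom_of)
        genes.loc[mask, "ordinal"] = genes.loc[mask, "gene_id"].map(ordinal_of)

        # synteny blocks for realized segmental pairs
        if len(dp_sp):
            for _, row in dp_sp[dp_sp["type"] == "segmental"].iterrows():
                ga, gb = row["gene_a"], row["gene_b"]
                if ga not in family_ids or gb not in family_ids:
                    continue
                block_serial += 1
                bid = f"B{block_serial:04d}"
                fa = filler_of_gene.get(ga, [])
                fb = filler_of_gene.get(gb, [])
                if fa and fb:
                    synteny_rows.append(dict(block_id=bid, gene_a=fa[0], gene_b=fb[0]))
                synteny_rows.append(dict(block_id=bid, gene_a=ga, gene_b=gb))
                truth.segmental_pairs.append((ga, gb))

    truth.gene_order = pd.DataFrame(
        order_rows, columns=["gene_id", "species", "chromosome", "ordinal"]
    )
    truth.synteny = pd.DataFrame(
        synteny_rows, columns=["block_id", "gene_a", "gene_b"]
    )


# ---------------------------------------------------------------------------
# plant_introns
# ---------------------------------------------------------------------------

def plant_introns(truth: SyntheticTruth, config: SimulationConfig) -> str:
    """Build GFF3 gene models with introns planted at the catalog sites.

    An intron at (domain column c, phase p) is placed after coding base
    3*(pos-1)+p where pos is the protein position of column c; phase-0
    introns therefore sit immediately before the codon of column c.  Random
    flank introns (outside the domain) are added with probability
    ``flank_intron_prob`` per gene and recorded as noise.  Returns the GFF3
    text; also fills ``truth.intron_sites`` / ``truth.noise_introns``.
    """
    if truth.gene_order is None:
        raise ValueError("layout_genome must run before plant_introns")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    catalog = list(config.intron_catalog)
    out = io.StringIO()
    out.write("##gff-version 3\n")

    genes = truth.genes.sort_values(["species", "chromosome", "ordinal"])
    next_start: dict[str, int] = {}
    for _, row in genes.iterrows():
        gid = row["gene_id"]
        prot = truth.proteins[gid]
        cds_len = 3 * len(prot)
        sites: list[tuple[int, int]] = []
        pat = int(row["pattern_id"])
        dstart = int(row["domain_start"])
        if pat >= 0 and dstart > 0:
            if pat >= len(catalog):
                raise ValueError(f"pattern id {pat} outside catalog")
            for col, phase in sorted(catalog[pat]):
                if col > DOMAIN_LENGTH:
                    raise ValueError(
                        f"pattern column {col} outside domain length {DOMAIN_LENGTH}"
                    )
                pos = dstart + col - 1
                sites.append((col, phase))
        truth.intron_sites[gid] = tuple(sorted(sites))
        breaks = sorted(
            3 * (dstart + col - 1 - 1) + phase for col, phase in sites
        )
        noise = []
        if rng.random() < config.flank_intron_prob:
            # one intron in the C-terminal flank, outside the domain
            dom_end_pos = (dstart + DOMAIN_LENGTH) if dstart > 0 else 1
            if dom_end_pos + 2 < len(prot):
                pos = int(rng.integers(dom_end_pos + 1, len(prot)))
                phase = int(rng.integers(0, 3))
                b = 3 * (pos - 1) + phase
                if 0 < b < cds_len and b not in breaks:
                    breaks.append(b)
                    breaks.sort()
                    noise.append((pos, phase))
        truth.noise_introns[gid] = noise

        seg_lens = []
        prev = 0
        for b in breaks:
            seg_lens.append(b - prev)
            prev = b
        seg_lens.append(cds_len - prev)

        chrom = row["chromosome"]
        strand = "+" if rng.random() < 0.5 else "-"
        span = cds_len + (len(seg_lens) - 1) * config.intron_length
        gstart = next_start.get(chrom, 1001)
        gend = gstart + span - 1
        next_start[chrom] = gend + 1500

        out.write(
            f"{chrom}\tmybtrace\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\t"
            f"ID=gene:{gid};Name={gid}\n"
        )
        out.write(
            f"{chrom}\tmybtrace\tmRNA\t{gstart}\t{gend}\t.\t{strand}\t.\t"
            f"ID=mrna:{gid};Parent=gene:{gid}\n"
        )
        # CDS features in translation order; genomic coords depend on strand
        cum = 0
        offset = 0
        cds_feats = []
        for L in seg_lens:
            frame = (3 - (cum % 3)) % 3
            if strand == "+":
                s = gstart + offset
                e = s + L - 1
            else:
                e = gend - offset
                s = e - L + 1
            cds_feats.append((s, e, frame))
            cum += L
            offset += L + config.intron_length
        for s, e, frame in sorted(cds_feats):
            out.write(
                f"{chrom}\tmybtrace\tCDS\t{s}\t{e}\t.\t{strand}\t{frame}\t"
                f"ID=cds:{gid};Parent=mrna:{gid}\n"
            )
    return out.getvalue()


# ---------------------------------------------------------------------------
# bundle writing
# ---------------------------------------------------------------------------

def _write_fasta(path: Path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            s = records[name]
            for i in range(0, len(s), 60):
                fh.write(s[i:i + 60] + "\n")


def simulate_bundle(config: SimulationConfig, outdir: str | Path) -> SyntheticTruth:
    """Run the full generator and write the input bundle to ``outdir``.

    Writes proteins.faa, cds.fna, genes.gff3, gene_order.tsv, synteny.tsv,
    species.nwk, species_map.tsv and truth/*.tsv.  Byte-identical for equal
    config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_family_evolution(config)
    emit_sequences(truth, config)
    layout_genome(truth, config)
    gff = plant_introns(truth, config)

    _write_fasta(outdir / "proteins.faa", truth.proteins)
    _write_fasta(outdir / "cds.fna", truth.cds)
    (outdir / "genes.gff3").write_text(gff)
    truth.gene_order.to_csv(outdir / "gene_order.tsv", sep="\t", index=False)
    truth.synteny.to_csv(outdir / "synteny.tsv", sep="\t", index=False)
    (outdir / "species.nwk").write_text(config.species_tree.strip() + "\n")
    truth.genes[["gene_id", "species"]].to_csv(
        outdir / "species_map.tsv", sep="\t", index=False
    )

    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    truth.genes.to_csv(tdir / "genes.tsv", sep="\t", index=False)
    truth.dup_pairs.to_csv(tdir / "dup_pairs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(n, c) for n, c in truth.node_counts.items()],
        columns=["node", "true_count"],
    ).to_csv(tdir / "node_counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (g, ";".join(f"{c}:{p}" for c, p in sites))
            for g, sites in truth.intron_sites.items()
        ],
        columns=["gene_id", "sites"],
    ).to_csv(tdir / "intron_sites.tsv", sep="\t", index=False)
    return truth
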