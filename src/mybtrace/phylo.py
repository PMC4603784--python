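"""Neighbor-joining trees, bootstrap supports, out-group rooting and
subfamily delimitation.

NJ follows Saitou & Nei's agglomeration with the canonical Q-criterion.
Determinism: when several pairs minimise Q equally, the lexicographically
smallest pair of cluster keys wins (a cluster's key is the smallest tip label
it contains).  Negative branch-length estimates are clamped to zero with the
deficit moved to the sibling branch, preserving the pairwise distance.

Bootstrap supports are percentages of replicates (columns resampled with
replacement, p-distance, NJ) whose trees contain the same bipartition.
Subfamilies are maximal supported clades of the rooted tree: support >= the
threshold, at least ``min_size`` tips, outside the out-group clade, with no
qualifying ancestor.  Remaining in-group tips are orphans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np

from .domain_align import DomainAlignment, DistanceMatrix, p_distance

logger = logging.getLogger(__name__)

ORPHAN = "ORPHAN"


class OutgroupError(ValueError):
    pass


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree."""
    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    taxa = dendropy.TaxonNamespace()
    nodes = []
    keys = []  # smallest tip label per cluster, for deterministic ties
    for label in d.ids:
        taxon = taxa.new_taxon(label)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
        keys.append(label)
    D = d.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # all index pairs attaining the minimum (within numerical noise)
        ii, jj = np.nonzero(np.isclose(Q, qmin, rtol=0.0, atol=1e-12))
        best = None
        for a, b in zip(ii, jj):
            if a >= b:
                continue
            key = tuple(sorted((keys[a], keys[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, i, j = best
        dij = D[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        if vi < 0.0:
            vj += vi
            vi = 0.0
        if vj < 0.0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = vi
        parent.add_child(nodes[j])
        nodes[j].edge.length = vj
        newd = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = newd[keep]
        D2[:-1, -1] = newd[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
        D = D2

    # join the last three clusters at an (unrooted) trifurcation
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    va = max(0.5 * (dab + dac - dbc), 0.0)
    vb = max(0.5 * (dab + dbc - dac), 0.0)
    vc = max(0.5 * (dac + dbc - dab), 0.0)
    root = dendropy.Node()
    for node, v in ((a, va), (b, vb), (c, vc)):
        root.add_child(node)
        node.edge.length = v
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions and bootstrap
# ---------------------------------------------------------------------------

def _splits(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial bipartitions as canonical frozensets of tip labels.

    The canonical side of a split is the one *not* containing the reference
    (lexicographically smallest) label, making splits comparable across
    differently rooted trees.
    """
    labels = sorted(t.label for t in tree.taxon_namespace)
    ref = labels[0]
    all_labels = set(labels)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        if ref in side:
            side = frozenset(all_labels - side)
        if 2 <= len(side) <= len(all_labels) - 2:
            out.add(side)
    return out


def _clade_split(node, all_labels: set, ref: str):
    side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
    if ref in side:
        side = frozenset(all_labels - side)
    return side


def bootstrap_support(
    alignment: DomainAlignment,
    n_reps: int = 1000,
    seed: int = 0,
    deletion: str = "pairwise",
) -> dendropy.Tree:
    """Point-estimate NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate; replicates in which
    some pair shares no ungapped column are dropped (an error is raised when
    more than 10% drop).  Supports are attached as ``node.support`` (floats
    in [0, 100]) and as node labels; the split->support map is kept on the
    returned tree as ``tree.split_supports``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    d0 = p_distance(alignment, deletion)
    tree = nj_tree(d0)
    width = alignment.n_columns
    counts: dict[frozenset, int] = {}
    dropped = 0
    used = 0
    for _ in range(n_reps):
        cols = rng.integers(0, width, size=width)
        rep = DomainAlignment(
            ids=list(alignment.ids),
            rows=["".join(row[c] for c in cols) for row in alignment.rows],
            column_maps=[np.zeros(width, dtype=np.int64)] * len(alignment.ids),
        )
        try:
            drep = p_distance(rep, deletion)
        except ValueError:
            dropped += 1
            continue
        used += 1
        for s in _splits(nj_tree(drep)):
            counts[s] = counts.get(s, 0) + 1
    if dropped > 0.10 * n_reps:
        raise ValueError(
            f"{dropped}/{n_reps} bootstrap replicates had undefined distances"
        )
    if dropped:
        logger.warning("dropped %d bootstrap replicates", dropped)
    supports = {s: 100.0 * c / used for s, c in counts.items()}
    tree.split_supports = supports
    annotate_supports(tree, supports)
    return tree


def annotate_supports(tree: dendropy.Tree, supports: dict[frozenset, float]) -> None:
    """Attach per-split supports to the internal nodes of ``tree``."""
    labels = sorted(t.label for t in tree.taxon_namespace)
    ref = labels[0]
    all_labels = set(labels)
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        node.support = None
        if node.parent_node is None:
            continue
        side = _clade_split(node, all_labels, ref)
        if 2 <= len(side) <= len(all_labels) - 2:
            node.support = supports.get(side, 0.0)
            node.label = f"{node.support:g}"


def root_on_outgroup(tree: dendropy.Tree, outgroup_ids: Iterable[str]) -> dendropy.Tree:
    """Root on the edge separating the out-group from everything else.

    The out-group must form one side of a split of the unrooted tree;
    otherwise an :class:`OutgroupError` lists the conflicting tips.
    """
    og = set(outgroup_ids)
    if not og:
        raise OutgroupError("empty out-group")
    labels = {t.label for t in tree.taxon_namespace}
    missing = og - labels
    if missing:
        raise OutgroupError(f"out-group tips not in tree: {sorted(missing)}")
    supports_in = getattr(tree, "split_supports", None)
    tree = tree.clone(depth=1)
    tree.split_supports = supports_in
    if len(og) == len(labels):
        raise OutgroupError("out-group contains every tip")

    target = None
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if side == og or (labels - side) == og:
            target = node
            break
    if target is None:
        tree.is_rooted = True  # treat seed node as root for MRCA reporting
        mrca = tree.mrca(taxa=[t for t in tree.taxon_namespace if t.label in og])
        inside = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        raise OutgroupError(
            "out-group is not monophyletic; conflicting tips: "
            f"{sorted(og)} (smallest containing clade also holds "
            f"{sorted(inside - og)[:10]})"
        )
    # ensure target subtends exactly the outgroup side
    side = {leaf.taxon.label for leaf in target.leaf_iter()}
    edge = target.edge
    L = edge.length or 0.0
    tree.reroot_at_edge(edge, length1=L / 2.0, length2=L / 2.0)
    tree.is_rooted = True
    supports = getattr(tree, "split_supports", None)
    if supports:
        annotate_supports(tree, supports)
    return tree


# ---------------------------------------------------------------------------
# subfamily calling
# ---------------------------------------------------------------------------

@dataclass
class SubfamilyAssignment:
    """Gene -> subfamily labels plus per-subfamily metadata."""

    assignment: dict[str, str]
    subfamilies: dict[str, dict] = field(default_factory=dict)
    outgroup: tuple[str, ...] = ()

    @property
    def n_subfamilies(self) -> int:
        return len(self.subfamilies)

    @property
    def orphans(self) -> list[str]:
        return sorted(g for g, s in self.assignment.items() if s == ORPHAN)

    def as_dataframe(self):
        import pandas as pd

        rows = [
            dict(
                gene_id=g,
                subfamily=s,
                support=self.subfamilies.get(s, {}).get("support", np.nan),
            )
            for g, s in self.assignment.items()
        ]
        return pd.DataFrame(rows, columns=["gene_id", "subfamily", "support"])


def call_subfamilies(
    tree: dendropy.Tree,
    min_support: float = 50.0,
    min_size: int = 2,
    outgroup_ids: Iterable[str] = (),
    min_stem_length: float = 0.05,
) -> SubfamilyAssignment:
    """Delimit subfamilies as maximal supported clades of the rooted tree.

    Traverses preorder; a node qualifies when its support >= ``min_support``,
    it spans >= ``min_size`` tips, and its stem branch is >=
    ``min_stem_length`` (subfamilies are anciently diverged lineages, so they
    sit on long stems; near-zero internal edges are unresolved backbone, and
    a reproducible out-group attachment can lend such a spine edge high
    support without it being a lineage).  Descendants of a qualifying node
    are skipped.  The root, the children of the root (the out-group clade and
    its complement, which share the same split) and anything inside the
    out-group never qualify.  Unassigned in-group tips become orphans.
    Subfamilies are numbered S1..Sk in traversal order.
    """
    og = set(outgroup_ids)
    assignment: dict[str, str] = {}
    meta: dict[str, dict] = {}
    serial = 0

    root = tree.seed_node
    # with an out-group, the in-group child of the root sits on the same
    # split as the out-group clade and must not swallow the whole in-group
    root_children = set(root.child_nodes()) if og else set()

    def visit(node):
        nonlocal serial
        tips = [leaf.taxon.label for leaf in node.leaf_iter()]
        if og and set(tips) <= og:
            return  # out-group clade: not classified
        qualifies = (
            node not in root_children
            and node.parent_node is not None
            and not node.is_leaf()
            and getattr(node, "support", None) is not None
            and node.support >= min_support
            and len(tips) >= min_size
            and (node.edge.length or 0.0) >= min_stem_length
            and not (og & set(tips))
        )
        if qualifies:
            serial += 1
            name = f"S{serial}"
            for t in tips:
                assignment[t] = name
            meta[name] = dict(
                support=float(node.support),
                size=len(tips),
                tips=tuple(sorted(tips)),
            )
            return
        if node.is_leaf():
            label = node.taxon.label
            if label not in og:
                assignment[label] = ORPHAN
            return
        for child in node.child_nodes():
            visit(child)

    visit(root)
    return SubfamilyAssignment(
        assignment=assignment, subfamilies=meta, outgroup=tuple(sorted(og))
    )


# ---------------------------------------------------------------------------
# helpers for tests and pipeline
# ---------------------------------------------------------------------------

def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Additive (path-length) distance matrix of a tree's tips."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels, M, np.full((n, n), 1))


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds distance via canonical split sets."""
    s1, s2 = _splits(t1), _splits(t2)
    return len(s1 ^ s2)
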