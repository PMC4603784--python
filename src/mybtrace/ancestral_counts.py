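"""Minimum / maximum family size at ancestral species-tree nodes.

The estimators work from subfamily-level presence only, with no gene-tree
reconciliation.  Each subfamily is assumed to descend from a single ancestral
gene (no convergent origins), so:

* the **minimum** at a node counts subfamilies present in at least two
  distinct child subtrees — such a subfamily's own MRCA lies at or above the
  node, proving at least one ancestral copy there;
* the **maximum** counts subfamilies present anywhere in the node's clade —
  each of those could already have been present, with losses elsewhere.

Both rules are deliberately conservative readings of presence data; gene
losses make the minimum an underestimate and lineage-specific subfamily
origins make the maximum an overestimate, so the true count sits between
them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import dendropy
import pandas as pd

from .phylo import SubfamilyAssignment, ORPHAN
from .synthetic_data import parse_species_tree, _node_label


@dataclass
class PresenceMatrix:
    """Boolean subfamily x species table (plus the orphan side-count)."""

    table: pd.DataFrame  # index: subfamily ids, columns: species, dtype bool
    n_orphans: int = 0

    @property
    def subfamilies(self) -> list[str]:
        return list(self.table.index)

    @property
    def species(self) -> list[str]:
        return list(self.table.columns)


@dataclass
class AncestralCountEstimate:
    node: str
    min_count: int
    max_count: int
    min_subfamilies: tuple[str, ...]
    max_subfamilies: tuple[str, ...]


def build_presence_matrix(
    assignment: SubfamilyAssignment | dict[str, str],
    species_map: dict[str, str],
) -> PresenceMatrix:
    """Cell (f, s) is true iff subfamily f has >=1 member in species s.

    Orphan genes are excluded from the matrix and counted separately.
    """
    genes = (
        assignment.assignment if isinstance(assignment, SubfamilyAssignment)
        else assignment
    )
    cells: dict[str, set] = {}
    n_orphans = 0
    species_seen = set()
    for gene, sf in genes.items():
        if gene not in species_map:
            raise ValueError(f"gene {gene} has no species in the species map")
        sp = species_map[gene]
        species_seen.add(sp)
        if sf == ORPHAN:
            n_orphans += 1
            continue
        cells.setdefault(sf, set()).add(sp)
    subfams = sorted(cells)
    species = sorted(species_seen)
    table = pd.DataFrame(
        [[sp in cells[sf] for sp in species] for sf in subfams],
        index=subfams,
        columns=species,
        dtype=bool,
    )
    return PresenceMatrix(table=table, n_orphans=n_orphans)


def _resolve_node(tree: dendropy.Tree, node: str) -> dendropy.Node:
    for n in tree.preorder_node_iter():
        if _node_label(n) == node:
            return n
    raise ValueError(f"node {node!r} not found in the species tree")


def _clade_species(node: dendropy.Node) -> set:
    return {leaf.taxon.label for leaf in node.leaf_iter()}


def mrca_min(
    presence: PresenceMatrix, species_tree: dendropy.Tree | str, node: str
) -> AncestralCountEstimate:
    """Minimum family size at ``node``: subfamilies spanning >=2 children.

    At a tip, the minimum is the number of subfamilies observed there.
    """
    tree = _as_tree(species_tree)
    n = _resolve_node(tree, node)
    tbl = presence.table
    if n.is_leaf():
        sp = n.taxon.label
        subs = tuple(tbl.index[tbl[sp]]) if sp in tbl.columns else ()
        return AncestralCountEstimate(node, len(subs), len(subs), subs, subs)
    child_species = [
        _clade_species(c) & set(tbl.columns) for c in n.child_nodes()
    ]
    spanning = []
    for sf in tbl.index:
        present = set(tbl.columns[tbl.loc[sf]])
        n_children = sum(bool(present & cs) for cs in child_species)
        if n_children >= 2:
            spanning.append(sf)
    est_max = mrca_max(presence, tree, node)
    return AncestralCountEstimate(
        node, len(spanning), est_max.max_count, tuple(spanning),
        est_max.max_subfamilies,
    )


def mrca_max(
    presence: PresenceMatrix, species_tree: dendropy.Tree | str, node: str
) -> AncestralCountEstimate:
    """Maximum family size at ``node``: subfamilies present in the clade."""
    tree = _as_tree(species_tree)
    n = _resolve_node(tree, node)
    tbl = presence.table
    clade = _clade_species(n) & set(tbl.columns)
    if not clade:
        return AncestralCountEstimate(node, 0, 0, (), ())
    mask = tbl[sorted(clade)].any(axis=1)
    subs = tuple(tbl.index[mask])
    return AncestralCountEstimate(node, 0, len(subs), (), subs)


def _as_tree(species_tree) -> dendropy.Tree:
    if isinstance(species_tree, dendropy.Tree):
        return species_tree
    return parse_species_tree(species_tree)


def mrca_profile(
    presence: PresenceMatrix, species_tree: dendropy.Tree | str
) -> pd.DataFrame:
    """(node, min, max) for every named internal node, root-to-tip order."""
    tree = _as_tree(species_tree)
    rows = []
    for n in tree.preorder_node_iter():
        if n.is_leaf():
            continue
        label = _node_label(n)
        if label.startswith("_internal_"):
            continue  # unnamed node
        mn = mrca_min(presence, tree, label)
        rows.append(
            dict(
                node=label,
                min=mn.min_count,
                max=mn.max_count,
                min_subfamilies=";".join(mn.min_subfamilies),
                max_subfamilies=";".join(mn.max_subfamilies),
            )
        )
    return pd.DataFrame(
        rows, columns=["node", "min", "max", "min_subfamilies", "max_subfamilies"]
    )
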