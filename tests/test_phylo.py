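"""NJ correctness, bootstrap supports, rooting and subfamily calling."""

import dendropy
import numpy as np
import pytest

from mybtrace import domain_align as da
from mybtrace import phylo
from mybtrace.domain_align import DistanceMatrix


from oracles import (
    enumerate_topologies,
    least_squares_sse,
    random_tree_newick,
    topology_splits,
)


def parse(newick):
    return dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True
    )


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def test_three_taxon_closed_form():
    d = DistanceMatrix(
        ["A", "B", "C"],
        np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
        np.ones((3, 3)),
    )
    tree = phylo.nj_tree(d)
    lengths = {
        leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
    }
    assert lengths["A"] == pytest.approx(0.05)
    assert lengths["B"] == pytest.approx(0.15)
    assert lengths["C"] == pytest.approx(0.25)


def test_nj_recovers_generating_topology_on_additive_matrices():
    rng = np.random.default_rng(8)
    for _ in range(25):
        n = int(rng.integers(4, 13))
        true = parse(random_tree_newick(n, rng))
        d = phylo.tree_distance_matrix(true)
        est = phylo.nj_tree(d)
        assert phylo.rf_distance(true, est) == 0


def test_nj_matches_bruteforce_least_squares_small_n():
    rng = np.random.default_rng(9)
    for n in (4, 5):
        for _ in range(5):
            true = parse(random_tree_newick(n, rng))
            d = phylo.tree_distance_matrix(true)
            est_splits = phylo._splits(phylo.nj_tree(d))
            best = None
            for edges in enumerate_topologies(d.ids):
                sse = least_squares_sse(edges, d.ids, d.values)
                if best is None or sse < best[0]:
                    best = (sse, edges)
            assert topology_splits(best[1], d.ids) == est_splits


def test_nj_invariant_to_taxon_order():
    rng = np.random.default_rng(10)
    true = parse(random_tree_newick(8, rng))
    d = phylo.tree_distance_matrix(true)
    perm = rng.permutation(len(d.ids))
    d2 = DistanceMatrix(
        [d.ids[i] for i in perm],
        d.values[np.ix_(perm, perm)],
        d.effective_columns[np.ix_(perm, perm)],
    )
    assert phylo._splits(phylo.nj_tree(d)) == phylo._splits(phylo.nj_tree(d2))


def test_nj_agrees_with_skbio_on_random_matrices():
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    rng = np.random.default_rng(11)
    for _ in range(5):
        n = 7
        true = parse(random_tree_newick(n, rng))
        d = phylo.tree_distance_matrix(true)
        sk_tree = sk_nj(SkDM(d.values, ids=d.ids))
        mine = phylo.nj_tree(d)
        ours = phylo._splits(mine)
        theirs = _skbio_splits(sk_tree, d.ids)
        assert ours == theirs


def _skbio_splits(sk_tree, labels):
    ref = sorted(labels)[0]
    alls = set(labels)
    out = set()
    for node in sk_tree.non_tips(include_self=True):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = frozenset(alls - side)
        if 2 <= len(side) <= len(alls) - 2:
            out.add(side)
    return out


def test_nj_rejects_fewer_than_three():
    d = DistanceMatrix(["A", "B"], np.array([[0, 1.0], [1.0, 0]]), np.ones((2, 2)))
    with pytest.raises(ValueError):
        phylo.nj_tree(d)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _four_taxon_alignment(n_ab, n_ac, n_const):
    rows = {
        "A": "A" * n_ab + "A" * n_ac + "G" * n_const,
        "B": "A" * n_ab + "C" * n_ac + "G" * n_const,
        "C": "C" * n_ab + "A" * n_ac + "G" * n_const,
        "D": "C" * n_ab + "C" * n_ac + "G" * n_const,
    }
    ids = list(rows)
    w = n_ab + n_ac + n_const
    return da.DomainAlignment(
        ids=ids,
        rows=[rows[i] for i in ids],
        column_maps=[np.zeros(w, dtype=int)] * 4,
    )


def test_unanimous_signal_gives_full_support():
    aln = _four_taxon_alignment(30, 0, 0)
    tree = phylo.bootstrap_support(aln, n_reps=100, seed=1)
    split = frozenset({"C", "D"})  # canonical side of AB|CD
    assert tree.split_supports[split] == pytest.approx(100.0)


def test_bootstrap_seed_determinism():
    aln = _four_taxon_alignment(12, 8, 20)
    t1 = phylo.bootstrap_support(aln, n_reps=50, seed=9)
    t2 = phylo.bootstrap_support(aln, n_reps=50, seed=9)
    assert t1.split_supports == t2.split_supports


def test_mixed_signal_support_matches_multinomial_oracle():
    """For 4 taxa the NJ split is the pair-sum minimiser, so the bootstrap
    support of AB|CD has a closed-form Monte-Carlo estimate: the frequency,
    over multinomial column resamples, that AB-supporting columns are at
    least as many as AC-supporting ones (ties resolve to AB by the
    lexicographic rule)."""
    n_ab, n_ac, n_const = 12, 8, 20
    w = n_ab + n_ac + n_const
    aln = _four_taxon_alignment(n_ab, n_ac, n_const)
    reps = 400
    tree = phylo.bootstrap_support(aln, n_reps=reps, seed=2)
    observed = tree.split_supports[frozenset({"C", "D"})] / 100.0

    rng = np.random.default_rng(3)
    m = 10_000
    draws = rng.multinomial(w, [n_ab / w, n_ac / w, n_const / w], size=m)
    oracle = float((draws[:, 0] >= draws[:, 1]).mean())
    se = np.sqrt(oracle * (1 - oracle) * (1 / reps + 1 / m)) or 1e-3
    assert abs(observed - oracle) <= 3 * se


# ---------------------------------------------------------------------------
# rooting and subfamily calling
# ---------------------------------------------------------------------------

def test_root_on_single_tip_outgroup():
    tree = parse("((A:1,B:1):1,(C:1,D:1):1);")
    rooted = phylo.root_on_outgroup(tree, ["A"])
    kids = rooted.seed_node.child_nodes()
    sides = [{l.taxon.label for l in k.leaf_iter()} for k in kids]
    assert {"A"} in sides


def test_nonmonophyletic_outgroup_raises_listing_tips():
    tree = parse("((A:1,B:1):1,(C:1,D:1):1);")
    with pytest.raises(phylo.OutgroupError, match="A.*C"):
        phylo.root_on_outgroup(tree, ["A", "C"])


def test_rooting_preserves_bipartitions():
    rng = np.random.default_rng(12)
    true = parse(random_tree_newick(8, rng))
    before = phylo._splits(true)
    rooted = phylo.root_on_outgroup(true, ["t0"])
    assert phylo._splits(rooted) == before


def _supported_tree(sup_a, sup_b):
    t = parse("(og:2.0,((a1:0.1,a2:0.1)A:0.5,(b1:0.1,b2:0.1)B:0.5)IN:2.0)R;")
    t.is_rooted = True
    for node in t.preorder_node_iter():
        node.support = None
        if node.label == "A":
            node.support = sup_a
        elif node.label == "B":
            node.support = sup_b
        elif node.label == "IN":
            node.support = 99.0
    return t


def test_supported_clade_becomes_subfamily():
    asg = phylo.call_subfamilies(
        _supported_tree(98.0, 98.0), min_support=50, min_size=2,
        outgroup_ids=["og"],
    )
    assert asg.n_subfamilies == 2
    assert asg.assignment["a1"] == asg.assignment["a2"]
    assert asg.assignment["b1"] == asg.assignment["b2"]
    assert asg.assignment["a1"] != asg.assignment["b1"]
    assert asg.orphans == []


def test_unsupported_clades_become_orphans():
    asg = phylo.call_subfamilies(
        _supported_tree(30.0, 30.0), min_support=50, min_size=2,
        outgroup_ids=["og"],
    )
    assert asg.n_subfamilies == 0
    assert set(asg.orphans) == {"a1", "a2", "b1", "b2"}


def test_subfamily_recovery_on_synthetic_bundle(scanned):
    from sklearn.metrics import adjusted_rand_score

    truth, accepted, _, aln = scanned
    tree = phylo.bootstrap_support(aln, n_reps=100, seed=1)
    og = [p for p, a in accepted.items() if a.is_atypical]
    rooted = phylo.root_on_outgroup(tree, og)
    asg = phylo.call_subfamilies(rooted, 50, 2, outgroup_ids=og)
    truth_sf = dict(zip(truth.genes.gene_id, truth.genes.subfamily))
    genes = list(asg.assignment)
    ari = adjusted_rand_score(
        [truth_sf[g] for g in genes], [asg.assignment[g] for g in genes]
    )
    assert ari >= 0.9
    # partition property: every non-outgroup aligned tip is classified
    assert set(genes) == set(aln.ids) - set(og)
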