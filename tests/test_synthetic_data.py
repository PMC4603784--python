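"""Generator: birth-death statistics, determinism, emitted-sequence truth."""

import math

import numpy as np
import pytest

from mybtrace import SimulationConfig, simulate_bundle, simulate_family_evolution
from mybtrace.synthetic_data import (
    DOMAIN_LENGTH,
    emit_sequences,
    _round_half_even,
)
from mybtrace._profiles import MYB_R2, MYB_R3


FOUR_TIP_TREE = "((A:0.5,B:0.5)n1:0.5,(C:0.5,D:0.5)n2:0.5)root;"


def test_no_events_gives_one_gene_per_subfamily_per_tip():
    cfg = SimulationConfig(
        species_tree=FOUR_TIP_TREE,
        n_ancestral_subfamilies=5,
        dup_rate=0.0,
        loss_rate=0.0,
        n_outgroup_per_species=0,
        seed=7,
    )
    truth = simulate_family_evolution(cfg)
    counts = truth.genes.groupby("species").size()
    assert sorted(counts.index) == ["A", "B", "C", "D"]
    assert (counts == 5).all()
    per_sf = truth.genes.groupby(["species", "subfamily"]).size()
    assert (per_sf == 1).all()


def test_birth_death_mean_matches_closed_form():
    """Mean tip count after t=1 at (lambda, mu)=(0.3, 0.1) is e^{0.2}."""
    lam, mu, t = 0.3, 0.1, 1.0
    n = 10_000
    cfg = SimulationConfig(
        species_tree="(A:1.0)root;",
        n_ancestral_subfamilies=n,
        dup_rate=lam,
        loss_rate=mu,
        n_outgroup_per_species=0,
        seed=11,
    )
    truth = simulate_family_evolution(cfg)
    counts = truth.genes.groupby("subfamily").size()
    mean = counts.sum() / n  # subfamilies with zero survivors count as zero
    expected = math.exp((lam - mu) * t)
    # variance of a linear birth-death population size
    var = (
        (lam + mu) / (lam - mu) * math.exp((lam - mu) * t)
        * (math.exp((lam - mu) * t) - 1)
    )
    se = math.sqrt(var / n)
    assert abs(mean - expected) < 3 * se


def test_seed_determinism_byte_identical(tmp_path):
    cfg = SimulationConfig(seed=5)
    simulate_bundle(cfg, tmp_path / "a")
    simulate_bundle(cfg, tmp_path / "b")
    names = [
        "proteins.faa", "cds.fna", "genes.gff3", "gene_order.tsv",
        "synteny.tsv", "species.nwk", "truth/genes.tsv",
        "truth/node_counts.tsv",
    ]
    for name in names:
        assert (tmp_path / "a" / name).read_bytes() == (
            tmp_path / "b" / name
        ).read_bytes(), name


def test_malformed_newick_and_negative_rates_raise():
    with pytest.raises(ValueError, match="malformed Newick"):
        simulate_family_evolution(
            SimulationConfig(species_tree="((A:1,B:1;", seed=0)
        )
    with pytest.raises(ValueError, match="non-negative"):
        SimulationConfig(dup_rate=-0.1)
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        SimulationConfig(repeat_divergence=1.5)
    with pytest.raises(ValueError, match="tandem_fraction"):
        SimulationConfig(tandem_fraction=0.7, segmental_fraction=0.7)


def test_zero_divergence_emits_exact_consensus_domains():
    cfg = SimulationConfig(
        species_tree=FOUR_TIP_TREE,
        n_ancestral_subfamilies=3,
        dup_rate=0.0,
        loss_rate=0.0,
        repeat_divergence=0.0,
        subfamily_stem_length=0.0,
        w_anchor_conservation=1.0,
        decoy_fraction=0.0,
        n_outgroup_per_species=0,
        seed=3,
    )
    truth = simulate_family_evolution(cfg)
    emit_sequences(truth, cfg)
    consensus = MYB_R2 + MYB_R3
    for _, row in truth.genes.iterrows():
        prot = truth.proteins[row.gene_id]
        d = int(row.domain_start) - 1
        assert prot[d:d + DOMAIN_LENGTH] == consensus


def test_decoy_count_uses_round_half_even():
    cfg = SimulationConfig(seed=2)
    truth = simulate_family_evolution(cfg)
    n_family = int((truth.genes["kind"] == "family").sum())
    emit_sequences(truth, cfg, decoy_fraction=0.2)
    n_decoys = int(truth.genes["kind"].str.startswith("decoy").sum())
    assert n_decoys == _round_half_even(0.2 * n_family)
    # decoys are recorded with their kind and present in the protein set
    decoys = truth.genes[truth.genes["kind"].str.startswith("decoy")]
    assert all(g in truth.proteins for g in decoys["gene_id"])


def test_gene_conservation_across_outputs(bundle):
    """FASTA records == mRNA features == truth gene-table rows."""
    truth, outdir = bundle
    n_truth = len(truth.genes)
    faa = (outdir / "proteins.faa").read_text()
    assert faa.count(">") == n_truth
    gff = (outdir / "genes.gff3").read_text()
    n_mrna = sum(1 for line in gff.splitlines() if "\tmRNA\t" in line)
    assert n_mrna == n_truth
    assert len(truth.cds) == n_truth
    # every gene appears exactly once
    assert truth.genes["gene_id"].is_unique


def test_tandem_children_adjacent_and_synteny_written(bundle):
    truth, _ = bundle
    order = truth.gene_order.set_index("gene_id")
    for sp, clusters in truth.tandem_clusters.items():
        for cluster in clusters:
            ords = sorted(order.loc[g, "ordinal"] for g in cluster)
            chroms = {order.loc[g, "chromosome"] for g in cluster}
            assert len(chroms) == 1
            for a, b in zip(ords, ords[1:]):
                assert b - a <= 2  # at most one filler between members
    for ga, gb in truth.segmental_pairs:
        hit = truth.synteny[
            (truth.synteny.gene_a == ga) & (truth.synteny.gene_b == gb)
        ]
        assert len(hit) >= 1


def test_no_duplication_modes_gives_empty_synteny(tmp_path):
    cfg = SimulationConfig(
        tandem_fraction=0.0, segmental_fraction=0.0, seed=4
    )
    truth = simulate_bundle(cfg, tmp_path)
    assert len(truth.synteny) == 0
    assert truth.tandem_clusters == {}
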