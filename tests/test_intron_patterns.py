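"""Intron phase/position mapping and pattern typing."""

import pytest

from mybtrace import intron_patterns as ip
from mybtrace import SimulationConfig, simulate_bundle
from mybtrace import domain_align, repeat_scan


IDENTITY_MAP = {p: p for p in range(1, 200)}


def _model(lengths, gene_id="g"):
    segs = []
    start = 1
    for L in lengths:
        segs.append((start, start + L - 1))
        start += L + 100
    return ip.GeneModel(gene_id=gene_id, cds_segments=segs)


def test_phase_zero_intron_position():
    events = ip.map_introns(_model([90, 90]), (1, 60), IDENTITY_MAP)
    assert len(events) == 1
    assert events[0].phase == 0
    assert events[0].protein_position == 31


def test_phase_one_intron():
    events = ip.map_introns(_model([91, 89]), (1, 60), IDENTITY_MAP)
    assert events[0].phase == 1
    assert events[0].protein_position == 31


def test_intron_outside_domain_excluded():
    events = ip.map_introns(_model([600, 120]), (10, 115), IDENTITY_MAP)
    assert events == []


def test_cds_not_multiple_of_three_raises():
    with pytest.raises(ValueError, match="divisible by 3"):
        ip.map_introns(_model([91, 90]), (1, 60), IDENTITY_MAP)


def test_identical_site_sets_share_pattern():
    cat = ip.PatternCatalog()
    e = [ip.IntronEvent(33, 1, 33), ip.IntronEvent(91, 0, 91)]
    s1 = cat.assign("g1", e)
    s2 = cat.assign("g2", e)
    assert s1 == s2
    pats = cat.finalize()
    assert len(pats) == 1 and pats[0].members == ["g1", "g2"]


def test_intronless_pattern_and_loss_derivability():
    cat = ip.PatternCatalog()
    two = [ip.IntronEvent(33, 1, 33), ip.IntronEvent(91, 0, 91)]
    cat.assign("g1", two)
    cat.assign("g2", two)
    cat.assign("g3", [ip.IntronEvent(33, 1, 33)])
    cat.assign("g4", [])
    pats = {p.pattern_id: p for p in cat.finalize()}
    # 'a' is the 2-member 2-site pattern; singletons tie-break by site list
    assert pats["a"].sites == frozenset({(33, 1), (91, 0)})
    one_site = next(p for p in pats.values() if p.sites == frozenset({(33, 1)}))
    assert one_site.derivable_by_loss_from == ["a"]
    empty = next(p for p in pats.values() if not p.sites)
    assert set(empty.derivable_by_loss_from) >= {"a"}


def test_summary_set_arithmetic_example():
    cat = ip.PatternCatalog()
    s1, s2 = (33, 1), (91, 0)
    for g, sites in [
        ("g1", [s1, s2]), ("g2", [s1, s2]), ("g3", [s1, s2]),
        ("g4", [s1]), ("g5", [s2]), ("g6", []),
    ]:
        cat.assign(g, [ip.IntronEvent(c, p, c) for c, p in sites])
    summary = ip.summarize_patterns(cat)
    assert summary["n_patterns"] == 4
    assert summary["n_unique_sites"] == 2
    assert summary["site_level_min_insertion_events"] == 2
    assert summary["pattern_level_novel_events"] == 1
    assert summary["novel_pattern_ids"] == ["a"]


def test_all_intronless_gives_zero_sites_and_events():
    cat = ip.PatternCatalog()
    for g in "abc":
        cat.assign(g, [])
    summary = ip.summarize_patterns(cat)
    assert summary["n_unique_sites"] == 0
    assert summary["pattern_level_novel_events"] == 0


def test_round_trip_recovers_planted_sites(tmp_path):
    """Scan -> align -> GFF3 intron mapping recovers every planted
    (column, phase) site exactly, despite flank-intron noise."""
    cfg = SimulationConfig(n_ancestral_subfamilies=12, dup_rate=0.0,
                          loss_rate=0.0, seed=6)
    truth = simulate_bundle(cfg, tmp_path)
    archs = repeat_scan.classify_proteins(truth.proteins)
    accepted, _ = repeat_scan.filter_candidates(archs)
    aln = domain_align.alignment_from_architectures(truth.proteins, accepted)
    models = ip.read_gene_models(tmp_path / "genes.gff3")
    typical = [p for p, a in accepted.items() if not a.is_atypical]
    assert len(typical) == 96
    cat = ip.PatternCatalog()
    for pid in typical:
        arch = accepted[pid]
        span = (arch.chain[0].start, arch.chain[1].end)
        colmap = aln.position_to_column(pid)
        events = ip.map_introns(models[pid], span, colmap)
        sites = cat.assign(pid, events)
        assert sites == frozenset(truth.intron_sites[pid]), pid
    summary = ip.summarize_patterns(cat)
    assert summary["n_patterns"] == 12
    assert summary["n_unique_sites"] == 17


def test_subfamily_homogeneity_is_one_when_patterns_follow_subfamilies(tmp_path):
    cfg = SimulationConfig(n_ancestral_subfamilies=6, seed=9)
    truth = simulate_bundle(cfg, tmp_path)
    archs = repeat_scan.classify_proteins(truth.proteins)
    accepted, _ = repeat_scan.filter_candidates(archs)
    aln = domain_align.alignment_from_architectures(truth.proteins, accepted)
    models = ip.read_gene_models(tmp_path / "genes.gff3")
    typical = [p for p, a in accepted.items() if not a.is_atypical]
    cat = ip.PatternCatalog()
    for pid in typical:
        arch = accepted[pid]
        events = ip.map_introns(
            models[pid],
            (arch.chain[0].start, arch.chain[1].end),
            aln.position_to_column(pid),
        )
        cat.assign(pid, events)
    truth_sf = dict(zip(truth.genes.gene_id, truth.genes.subfamily))
    summary = ip.summarize_patterns(cat, {p: truth_sf[p] for p in typical})
    assert summary["mean_subfamily_homogeneity"] == pytest.approx(1.0)
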