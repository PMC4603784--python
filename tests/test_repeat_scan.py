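"""Repeat scanner: anchor rule, architecture classes, greedy optimality."""

import numpy as np
import pytest

from mybtrace import repeat_scan as rs
from mybtrace._profiles import (
    ANCHOR_OFFSETS,
    CDC5_R1,
    CDC5_R2,
    MYB_R2,
    MYB_R3,
    REPEAT_LENGTH,
)

RNG = np.random.default_rng(42)
AA = "ACDEFGHIKLMNPQRSTVWY"


def random_flank(n, rng=RNG):
    return "".join(rng.choice(list(AA.replace("W", ""))) for _ in range(n))


def test_empty_sequence_yields_no_repeats():
    assert rs.scan_repeats("") == []


def test_consensus_matches_itself_with_three_anchors():
    reps = rs.scan_repeats(MYB_R2)
    assert len(reps) == 1
    assert (reps[0].start, reps[0].end) == (1, REPEAT_LENGTH)
    assert reps[0].anchors == ("W", "W", "W")


@pytest.mark.parametrize("n_killed,expect", [(1, 1), (2, 0)])
def test_two_of_three_tryptophan_rule(n_killed, expect):
    seq = list(MYB_R2)
    for off in ANCHOR_OFFSETS[-n_killed:]:
        seq[off] = "F"
    reps = rs.scan_repeats("".join(seq))
    assert len(reps) == expect
    if expect:
        assert reps[0].n_w_anchors == 2


def test_illegal_characters_rejected_with_positions():
    with pytest.raises(ValueError, match="position"):
        rs.scan_repeats(MYB_R2[:10] + "B" + MYB_R2[11:])


@pytest.mark.parametrize(
    "gap,expected_class,expect_reason",
    [(3, rs.ARCH_2R, False), (300, rs.ARCH_1R, True)],
)
def test_adjacency_rule(gap, expected_class, expect_reason):
    seq = MYB_R2 + random_flank(gap) + MYB_R3
    reps = rs.scan_repeats(seq)
    assert len(reps) == 2
    arch = rs.classify_architecture(reps, seq)
    assert arch.arch_class == expected_class
    assert ("non-adjacent" in arch.reasons) == expect_reason


def test_three_and_four_adjacent_repeats():
    seq3 = MYB_R2 + MYB_R3 + MYB_R2
    arch3 = rs.classify_architecture(rs.scan_repeats(seq3), seq3)
    assert arch3.arch_class == rs.ARCH_3R
    seq4 = MYB_R2 + MYB_R3 + MYB_R2 + MYB_R3
    arch4 = rs.classify_architecture(rs.scan_repeats(seq4), seq4)
    assert arch4.arch_class == rs.ARCH_4R


def test_cdc5_signature_flags_atypical():
    seq = random_flank(15) + CDC5_R1 + CDC5_R2 + random_flank(30)
    arch = rs.classify_architecture(rs.scan_repeats(seq), seq, protein_id="x")
    assert arch.arch_class == rs.ARCH_ATYPICAL
    accepted, rejected = rs.filter_candidates({"x": arch})
    assert "x" in accepted and accepted["x"].is_atypical


def test_filter_rejects_wrong_repeat_count_and_dead_anchors():
    single = random_flank(20) + MYB_R2 + random_flank(40)
    arch1 = rs.classify_architecture(rs.scan_repeats(single), single, protein_id="s")
    dead = list(MYB_R2 + MYB_R3)
    for base in (0, REPEAT_LENGTH):
        for off in ANCHOR_OFFSETS[:2]:
            dead[base + off] = "L"
    dead = "".join(dead)
    arch2 = rs.classify_architecture(rs.scan_repeats(dead), dead, protein_id="d")
    accepted, rejected = rs.filter_candidates({"s": arch1, "d": arch2})
    assert accepted == {}
    assert rejected["s"] == ["wrong_repeat_count"]
    assert rejected["d"] == ["too_few_anchors"]


def test_greedy_equals_bruteforce_optimal_selection():
    """On short sequences, greedy best-score-first selection attains the
    exhaustive best-scoring non-overlapping window placement."""
    model = rs.RepeatModel.default()
    L = model.length
    rng = np.random.default_rng(0)
    for trial in range(20):
        n_reps = int(rng.integers(1, 3))
        seq = random_flank(int(rng.integers(0, 20)), rng)
        for _ in range(n_reps):
            rep = list(MYB_R2)
            for i in np.asarray(rng.choice(L, size=8, replace=False)):
                if int(i) not in ANCHOR_OFFSETS:
                    rep[int(i)] = AA[int(rng.integers(20))]
            seq += "".join(rep) + random_flank(int(rng.integers(0, 25)), rng)
        assert len(seq) <= 250
        greedy = rs.scan_repeats(seq, model)
        greedy_score = sum(r.score for r in greedy)
        cands, _ = rs._window_candidates(seq, model)
        # exact optimum by dynamic programming over window starts
        best = _optimal_nonoverlap_score(cands, L)
        assert greedy_score == pytest.approx(best)


def _optimal_nonoverlap_score(cands, L):
    cands = sorted(cands, key=lambda t: t[1])
    n = len(cands)
    memo = {}

    def solve(k):
        if k >= n:
            return 0.0
        if k in memo:
            return memo[k]
        score, start, _ = cands[k]
        nxt = n
        for m in range(k + 1, n):
            if cands[m][1] >= start + L:
                nxt = m
                break
        res = max(solve(k + 1), score + solve(nxt))
        memo[k] = res
        return res

    return solve(0)


def test_scan_determinism(scanned):
    truth, accepted, rejected, aln = scanned
    again = rs.classify_proteins(truth.proteins)
    acc2, rej2 = rs.filter_candidates(again)
    assert set(acc2) == set(accepted) and rej2 == rejected


def test_recovery_on_default_bundle(scanned):
    """Planted 2R proteins recovered; decoys and outgroup separated."""
    truth, accepted, rejected, _ = scanned
    family = set(truth.family_gene_ids)
    typical = {p for p, a in accepted.items() if not a.is_atypical}
    tp = len(typical & family)
    recall = tp / len(family)
    precision = tp / len(typical)
    assert recall >= 0.95 and precision >= 0.95
    outgroup = set(
        truth.genes.loc[truth.genes["kind"] == "outgroup", "gene_id"]
    )
    atypical = {p for p, a in accepted.items() if a.is_atypical}
    assert atypical == outgroup
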