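"""MYB repeat detection and domain-architecture classification.

A protein is scanned with a positional profile of the 53-column MYB repeat;
windows scoring at least a threshold (default 60% of the profile self-score)
and carrying >=2 of the 3 conserved Trp anchors are accepted as repeats.
Non-overlapping repeats are selected greedily best-score-first, chained when
adjacent (gap <= ``max_gap``), and the chain length gives the architecture
class (1R/2R/3R/4R).  Two-repeat proteins scoring higher against the CDC5
signature than against the c-MYB profile are labelled atypical
(ATYPICAL_CDC5); these are retained as the phylogenetic out-group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._profiles import (
    AMINO_ACIDS,
    ANCHOR_OFFSETS,
    ANCHOR_WEIGHT,
    CDC5_R1,
    CDC5_R2,
    FAST_WEIGHT,
    HELIX_SPANS,
    MYB_R2,
    MYB_R3,
    REPEAT_LENGTH,
    SLOW_COLUMNS,
    SLOW_WEIGHT,
)

ARCH_NONE = "NONE"
ARCH_1R = "1R"
ARCH_2R = "2R"
ARCH_3R = "3R"
ARCH_4R = "4R"
ARCH_ATYPICAL = "ATYPICAL_CDC5"

_VALID_CHARS = set(AMINO_ACIDS) | {"X"}


@dataclass(frozen=True)
class RepeatModel:
    """Positional scoring model for one MYB repeat.

    ``weights`` holds, per column, a residue->weight map; a window scores the
    sum of weights of its residues.  Anchor columns expect Trp and are
    weighted ``ANCHOR_WEIGHT``.  The acceptance threshold defaults to 60% of
    the self-score (the score of a sequence matching the best residue in
    every column).
    """

    weights: tuple  # tuple of dicts residue -> weight
    anchor_columns: tuple[int, ...] = tuple(o + 1 for o in ANCHOR_OFFSETS)  # 1-based
    min_length: int = 50
    max_length: int = 54
    min_anchors: int = 2
    threshold: float = 0.0  # absolute; set by factory

    def __post_init__(self):
        cols = self.anchor_columns
        if not all(1 <= c <= len(self.weights) for c in cols):
            raise ValueError("anchor columns must lie inside the profile")
        if list(cols) != sorted(set(cols)):
            raise ValueError("anchor columns must be strictly increasing")

    @property
    def length(self) -> int:
        return len(self.weights)

    @property
    def self_score(self) -> float:
        return sum(max(w.values()) for w in self.weights)

    def window_score(self, window: str) -> float:
        return sum(w.get(c, 0.0) for c, w in zip(window, self.weights))

    @classmethod
    def from_consensi(cls, consensi: Sequence[str],
                      threshold_fraction: float = 0.6) -> "RepeatModel":
        """Build a model admitting the residues of the given consensi."""
        length = len(consensi[0])
        if any(len(c) != length for c in consensi):
            raise ValueError("consensi must share one length")
        weights = []
        anchors = set(ANCHOR_OFFSETS)
        slow = set(SLOW_COLUMNS)
        for i in range(length):
            if i in anchors:
                weights.append({"W": ANCHOR_WEIGHT})
            else:
                w = SLOW_WEIGHT if i in slow else FAST_WEIGHT
                weights.append({c[i]: w for c in consensi})
        model = cls(weights=tuple(weights))
        thr = threshold_fraction * model.self_score
        return cls(weights=tuple(weights), threshold=thr)

    @classmethod
    def default(cls) -> "RepeatModel":
        """Scanning model covering typical (c-MYB-like) and CDC5 repeats."""
        return cls.from_consensi([MYB_R2, MYB_R3, CDC5_R1, CDC5_R2])


@dataclass(frozen=True)
class MybRepeat:
    """One accepted repeat: 1-based inclusive protein coordinates."""

    start: int
    end: int
    anchors: tuple[str, str, str]
    score: float
    helices: tuple[tuple[int, int], ...] = ()

    @property
    def n_w_anchors(self) -> int:
        return sum(a == "W" for a in self.anchors)


@dataclass
class DomainArchitecture:
    protein_id: str
    repeats: list[MybRepeat]
    arch_class: str
    chain: list[MybRepeat] = field(default_factory=list)
    reasons: list[str] = field(default_factory=list)
    myb_score: float = 0.0
    cdc5_score: float = 0.0

    @property
    def is_atypical(self) -> bool:
        return self.arch_class == ARCH_ATYPICAL


def _validate_sequence(sequence: str) -> None:
    bad = [i + 1 for i, c in enumerate(sequence) if c not in _VALID_CHARS]
    if bad:
        raise ValueError(
            f"illegal characters at positions {bad[:20]}"
            + ("..." if len(bad) > 20 else "")
        )


def _window_candidates(sequence: str, model: RepeatModel):
    """All windows passing the score threshold, with anchor diagnostics.

    Returns (candidates, anchor_failed) where candidates are accepted
    (score, start) windows and anchor_failed counts windows that scored but
    missed the >=2/3-W rule.
    """
    L = model.length
    cands = []
    anchor_failed = 0
    for s in range(0, len(sequence) - L + 1):
        window = sequence[s:s + L]
        score = model.window_score(window)
        if score < model.threshold:
            continue
        anchors = tuple(window[c - 1] for c in model.anchor_columns)
        if sum(a == "W" for a in anchors) >= model.min_anchors:
            cands.append((score, s, anchors))
        else:
            anchor_failed += 1
    return cands, anchor_failed


def scan_repeats(sequence: str, model: Optional[RepeatModel] = None) -> list[MybRepeat]:
    """Detect non-overlapping MYB repeats, left to right.

    Greedy best-score-first selection among overlapping candidate windows;
    ties broken toward the leftmost start.  Each accepted repeat scores at
    least the model threshold and keeps >=2 of 3 Trp anchors.
    """
    if model is None:
        model = RepeatModel.default()
    _validate_sequence(sequence)
    cands, _ = _window_candidates(sequence, model)
    return _select_nonoverlapping(cands, model)


def _select_nonoverlapping(cands, model: RepeatModel) -> list[MybRepeat]:
    L = model.length
    chosen: list[tuple[float, int, tuple]] = []
    occupied: list[tuple[int, int]] = []
    for score, s, anchors in sorted(cands, key=lambda t: (-t[0], t[1])):
        if any(s < e and s + L > b for b, e in occupied):
            continue
        occupied.append((s, s + L))
        chosen.append((score, s, anchors))
    out = []
    for score, s, anchors in sorted(chosen, key=lambda t: t[1]):
        out.append(
            MybRepeat(
                start=s + 1,
                end=s + L,
                anchors=anchors,
                score=score,
                helices=tuple((s + a + 1, s + b) for a, b in HELIX_SPANS),
            )
        )
    return out


def _identity_score(window: str, consensus: str) -> int:
    return sum(a == b for a, b in zip(window, consensus))


def classify_architecture(
    repeats: list[MybRepeat],
    sequence: str,
    model: Optional[RepeatModel] = None,
    cdc5_signature: tuple[str, str] = (CDC5_R1, CDC5_R2),
    myb_signature: tuple[str, str] = (MYB_R2, MYB_R3),
    max_gap: int = 20,
    protein_id: str = "",
) -> DomainArchitecture:
    """Classify a protein's repeat architecture.

    Repeats are chained while the inter-repeat gap is <= ``max_gap`` aa; the
    longest chain sets the class (1R/2R/3R, >=4 repeats -> 4R).  A 2-repeat
    chain whose identity to the CDC5 signature pair exceeds its identity to
    the c-MYB pair is ATYPICAL_CDC5.  Non-chained repeats are recorded with
    reason "non-adjacent".
    """
    if model is None:
        model = RepeatModel.default()
    reasons: list[str] = []
    if not repeats:
        _, anchor_failed = _window_candidates(sequence, model)
        if anchor_failed:
            reasons.append("too_few_anchors")
        elif _has_low_similarity_window(sequence, model):
            reasons.append("low_similarity")
        else:
            reasons.append("no_repeat")
        return DomainArchitecture(protein_id, [], ARCH_NONE, reasons=reasons)

    # longest run of adjacent repeats
    chains: list[list[MybRepeat]] = [[repeats[0]]]
    for prev, cur in zip(repeats, repeats[1:]):
        gap = cur.start - prev.end - 1
        if gap <= max_gap:
            chains[-1].append(cur)
        else:
            chains.append([cur])
    best = max(chains, key=len)
    if len(chains) > 1:
        reasons.append("non-adjacent")

    n = len(best)
    arch = {1: ARCH_1R, 2: ARCH_2R, 3: ARCH_3R}.get(n, ARCH_4R)
    myb_score = cdc5_score = 0.0
    if n == 2:
        w1 = sequence[best[0].start - 1:best[0].end]
        w2 = sequence[best[1].start - 1:best[1].end]
        myb_score = _identity_score(w1, myb_signature[0]) + _identity_score(
            w2, myb_signature[1]
        )
        cdc5_score = _identity_score(w1, cdc5_signature[0]) + _identity_score(
            w2, cdc5_signature[1]
        )
        if cdc5_score > myb_score:
            arch = ARCH_ATYPICAL
    return DomainArchitecture(
        protein_id, repeats, arch, chain=best, reasons=reasons,
        myb_score=myb_score, cdc5_score=cdc5_score,
    )


def _has_low_similarity_window(sequence: str, model: RepeatModel) -> bool:
    """True if some window keeps >=2 W anchors at repeat spacing but scores
    below threshold (the "similar but not c-MYB-like enough" case)."""
    L = model.length
    for s in range(0, len(sequence) - L + 1):
        window = sequence[s:s + L]
        n_w = sum(window[c - 1] == "W" for c in model.anchor_columns)
        if n_w >= model.min_anchors:
            return True
    return False


def classify_proteins(
    proteins: dict[str, str],
    model: Optional[RepeatModel] = None,
    max_gap: int = 20,
) -> dict[str, DomainArchitecture]:
    """Scan and classify a whole protein set (insertion-ordered dict)."""
    if model is None:
        model = RepeatModel.default()
    out = {}
    for pid, seq in proteins.items():
        reps = scan_repeats(seq, model)
        out[pid] = classify_architecture(
            reps, seq, model, max_gap=max_gap, protein_id=pid
        )
    return out


def filter_candidates(
    architectures: dict[str, DomainArchitecture],
    target_class: str = ARCH_2R,
    accept_atypical: bool = True,
):
    """Split architectures into accepted candidates and reasoned rejects.

    Accepted proteins have the target class (default 2R); CDC5-like atypical
    two-repeat proteins are accepted and flagged separately.  Every rejection
    carries a machine-readable reason.
    """
    accepted: dict[str, DomainArchitecture] = {}
    rejected: dict[str, list[str]] = {}
    for pid, arch in architectures.items():
        if arch.arch_class == target_class or (
            accept_atypical and arch.arch_class == ARCH_ATYPICAL
        ):
            accepted[pid] = arch
            continue
        reasons = list(arch.reasons)
        if arch.arch_class == ARCH_NONE:
            if not reasons:
                reasons.append("no_repeat")
        else:
            reasons.append("wrong_repeat_count")
        rejected[pid] = reasons
    return accepted, rejected


def architectures_table(architectures: dict[str, DomainArchitecture]):
    """Flat per-protein table (protein_id, class, repeats, anchors, reasons)."""
    import pandas as pd

    rows = []
    for pid, a in architectures.items():
        rows.append(
            dict(
                protein_id=pid,
                arch_class=a.arch_class,
                n_repeats=len(a.repeats),
                repeat_coords=";".join(f"{r.start}-{r.end}" for r in a.repeats),
                anchors=";".join("".join(r.anchors) for r in a.repeats),
                reasons=";".join(a.reasons),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "arch_class", "n_repeats",
            "repeat_coords", "anchors", "reasons",
        ],
    )
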