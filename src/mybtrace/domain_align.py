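"""Anchor-pinned alignment of R2R3 domains and p-distance computation.

The three Trp anchors of each repeat are pinned to fixed columns; the four
inter-anchor segments of each repeat are aligned to the corresponding
consensus segment by global pairwise alignment (match +1, mismatch 0, gap -1)
and merged align-to-reference style, so an insertion in one sequence opens a
gap column in all others at that segment.  R2 block columns precede R3 block
columns.  Distances are proportions of mismatched sites (p-distances) under
pairwise or complete deletion of gapped columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align, AlignIO

from ._profiles import ANCHOR_OFFSETS, MYB_R2, MYB_R3, REPEAT_LENGTH

GAP = "-"


@dataclass
class DomainAlignment:
    """Aligned domains in shared column coordinates.

    ``column_maps[i][c]`` is the 1-based ungapped protein position of row
    ``i`` at aligned column ``c`` (0 where the row has a gap).
    """

    ids: list[str]
    rows: list[str]
    column_maps: list[np.ndarray]

    def __post_init__(self):
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def position_to_column(self, row_id: str) -> dict[int, int]:
        """Map 1-based ungapped protein position -> 1-based aligned column."""
        i = self.ids.index(row_id)
        out = {}
        for c, p in enumerate(self.column_maps[i], start=1):
            if p > 0:
                out[int(p)] = c
        return out

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{r}\n" for i, r in zip(self.ids, self.rows))


class AlignmentError(ValueError):
    pass


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -1.0
    a.extend_gap_score = -1.0
    return a


def _segment_layout(segments: list[str], ref: str):
    """Align each segment to ``ref`` and merge into shared columns.

    Returns (layout, width): layout[i] is a list of (residue or GAP) strings
    of length width.  Insertion columns relative to the reference are opened
    at the reference position where any sequence inserts; ties in the
    pairwise step resolve to the first reported (leftmost-gap) alignment.
    """
    aligner = _aligner()
    n_ref = len(ref)
    # per sequence: matched[k] residue aligned to ref pos k (or GAP),
    # inserts[k] residues inserted before ref pos k (k in 0..n_ref)
    matched_all, inserts_all = [], []
    for seg in segments:
        matched = [GAP] * n_ref
        inserts: list[list[str]] = [[] for _ in range(n_ref + 1)]
        if seg and len(seg) == n_ref:
            # equal length between pinned anchors: no indel, map diagonally
            matched = list(seg)
        elif seg and n_ref:
            aln = aligner.align(seg, ref)[0]
            sa, sr = aln[0], aln[1]
            rpos = 0
            for cs, cr in zip(sa, sr):
                if cr == GAP:
                    inserts[rpos].append(cs)
                else:
                    if cs != GAP:
                        matched[rpos] = cs
                    rpos += 1
        elif seg:  # no reference segment: everything is an insertion
            inserts[0].extend(seg)
        matched_all.append(matched)
        inserts_all.append(inserts)
    max_ins = [
        max(len(ins[k]) for ins in inserts_all) if inserts_all else 0
        for k in range(n_ref + 1)
    ]
    layout = []
    for matched, inserts in zip(matched_all, inserts_all):
        row: list[str] = []
        for k in range(n_ref + 1):
            ins = inserts[k]
            row.extend(ins + [GAP] * (max_ins[k] - len(ins)))
            if k < n_ref:
                row.append(matched[k])
        layout.append(row)
    width = sum(max_ins) + n_ref
    return layout, width


def locate_anchors(
    repeat: str, expected: tuple[int, ...] = ANCHOR_OFFSETS
) -> tuple[int, ...]:
    """Find the three anchor positions (0-based) of one repeat.

    Candidates are the Trp positions plus the expected offsets (anchors may
    be substituted); the strictly increasing triple minimising total offset
    from the expected spacing wins, with a small penalty for non-Trp.
    """
    from itertools import combinations

    cands = sorted(
        {i for i, c in enumerate(repeat) if c == "W"}
        | {e for e in expected if e < len(repeat)}
    )
    if len(cands) < 3:
        raise AlignmentError("repeat has no locatable anchor positions")
    best = None
    for triple in combinations(cands, 3):
        cost = sum(abs(t - e) for t, e in zip(triple, expected))
        cost += sum(3.0 for t in triple if repeat[t] != "W")
        if best is None or cost < best[0]:
            best = (cost, triple)
    return best[1]


def anchor_align(
    domains: Sequence[tuple],
    consensi: tuple[str, str] = (MYB_R2, MYB_R3),
    anchor_offsets: tuple[int, ...] = ANCHOR_OFFSETS,
) -> DomainAlignment:
    """Align (id, r2, r3) domain triples by pinning the W anchor columns.

    Each element of ``domains`` is ``(id, r2_seq, r3_seq)`` or
    ``(id, r2_seq, r3_seq, r2_protein_start[, r3_protein_start])``; repeats
    must carry their anchors at ``anchor_offsets``.  Sequences whose repeats
    cannot host the anchors (too short) raise :class:`AlignmentError`.
    """
    if not domains:
        raise AlignmentError("no domains to align")
    ids, r2s, r3s, positions = [], [], [], []
    min_len = anchor_offsets[-1] + 1
    for d in domains:
        did, r2, r3 = d[0], d[1], d[2]
        r2_start = d[3] if len(d) > 3 else 1
        r3_start = d[4] if len(d) > 4 else r2_start + len(r2)
        if len(r2) < min_len or len(r3) < min_len:
            raise AlignmentError(f"repeat of {did} too short to locate anchors")
        ids.append(did)
        r2s.append(r2)
        r3s.append(r3)
        positions.append(
            list(range(r2_start, r2_start + len(r2)))
            + list(range(r3_start, r3_start + len(r3)))
        )

    a1, a2, a3 = anchor_offsets
    ref_bounds = [(0, a1), (a1 + 1, a2), (a2 + 1, a3), (a3 + 1, None)]
    pieces: list[list[str]] = [[] for _ in ids]  # per-seq column chars
    for reps, cons in ((r2s, consensi[0]), (r3s, consensi[1])):
        anchors = [locate_anchors(r, anchor_offsets) for r in reps]
        for si in range(4):
            segs = []
            for r, anc in zip(reps, anchors):
                b = 0 if si == 0 else anc[si - 1] + 1
                e = anc[si] if si < 3 else len(r)
                segs.append(r[b:e])
            rb, re_ = ref_bounds[si]
            layout, _ = _segment_layout(segs, cons[rb:re_])
            for i, row in enumerate(layout):
                pieces[i].extend(row)
            if si < 3:  # pinned anchor column
                for i, (r, anc) in enumerate(zip(reps, anchors)):
                    pieces[i].append(r[anc[si]])

    rows = ["".join(p) for p in pieces]
    column_maps = []
    for i, row in enumerate(rows):
        cmap = np.zeros(len(row), dtype=np.int64)
        pos = 0
        for c, ch in enumerate(row):
            if ch != GAP:
                cmap[c] = positions[i][pos]
                pos += 1
        column_maps.append(cmap)
    return DomainAlignment(ids=ids, rows=rows, column_maps=column_maps)


def alignment_from_architectures(
    proteins: dict[str, str], architectures: dict, **kwargs
) -> DomainAlignment:
    """Build the R2R3 domain alignment for accepted 2-repeat proteins."""
    domains = []
    for pid, arch in architectures.items():
        if len(arch.chain) != 2:
            continue
        r2, r3 = arch.chain
        seq = proteins[pid]
        domains.append(
            (pid, seq[r2.start - 1:r2.end], seq[r3.start - 1:r3.end],
             r2.start, r3.start)
        )
    return anchor_align(domains, **kwargs)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal
    effective_columns: np.ndarray  # per-pair shared (compared) column counts

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def p_distance(alignment: DomainAlignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Proportion of differing residues between rows.

    Pairwise deletion compares, for each pair, only the columns where both
    rows are ungapped; complete deletion restricts every pair to columns with
    no gap in any row.  A pair sharing zero columns is an error naming the
    pair.
    """
    if len(alignment.rows) < 2:
        raise ValueError("need at least 2 sequences for distances")
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode: {deletion}")
    arr = np.array([list(r) for r in alignment.rows], dtype="U1")
    nongap = arr != GAP
    if deletion == "complete":
        keep = nongap.all(axis=0)
        arr = arr[:, keep]
        nongap = nongap[:, keep]
    n = arr.shape[0]
    both = nongap[:, None, :] & nongap[None, :, :]
    shared = both.sum(axis=2)
    diff = ((arr[:, None, :] != arr[None, :, :]) & both).sum(axis=2)
    for i in range(n):
        for j in range(i + 1, n):
            if shared[i, j] == 0:
                raise ValueError(
                    "no shared ungapped columns between "
                    f"{alignment.ids[i]} and {alignment.ids[j]}"
                )
    with np.errstate(invalid="ignore"):
        d = np.where(shared > 0, diff / np.maximum(shared, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(alignment.ids), d, shared)


# ---------------------------------------------------------------------------
# import / export
# ---------------------------------------------------------------------------

def import_alignment(path, fmt: str = "fasta") -> DomainAlignment:
    """Load an externally produced MSA (fasta or clustal).

    Column maps are rebuilt from the gap structure; protein positions are
    1-based within the aligned subsequence.
    """
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format: {fmt}")
    try:
        msa = AlignIO.read(path, fmt)
    except ValueError as exc:
        # Biopython raises on ragged rows; identify the offender for fasta
        if fmt == "fasta":
            from Bio import SeqIO

            lengths = {}
            for rec in SeqIO.parse(path, "fasta"):
                lengths[rec.id] = len(rec.seq)
            if lengths and len(set(lengths.values())) > 1:
                ref = max(set(lengths.values()), key=list(lengths.values()).count)
                bad = [i for i, L in lengths.items() if L != ref]
                raise AlignmentError(
                    f"ragged alignment rows for ids: {', '.join(bad)}"
                ) from exc
        raise AlignmentError(str(exc)) from exc
    ids = [rec.id for rec in msa]
    rows = [str(rec.seq).upper() for rec in msa]
    column_maps = []
    for row in rows:
        cmap = np.zeros(len(row), dtype=np.int64)
        pos = 0
        for c, ch in enumerate(row):
            if ch != GAP:
                pos += 1
                cmap[c] = pos
        column_maps.append(cmap)
    return DomainAlignment(ids=ids, rows=rows, column_maps=column_maps)


def export_alignment(alignment: DomainAlignment, path, fmt: str = "fasta") -> None:
    if fmt == "fasta":
        with open(path, "w") as fh:
            fh.write(alignment.to_fasta())
        return
    if fmt == "clustal":
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        msa = MultipleSeqAlignment(
            SeqRecord(Seq(r), id=i, description="")
            for i, r in zip(alignment.ids, alignment.rows)
        )
        AlignIO.write(msa, path, "clustal")
        return
    raise ValueError(f"unsupported alignment format: {fmt}")
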