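"""Intron position/phase mapping and pattern classification.

Only introns inside the R2R3 domain are considered; the remaining gene
regions are too variable for cross-family comparison.  An intron between two
CDS segments has phase = (coding bases upstream) mod 3 (0 between codons, 1
after the first base, 2 after the second) and affects the codon of protein
position floor(upstream/3)+1; that position is translated to a domain
alignment column, so genes are comparable across species.  Genes sharing an
identical set of (column, phase) sites form one intron pattern; pattern ids
a, b, c, ... are assigned in descending membership order.  A pattern is
derivable-by-loss from another when its site set is a strict subset.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntronEvent:
    """One intron: alignment column of the affected codon, and phase."""

    column: int
    phase: int
    protein_position: int
    genomic_position: Optional[int] = None

    def __post_init__(self):
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0, 1 or 2, got {self.phase}")


@dataclass
class GeneModel:
    """CDS layout of one gene in translation order."""

    gene_id: str
    cds_segments: list[tuple[int, int]]  # genomic (start, end), 1-based inclusive
    strand: str = "+"

    @property
    def segment_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.cds_segments]


def read_gene_models(gff3_path) -> dict[str, GeneModel]:
    """Load CDS layouts from a GFF3 file (gene/mRNA/CDS features)."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: dict[str, GeneModel] = {}
    for mrna in db.features_of_type("mRNA"):
        gid = mrna.id.split("mrna:")[-1]
        cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
        if not cds:
            continue
        strand = cds[0].strand
        segs = [(c.start, c.end) for c in cds]
        if strand == "-":
            segs = segs[::-1]  # translation order runs high -> low
        models[gid] = GeneModel(gene_id=gid, cds_segments=segs, strand=strand)
    return models


def map_introns(
    gene_model: GeneModel,
    domain_span: tuple[int, int],
    column_map: dict[int, int],
) -> list[IntronEvent]:
    """Map a gene's introns into domain-alignment coordinates.

    ``domain_span`` is the (start, end) protein interval of the R2R3 domain;
    ``column_map`` maps 1-based protein positions to 1-based alignment
    columns.  Introns whose affected codon lies outside the span are
    discarded.  An in-span position missing from the column map (a gap
    column) is flagged and assigned the nearest preceding mapped position.
    """
    lens = gene_model.segment_lengths
    total = sum(lens)
    if total % 3 != 0:
        raise ValueError(
            f"CDS length of {gene_model.gene_id} not divisible by 3 ({total})"
        )
    lo, hi = domain_span
    events: list[IntronEvent] = []
    upstream = 0
    for (seg, nxt) in zip(gene_model.cds_segments[:-1], gene_model.cds_segments[1:]):
        upstream += seg[1] - seg[0] + 1
        phase = upstream % 3
        # phase 1/2: codon containing the splice point; phase 0: the codon
        # immediately after it -- both reduce to floor(upstream/3)+1
        pos = upstream // 3 + 1
        if not lo <= pos <= hi:
            continue
        col = column_map.get(pos)
        if col is None:
            fallback = max((p for p in column_map if p < pos), default=None)
            if fallback is None:
                logger.warning(
                    "intron of %s at protein position %d maps to no column; "
                    "skipped", gene_model.gene_id, pos,
                )
                continue
            logger.warning(
                "intron of %s at protein position %d falls in a gap column; "
                "assigned nearest preceding position %d",
                gene_model.gene_id, pos, fallback,
            )
            col = column_map[fallback]
        genomic = seg[1] if gene_model.strand == "+" else seg[0]
        events.append(
            IntronEvent(
                column=int(col), phase=int(phase),
                protein_position=int(pos), genomic_position=int(genomic),
            )
        )
    return events


# ---------------------------------------------------------------------------
# pattern registry
# ---------------------------------------------------------------------------

@dataclass
class IntronPattern:
    pattern_id: str
    sites: frozenset  # of (column, phase)
    members: list[str] = field(default_factory=list)
    derivable_by_loss_from: list[str] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)


class PatternCatalog:
    """Mutable registry assigning genes to intron patterns.

    Genes with identical site sets share a pattern; ids (a, b, c, ...) are
    assigned at :meth:`finalize` by descending member count, ties broken by
    the lexicographic site list.
    """

    def __init__(self, column_tolerance: int = 0):
        self.column_tolerance = int(column_tolerance)
        self._members: dict[frozenset, list[str]] = {}
        self._final: Optional[list[IntronPattern]] = None

    def assign(self, gene_id: str, events: Iterable[IntronEvent]) -> frozenset:
        sites = frozenset((e.column, e.phase) for e in events)
        if self.column_tolerance > 0:
            sites = self._snap(sites)
        self._members.setdefault(sites, []).append(gene_id)
        self._final = None
        return sites

    def _snap(self, sites: frozenset) -> frozenset:
        """Merge near-identical columns (same phase) into existing site keys."""
        snapped = set()
        known = {s for key in self._members for s in key}
        for col, phase in sites:
            match = None
            for kc, kp in known:
                if kp == phase and abs(kc - col) <= self.column_tolerance:
                    match = (kc, kp)
                    break
            snapped.add(match if match else (col, phase))
        return frozenset(snapped)

    def finalize(self) -> list[IntronPattern]:
        if self._final is not None:
            return self._final
        ordered = sorted(
            self._members.items(),
            key=lambda kv: (-len(kv[1]), sorted(kv[0])),
        )
        patterns = []
        for i, (sites, members) in enumerate(ordered):
            pid = _pattern_label(i)
            patterns.append(
                IntronPattern(pattern_id=pid, sites=sites, members=sorted(members))
            )
        for p in patterns:
            p.derivable_by_loss_from = [
                q.pattern_id for q in patterns
                if p.sites < q.sites
            ]
        self._final = patterns
        return patterns

    def pattern_of(self, gene_id: str) -> str:
        for p in self.finalize():
            if gene_id in p.members:
                return p.pattern_id
        raise KeyError(gene_id)


def _pattern_label(i: int) -> str:
    letters = string.ascii_lowercase
    if i < len(letters):
        return letters[i]
    return f"{letters[i % 26]}{i // 26}"


def assign_pattern(
    catalog: PatternCatalog, gene_id: str, events: Iterable[IntronEvent]
) -> frozenset:
    """Register one gene's mapped introns; returns its site set."""
    return catalog.assign(gene_id, events)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_patterns(
    catalog: PatternCatalog,
    subfamily_assignment: Optional[dict[str, str]] = None,
) -> dict:
    """Pattern-diversity summary.

    Reports the number of patterns, the number of unique (column, phase)
    sites, the minimal site-level insertion-event count under a single-gain
    (Dollo) assumption (equal to the unique-site count), the number of
    non-intronless patterns not derivable by loss from any other pattern
    (pattern-level novel events), the fraction of genes in the three largest
    patterns, and per-subfamily homogeneity (fraction of members sharing the
    subfamily's modal pattern).
    """
    patterns = catalog.finalize()
    all_sites = set()
    for p in patterns:
        all_sites |= p.sites
    n_genes = sum(p.n_members for p in patterns)
    top3 = sorted((p.n_members for p in patterns), reverse=True)[:3]
    novel = [
        p.pattern_id
        for p in patterns
        if p.sites and not p.derivable_by_loss_from
    ]
    summary = dict(
        n_patterns=len(patterns),
        n_unique_sites=len(all_sites),
        site_level_min_insertion_events=len(all_sites),
        pattern_level_novel_events=len(novel),
        novel_pattern_ids=novel,
        top3_gene_fraction=(sum(top3) / n_genes) if n_genes else 0.0,
        n_genes=n_genes,
    )
    if subfamily_assignment is not None:
        gene_pattern = {
            g: p.pattern_id for p in patterns for g in p.members
        }
        by_sf: dict[str, list[str]] = {}
        for g, sf in subfamily_assignment.items():
            if g in gene_pattern:
                by_sf.setdefault(sf, []).append(gene_pattern[g])
        homog = {}
        for sf, pats in by_sf.items():
            modal = max(set(pats), key=pats.count)
            homog[sf] = pats.count(modal) / len(pats)
        summary["subfamily_homogeneity"] = homog
        summary["mean_subfamily_homogeneity"] = (
            sum(homog.values()) / len(homog) if homog else 0.0
        )
    return summary


def patterns_table(catalog: PatternCatalog) -> pd.DataFrame:
    rows = [
        dict(
            pattern_id=p.pattern_id,
            sites=";".join(f"{c}:{ph}" for c, ph in sorted(p.sites)),
            n_genes=p.n_members,
            derivable_from=";".join(p.derivable_by_loss_from),
        )
        for p in catalog.finalize()
    ]
    return pd.DataFrame(
        rows, columns=["pattern_id", "sites", "n_genes", "derivable_from"]
    )
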