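"""Tandem / segmental / dispersed duplication classification.

Tandem: two family members on the same chromosome with at most
``max_intervening`` (default 1) non-family genes between them; links are
chained into maximal clusters, so arrays of three to six members form a
single cluster.  Family members never count as intervening genes.
Segmental: a synteny-block anchor pair whose two genes are both family
members.  Family genes in neither category are dispersed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    species: str
    chromosome: str
    ordinal: int


@dataclass
class SyntenyBlock:
    block_id: str
    anchors: list[tuple[str, str]]


def read_gene_order(path) -> list[GeneLocus]:
    df = pd.read_csv(path, sep="\t")
    return loci_from_frame(df)


def loci_from_frame(df: pd.DataFrame) -> list[GeneLocus]:
    return [
        GeneLocus(r.gene_id, r.species, r.chromosome, int(r.ordinal))
        for r in df.itertuples()
    ]


def read_synteny(path) -> list[SyntenyBlock]:
    df = pd.read_csv(path, sep="\t")
    blocks: dict[str, SyntenyBlock] = {}
    for r in df.itertuples():
        blocks.setdefault(r.block_id, SyntenyBlock(r.block_id, []))
        blocks[r.block_id].anchors.append((r.gene_a, r.gene_b))
    return list(blocks.values())


def find_tandem(
    loci: Iterable[GeneLocus],
    family_ids: Iterable[str],
    max_intervening: int = 1,
) -> list[tuple[str, ...]]:
    """Maximal tandem clusters of family genes.

    Two family members on one chromosome are linked when at most
    ``max_intervening`` non-family genes sit between them; clusters are the
    connected components of the links (size >= 2), each returned as a tuple
    of gene ids sorted by ordinal.
    """
    fam = set(family_ids)
    by_chrom: dict[tuple[str, str], list[GeneLocus]] = {}
    seen: dict[tuple[str, str, int], str] = {}
    for locus in loci:
        key = (locus.species, locus.chromosome, locus.ordinal)
        if key in seen:
            raise ValueError(
                f"duplicate ordinal {locus.ordinal} on {locus.chromosome} "
                f"({seen[key]} vs {locus.gene_id})"
            )
        seen[key] = locus.gene_id
        by_chrom.setdefault((locus.species, locus.chromosome), []).append(locus)

    clusters: list[tuple[str, ...]] = []
    for key in sorted(by_chrom):
        genes = sorted(by_chrom[key], key=lambda l: l.ordinal)
        fam_here = [g for g in genes if g.gene_id in fam]
        current: list[GeneLocus] = []
        for prev, cur in zip([None] + fam_here[:-1], fam_here):
            if prev is not None:
                # intervening non-family genes = ordinal gap minus 1
                intervening = cur.ordinal - prev.ordinal - 1
                if intervening <= max_intervening:
                    if not current:
                        current = [prev]
                    current.append(cur)
                    continue
            if len(current) >= 2:
                clusters.append(tuple(g.gene_id for g in current))
            current = []
        if len(current) >= 2:
            clusters.append(tuple(g.gene_id for g in current))
    return clusters


def find_segmental(
    family_ids: Iterable[str],
    blocks: Iterable[SyntenyBlock],
    known_genes: Optional[set] = None,
) -> list[tuple[str, str, str]]:
    """Segmental pairs: anchors whose both genes are family members.

    Returns (gene_a, gene_b, block_id) triples.  Anchors referencing genes
    outside ``known_genes`` (when given) are skipped with a warning.
    """
    fam = set(family_ids)
    skipped = 0
    out = []
    for block in blocks:
        for ga, gb in block.anchors:
            if known_genes is not None and (
                ga not in known_genes or gb not in known_genes
            ):
                skipped += 1
                continue
            if ga in fam and gb in fam:
                out.append((ga, gb, block.block_id))
    if skipped:
        logger.warning("skipped %d synteny anchors with unknown genes", skipped)
    return out


def duplication_calls(
    loci: Iterable[GeneLocus],
    family_ids: Iterable[str],
    blocks: Iterable[SyntenyBlock],
    max_intervening: int = 1,
) -> pd.DataFrame:
    """Per-gene duplication-mode table (a gene may be tandem and segmental)."""
    loci = list(loci)
    fam = sorted(set(family_ids))
    clusters = find_tandem(loci, fam, max_intervening)
    seg_pairs = find_segmental(fam, blocks, known_genes={l.gene_id for l in loci})
    tandem_genes = {g for c in clusters for g in c}
    seg_genes = {g for a, b, _ in seg_pairs for g in (a, b)}
    sp_of = {l.gene_id: l.species for l in loci}
    rows = []
    for g in fam:
        tandem = g in tandem_genes
        segmental = g in seg_genes
        mode = (
            "tandem+segmental" if tandem and segmental
            else "tandem" if tandem
            else "segmental" if segmental
            else "dispersed"
        )
        rows.append(
            dict(gene_id=g, species=sp_of.get(g, ""), mode=mode,
                 tandem=tandem, segmental=segmental)
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "species", "mode", "tandem", "segmental"]
    )


def duplication_rates(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-species family size, tandem/segmental gene counts and rates.

    The segmental rate is segmental genes / family size, as a percentage.
    Tandem clusters and tandem genes are both reported.
    """
    rows = []
    for sp, sub in calls.groupby("species", sort=True):
        n = len(sub)
        n_tandem = int(sub["tandem"].sum())
        n_seg = int(sub["segmental"].sum())
        rows.append(
            dict(
                species=sp,
                family_size=n,
                tandem_genes=n_tandem,
                segmental_genes=n_seg,
                dispersed_genes=int((sub["mode"] == "dispersed").sum()),
                segmental_rate_pct=(100.0 * n_seg / n) if n else 0.0,
                tandem_rate_pct=(100.0 * n_tandem / n) if n else 0.0,
            )
        )
    cols = ["species", "family_size", "tandem_genes", "segmental_genes",
            "dispersed_genes", "segmental_rate_pct", "tandem_rate_pct"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)
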