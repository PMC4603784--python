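"""End-to-end orchestration: scan -> align -> tree -> introns -> ancestral
counts -> duplication, from one config, with a single JSON report.

Inputs are either files (proteins FASTA, GFF3, species tree, species map,
gene order, synteny) or a simulate block that generates them first.  Every
stage writes its table next to the report so each reported number is
traceable to an intermediate TSV.  Outputs are pure functions of (inputs,
parameters, seed); the bootstrap stage caches on a content hash of its
inputs and parameters because it dominates runtime.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import ancestral_counts, domain_align, duplication, intron_patterns
from . import phylo, repeat_scan, synthetic_data
from ._profiles import REPEAT_LENGTH
from .synthetic_data import DOMAIN_LENGTH, SimulationConfig

logger = logging.getLogger("mybtrace")


@dataclass
class PipelineConfig:
    """Everything one run needs; either ``inputs`` paths or ``simulate``."""

    output_dir: str = "mybtrace_out"
    seed: int = 0
    inputs: Optional[dict] = None          # proteins, gff3, species_tree,
                                           # species_map, gene_order, synteny
    simulate: Optional[SimulationConfig] = None
    bootstrap_reps: int = 200
    min_support: float = 50.0
    min_size: int = 2
    max_gap: int = 20
    max_intervening: int = 1
    threshold_fraction: float = 0.6

    def __post_init__(self):
        if self.inputs is None and self.simulate is None:
            raise ValueError("config needs either an inputs block or a simulate block")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        if sim is not None:
            if "intron_catalog" in sim:
                sim["intron_catalog"] = [
                    frozenset(tuple(site) for site in pat)
                    for pat in sim["intron_catalog"]
                ]
            sim = SimulationConfig(**sim)
        return cls(simulate=sim, **raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers = [logging.StreamHandler(sys.stderr)]
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    logger.addHandler(fh)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order and write the report bundle.

    Returns the report dict (also written as report.json).  Raises
    :class:`StageError` naming the failing stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    t0 = time.time()
    report: dict = {"parameters": _config_dict(config), "seed": config.seed}

    # ---- inputs ----------------------------------------------------------
    stage = "inputs"
    try:
        if config.simulate is not None:
            sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
            truth = synthetic_data.simulate_bundle(sim_cfg, outdir / "inputs")
            paths = {k: outdir / "inputs" / v for k, v in {
                "proteins": "proteins.faa", "gff3": "genes.gff3",
                "species_tree": "species.nwk", "species_map": "species_map.tsv",
                "gene_order": "gene_order.tsv", "synteny": "synteny.tsv",
            }.items()}
        else:
            paths = {k: Path(v) for k, v in config.inputs.items()}
        for key in ("proteins", "species_tree", "species_map"):
            if key not in paths or not Path(paths[key]).exists():
                raise FileNotFoundError(f"required input {key!r} missing")
        proteins = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(paths["proteins"], "fasta")
        }
        species_map = dict(
            pd.read_csv(paths["species_map"], sep="\t").values
        )
        species_tree = synthetic_data.parse_species_tree(
            Path(paths["species_tree"]).read_text()
        )
        logger.info("loaded %d proteins", len(proteins))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- scan ------------------------------------------------------------
    stage = "scan"
    try:
        model = repeat_scan.RepeatModel.from_consensi(
            [repeat_scan.MYB_R2, repeat_scan.MYB_R3,
             repeat_scan.CDC5_R1, repeat_scan.CDC5_R2],
            threshold_fraction=config.threshold_fraction,
        )
        archs = repeat_scan.classify_proteins(
            proteins, model, max_gap=config.max_gap
        )
        accepted, rejected = repeat_scan.filter_candidates(archs)
        repeat_scan.architectures_table(archs).to_csv(
            outdir / "architectures.tsv", sep="\t", index=False
        )
        atypical = sorted(
            pid for pid, a in accepted.items() if a.is_atypical
        )
        typical = sorted(set(accepted) - set(atypical))
        logger.info(
            "scan: %d accepted (%d typical 2R, %d atypical CDC5-like), "
            "%d rejected", len(accepted), len(typical), len(atypical),
            len(rejected),
        )
        if len(typical) < 4:
            raise ValueError("fewer than 4 typical 2R candidates; cannot build a tree")
        family_sizes = (
            pd.Series({p: species_map.get(p) for p in typical})
            .value_counts().sort_index()
        )
        report["family"] = {
            "n_candidates": len(accepted),
            "n_typical": len(typical),
            "n_atypical_cdc5": len(atypical),
            "n_rejected": len(rejected),
            "family_size_per_species": {
                str(k): int(v) for k, v in family_sizes.items()
            },
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- align -----------------------------------------------------------
    stage = "align"
    try:
        aln = domain_align.alignment_from_architectures(proteins, accepted)
        domain_align.export_alignment(aln, outdir / "alignment.fasta")
        dist = domain_align.p_distance(aln, "pairwise")
        dist.as_dataframe().to_csv(outdir / "distances.tsv", sep="\t")
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- phylo -----------------------------------------------------------
    stage = "phylo"
    try:
        cache_key = _phylo_cache_key(aln, config)
        cached = _load_cached_tree(outdir, cache_key)
        if cached is not None:
            tree = cached
            logger.info("phylo: reusing cached bootstrap tree")
        else:
            tree = phylo.bootstrap_support(
                aln, n_reps=config.bootstrap_reps, seed=config.seed
            )
            _store_cached_tree(outdir, cache_key, tree)
        rooted = phylo.root_on_outgroup(tree, atypical) if atypical else tree
        rooted.write(path=outdir / "tree.nwk", schema="newick")
        assignment = phylo.call_subfamilies(
            rooted,
            min_support=config.min_support,
            min_size=config.min_size,
            outgroup_ids=atypical,
        )
        assignment.as_dataframe().to_csv(
            outdir / "subfamilies.tsv", sep="\t", index=False
        )
        report["subfamilies"] = {
            "n_subfamilies": assignment.n_subfamilies,
            "n_orphans": len(assignment.orphans),
            "sizes": {
                s: m["size"] for s, m in assignment.subfamilies.items()
            },
            "note": (
                "automatic maximal-supported-clade delimitation "
                f"(support >= {config.min_support}, size >= {config.min_size})"
            ),
        }
        logger.info(
            "phylo: %d subfamilies, %d orphans",
            assignment.n_subfamilies, len(assignment.orphans),
        )
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- introns ---------------------------------------------------------
    stage = "introns"
    try:
        if "gff3" not in paths or not Path(paths["gff3"]).exists():
            raise FileNotFoundError("GFF3 input missing for the intron stage")
        models = intron_patterns.read_gene_models(paths["gff3"])
        catalog = intron_patterns.PatternCatalog()
        event_rows = []
        for pid in typical:
            arch = accepted[pid]
            span = (arch.chain[0].start, arch.chain[1].end)
            colmap = aln.position_to_column(pid)
            gm = models.get(pid)
            events = (
                intron_patterns.map_introns(gm, span, colmap) if gm else []
            )
            catalog.assign(pid, events)
            for e in events:
                event_rows.append(
                    dict(gene_id=pid, column=e.column, phase=e.phase,
                         protein_position=e.protein_position)
                )
        pd.DataFrame(
            event_rows,
            columns=["gene_id", "column", "phase", "protein_position"],
        ).to_csv(outdir / "intron_events.tsv", sep="\t", index=False)
        intron_patterns.patterns_table(catalog).to_csv(
            outdir / "patterns.tsv", sep="\t", index=False
        )
        summary = intron_patterns.summarize_patterns(
            catalog, assignment.assignment
        )
        report["intron_patterns"] = summary
        logger.info(
            "introns: %d patterns over %d unique sites",
            summary["n_patterns"], summary["n_unique_sites"],
        )
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- ancestral counts ------------------------------------------------
    stage = "mrca"
    try:
        presence = ancestral_counts.build_presence_matrix(
            assignment, species_map
        )
        profile = ancestral_counts.mrca_profile(presence, species_tree)
        profile.to_csv(outdir / "mrca_profile.tsv", sep="\t", index=False)
        report["mrca"] = {
            "profile": profile[["node", "min", "max"]].to_dict("records"),
            "n_orphans_excluded": presence.n_orphans,
        }
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- duplication -----------------------------------------------------
    stage = "duplication"
    try:
        if "gene_order" in paths and Path(paths["gene_order"]).exists():
            loci = duplication.read_gene_order(paths["gene_order"])
        else:
            raise FileNotFoundError("gene_order input missing")
        blocks = (
            duplication.read_synteny(paths["synteny"])
            if "synteny" in paths and Path(paths["synteny"]).exists()
            else []
        )
        calls = duplication.duplication_calls(
            loci, typical, blocks, max_intervening=config.max_intervening
        )
        calls.to_csv(outdir / "duplications.tsv", sep="\t", index=False)
        rates = duplication.duplication_rates(calls)
        rates.to_csv(outdir / "rates.tsv", sep="\t", index=False)
        clusters = duplication.find_tandem(
            loci, typical, config.max_intervening
        )
        report["duplication"] = {
            "n_tandem_clusters": len(clusters),
            "rates": rates.to_dict("records"),
        }
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    report["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "report.json").write_text(_dump_report(report))
    (outdir / "config_echo.json").write_text(
        json.dumps(_config_dict(config), indent=2, default=str)
    )
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return report


def _dump_report(report: dict) -> str:
    stable = {k: v for k, v in report.items() if k not in ("timestamp",)}
    out = dict(stable)
    out["timestamp"] = report.get("timestamp")
    return json.dumps(out, indent=2, sort_keys=False, default=str)


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("simulate") and d["simulate"].get("intron_catalog") is not None:
        d["simulate"]["intron_catalog"] = [
            sorted(p) for p in d["simulate"]["intron_catalog"]
        ]
    return d


def _phylo_cache_key(aln, config: PipelineConfig) -> str:
    h = hashlib.sha256()
    h.update(aln.to_fasta().encode())
    h.update(f"{config.bootstrap_reps}|{config.seed}".encode())
    return h.hexdigest()


def _load_cached_tree(outdir: Path, key: str):
    import dendropy

    keyfile = outdir / "cache" / "phylo.key"
    treefile = outdir / "cache" / "phylo.tree.json"
    if not (keyfile.exists() and treefile.exists()):
        return None
    if keyfile.read_text().strip() != key:
        return None
    payload = json.loads(treefile.read_text())
    tree = dendropy.Tree.get(data=payload["newick"], schema="newick",
                             suppress_internal_node_taxa=True)
    supports = {
        frozenset(s): v for s, v in payload["supports"]
    }
    tree.split_supports = supports
    phylo.annotate_supports(tree, supports)
    tree.is_rooted = False
    return tree


def _store_cached_tree(outdir: Path, key: str, tree) -> None:
    cdir = outdir / "cache"
    cdir.mkdir(exist_ok=True)
    payload = {
        "newick": tree.as_string(schema="newick"),
        "supports": [
            [sorted(s), v] for s, v in getattr(tree, "split_supports", {}).items()
        ],
    }
    (cdir / "phylo.tree.json").write_text(json.dumps(payload))
    (cdir / "phylo.key").write_text(key)
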