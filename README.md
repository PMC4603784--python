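# mybtrace

Desk-scale evolutionary analysis of **R2R3-MYB (2R-MYB) gene families** —
the largest transcription-factor family of land plants — for researchers who
want the full analysis chain of a gene-family study as reproducible,
testable code rather than a one-off collection of web tools and manual
curation steps.

The package covers:

1. **Repeat scanning** — detect ~53-aa MYB repeats with a positional profile
   and classify each protein's domain architecture (1R/2R/3R/4R). A repeat is
   accepted when it scores ≥ 60% of the profile self-score and keeps at
   least **2 of the 3 conserved tryptophan (W) anchors**; repeats must be
   adjacent (gap ≤ 20 aa) to count toward the architecture. Two-repeat
   proteins matching the CDC5 signature better than the c-MYB profile are
   flagged *atypical* and serve as the phylogenetic out-group.
2. **Domain alignment & distances** — anchor-pinned alignment of R2R3
   domains and p-distances
   (d<sub>ij</sub> = mismatches / shared ungapped sites) with pairwise or
   complete deletion. External MSAs (FASTA/Clustal) can be imported instead.
3. **Phylogeny** — Saitou–Nei neighbor joining with bootstrap supports
   (column resampling), rooting on the atypical out-group, and subfamily
   delimitation as maximal supported clades (support ≥ 50, size ≥ 2, stem
   length ≥ 0.05); unassigned genes become orphans.
4. **Intron patterns** — map each intron to the **(domain alignment column,
   phase)** of its codon (phase 0 = between codons, 1/2 = after the first /
   second base) and group genes with identical site sets into patterns
   a, b, c, …; loss-derivability between patterns is computed as strict
   subset structure.
5. **Ancestral family sizes** — minimum and maximum gene counts at each
   species-tree node from subfamily presence: *min* counts subfamilies
   spanning ≥ 2 child subtrees (their MRCA proves an ancestral copy), *max*
   counts subfamilies present anywhere in the clade.
6. **Duplication modes** — tandem arrays (family members with ≤ 1
   intervening gene, chained into clusters), segmental pairs (family genes
   anchored in the same synteny block), dispersed otherwise, with
   per-species rates.
7. **Synthetic data** — a birth–death simulator over a species tree with
   known ground truth (subfamily membership, per-node lineage counts,
   planted intron sites, realized tandem/segmental events), so every stage
   is benchmarked without downloading genomes.

## Worked example

```bash
mybtrace simulate --out demo_inputs --seed 7   # optional stage-wise use
```

or run everything from one config:

```python
from mybtrace import SimulationConfig
from mybtrace.pipeline import PipelineConfig, run_all

report = run_all(PipelineConfig(
    output_dir="demo_run",
    seed=7,
    simulate=SimulationConfig(n_ancestral_subfamilies=10),
    bootstrap_reps=200,
))
```

which logs

```
loaded 103 proteins
scan: 91 accepted (83 typical 2R, 8 atypical CDC5-like), 12 rejected
phylo: 10 subfamilies, 0 orphans
introns: 10 patterns over 14 unique sites
```

and writes `report.json` containing (abridged):

```json
"subfamilies": {"n_subfamilies": 10, "n_orphans": 0},
"intron_patterns": {"n_patterns": 10, "n_unique_sites": 14,
                    "mean_subfamily_homogeneity": 1.0},
"mrca": {"profile": [{"node": "root", "min": 9, "max": 10},
                     {"node": "n2",   "min": 8, "max": 10}, "..."]}
```

Reading: of 103 simulated proteins, 91 pass the repeat criteria (83 typical
2R-MYBs, 8 CDC5-like used as out-group; the rejects are decoys and a few
heavily diverged repeats). All ten planted subfamilies are recovered as
supported clades with no orphans, each subfamily is perfectly homogeneous in
its intron pattern, and the root of the species tree is inferred to have
carried between 9 and 10 family lineages (the simulation's true count is
recorded in `demo_run/inputs/truth/node_counts.tsv`). Every number in the
report is traceable to an intermediate TSV
(`architectures.tsv`, `subfamilies.tsv`, `patterns.tsv`,
`mrca_profile.tsv`, `rates.tsv`, …) in the output directory.

## Layout

```
src/mybtrace/
  synthetic_data.py   # birth-death simulator, sequence/GFF3/layout emission
  repeat_scan.py      # profile scanning, architecture classes, filtering
  domain_align.py     # anchor-pinned alignment, p-distance, MSA import
  phylo.py            # NJ, bootstrap, out-group rooting, subfamily calling
  intron_patterns.py  # intron mapping, pattern registry, summaries
  ancestral_counts.py # presence matrix, min/max ancestral profiles
  duplication.py      # tandem/segmental/dispersed calls and rates
  pipeline.py         # orchestration, report.json, caching, logging
  cli.py              # `mybtrace` subcommands
docs/methods.md       # model assumptions, parameters, design choices
```
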