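# pavkit

Gene presence/absence variation (PAV) analysis for pan-genomes built
with the map-to-pan strategy, as used in livestock resequencing studies
of goats and their wild relatives. The package covers the downstream
half of such a study — everything after reads have been mapped and
per-base depth has been computed:

* **Presence calling** from coverage breadth: a gene is *absent* in an
  individual when fewer than 5% of the exonic bases of its gene body
  (the longest transcript) are covered by ≥2 reads, and *present*
  otherwise; individuals below 10× mean depth are excluded first.
* **Pan-genome classification** of genes by presence frequency *f*
  across the cohort: core (*f* = 100%), softcore (99% < *f* < 100%),
  shell (1% ≤ *f* ≤ 99%) and cloud (*f* < 1%); softcore + shell + cloud
  form the dispensable genome. Boundary genes are classified with exact
  rational arithmetic.
* **Rarefaction / openness modeling**: pan and core gene counts are
  traced over 200 random cohort orderings for every sample size
  *n* = 1…N, and the mean pan curve is fit with a bounded-exponential
  saturation model P(n) = A − B·e^(−n/τ) whose asymptote A estimates the
  total pan-genome size, alongside a Heaps power law P(n) = D·n^γ whose
  exponent γ > 0.02 flags an open pan-genome.
* **Selection scan**: per-gene 2×2 presence tables between a reference
  population (e.g. wild Bezoar) and a derived population (native or
  improved goats), tested with two-sided Fisher's exact tests at raw
  P < 0.005; significant genes are *favorable* (higher derived
  frequency) or *unfavorable* (lower — gene loss under domestication).
* **Nonreference contig curation** for map-to-pan assembly: retain
  contigs >500 bp, drop reference-redundant contigs (identity ≥90% and
  coverage ≥80%) and self-redundant contigs (identity ≥90% and coverage
  ≥90%, shorter copy removed).

A synthetic-data generator (`pavkit.synthetic_data`) produces gene
models, presence matrices, depth tracks, gene pools and contig/alignment
fixtures with known ground truth, so the whole pipeline is testable
without sequencing data.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study.
`python analysis/01_simulate_cohort.py` simulates 50 genes × 60
individuals (20 wild / 20 native / 20 improved, 20× depth) and
`python analysis/02_call_presence.py` calls presence from the depth
tracks:

```
retained 60 / 60 individuals at >=10x
called 50 genes x 60 individuals
agreement with ground truth: 100.00% of cells
```

`python analysis/03_classify_genes.py` classifies the called matrix —
with 60 individuals, 39 of the 50 genes are core (78.00%), 9 shell,
2 cloud, 11 dispensable in total — and compares per-individual gene
counts between classes with Mann–Whitney U tests.
`python analysis/04_rarefaction.py` contrasts a closed pool (flat
curves, A = 100.0, verdict `closed`) with an open pool of 384 realized
genes over 100 individuals (A = 384.0, γ = 0.088, verdict `open`).
`python analysis/05_selection_scan.py` plants 10 favorable and 10
unfavorable genes among 500 neutral ones in a Bezoar (n=24) vs native
(n=121) cohort and recovers all 20 with zero false positives at
P < 0.005. `python analysis/06_filter_contigs.py` curates a 200-contig
fixture and matches the planned keep/drop oracle on every contig.

As a library:

```python
from pavkit import presence_caller as pc, io_formats as iof

models = iof.read_gene_models("results/sim/gene_models.bed", "bed12")
bodies = [pc.select_gene_body(m) for m in models]
track = iof.read_depth("scratch/sim/depth/Native_000.depth.tsv", "Native_000")
print(pc.exon_breadth(track, bodies[0], min_depth=2))  # e.g. 1.0 -> present
```

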