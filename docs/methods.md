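# Methods

## Presence/absence calling from coverage breadth

The unit of analysis is the **gene body**: the exon set of a gene's
longest transcript, where length is total exonic length and ties go to
the lexicographically smallest transcript id. Overlapping or
book-ended exons are unioned so no base is counted twice. For each
(gene, individual) pair the caller computes the **breadth**
b = (exonic bases with depth ≥ 2) / (exonic length) and calls the gene
absent iff b < 0.05. Both thresholds are configurable
(`CallerConfig`); the absence inequality is strict, so b = 0.05 is a
presence call. "Covered by two reads" is interpreted as per-base depth
≥ 2 — depth is the only information in the declared input (a
samtools-depth TSV), so read-pair identity cannot enter the rule.

Depth files follow the samtools-depth dialect: three columns (chrom,
1-based position, depth) with zero-depth rows omitted; the reader
converts to the package-wide 0-based half-open convention at the file
boundary and treats unlisted positions as depth 0. Individuals are
retained only if their genome-wide mean depth — summed depth divided by
a caller-supplied total reference length, not merely the covered
positions — is at least 10×. The denominator is explicit because the
meaning of "average sequencing depth" depends on it; callers of the
library must state which reference length they normalise by.

Whether duplicate reads or low-MAPQ alignments contribute to depth is
the responsibility of whatever produced the depth file; the caller is
agnostic.

## Pan-genome categories

Presence frequency is kept as an exact rational n_present/n_total;
category boundaries are evaluated by integer cross-multiplication
(e.g. softcore iff 100·k > 99·n and k < n), so a cohort of 277 splits
exactly at counts {277} core, {275, 276} softcore, {3…274} shell and
{0, 1, 2} cloud. Shell is inclusive on both ends (1% ≤ f ≤ 99%) and
softcore is the open interval (99%, 100%), making the four categories a
partition. Genes present in no retained individual are cloud by the
letter of the rule but carry a `flagged_zero_presence` marker, since a
gene observed nowhere usually indicates an annotation or calling
problem rather than a rare gene. Displayed percentages round half-up
to two decimals; all comparisons happen before rounding.

Per-individual gene counts (column sums of the presence matrix) are
compared between population classes with a two-sided Mann–Whitney U
test: the exact null distribution when n_a·n_b ≤ 400 with no ties,
otherwise the normal approximation with tie and continuity corrections
(delegated to `scipy.stats.mannwhitneyu`).

## Rarefaction and openness

`rarefy` draws, per iteration, one random permutation of the cohort and
reads pan (union) and core (intersection) gene counts off its prefixes,
for every sample size n = 1…N at 200 iterations by default. Each
(n, iteration) cell is a uniform without-replacement sample of n
individuals, and the nested design makes pan non-decreasing and core
non-increasing within every iteration — so the mean curves are monotone
by construction rather than only in expectation, matching what
accumulation curves are meant to show. A `stride` option thins the
grid of sample sizes for very large cohorts; it defaults off.

The mean pan curve is fit by nonlinear least squares to the bounded
exponential P(n) = A − B·e^(−n/τ) with A constrained to at least the
observed maximum, B ≥ 0 and τ > 0. This form is chosen because the
quantity of interest is a finite estimated total pan-genome size, which
a pure power law cannot provide. A Heaps power law P(n) = D·n^γ is fit
alongside on n ≥ 2 by log–log regression, and the pool is called
**open** when the observed curve is still below 99% of the fitted
asymptote at n = N or γ > 0.02 — the conventional Heaps-style openness
criterion. A perfectly flat curve short-circuits to A = observed,
B = 0, τ = 1 (the model is exact there and τ is unidentifiable).
Fit failure is reported in the returned object (`converged=False` with
diagnostics), never silently replaced. The fit uses per-n means,
unweighted; per-n SDs are reported for inspection.

## Selection scan

For each gene, presence counts in the reference and derived populations
form a 2×2 table tested with a two-sided Fisher's exact test under the
probability-mass convention (the two-sided P sums hypergeometric
probabilities of all tables with the observed margins whose point
probability does not exceed the observed one). Conventions for
two-sided Fisher tests differ; this is the dominant one and the one the
tests pin against rational enumeration. The significance flag uses raw
P < 0.005 with no multiple-testing correction; Benjamini–Hochberg
q-values are emitted as a transparency column only. Significant genes
are labeled favorable/unfavorable by exact integer comparison of
frequencies (k_der·n_ref vs k_ref·n_der); equal frequencies get
direction "none", though such a gene cannot in practice reach
significance.

## Nonreference contig curation

Three filters compose in a fixed order, and the report records the
first reason each contig was dropped: (1) length — retained iff
strictly longer than 500 bp; (2) reference redundancy — excluded iff
identity ≥ 0.90 **and** coverage ≥ 0.80, both inclusive; (3) self
redundancy — at identity ≥ 0.90 and coverage ≥ 0.90 of the shorter
contig, the shorter of a pair is removed. At the multi-alignment
level, a contig's coverage is the fraction of its bases inside the
union of its aligned query intervals, and its identity the
block-length-weighted mean of matches/block_len: both definitions are
deterministic and independent of record order. For self-redundancy,
contigs are processed in decreasing length (ties keep the
lexicographically smaller id), and a contig is only removed for
redundancy against a *surviving* contig, which resolves removal
cascades deterministically. Contamination screening against external
sequence databases is out of scope; an externally produced exclusion
list can be passed instead.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the pipeline
assumes, not sequencing physics:

* **Frequency spectrum** — per gene and population, drawn from a
  mixture of fixed (78%), nearly fixed (8%, 0.97–0.999), intermediate
  (10%, uniform 0.1–0.9 independently per population, creating
  between-population differences) and rare (4%, <0.03) genes, or
  supplied explicitly as an (n_genes × n_populations) array. The
  default cohort is 50 genes × 60 individuals in three classes (wild,
  native, improved), 20 each — large enough to exercise every category
  and small enough to run in seconds.
* **Depth** — per-base Poisson(mean_depth, default 20×) over the gene's
  exon union for present genes; absent genes get a contiguous block of
  depth 2 spanning floor(residual_breadth × exonic length) bases
  (default 2%) at the start of the gene body. The contiguous block is
  the simplest adversarial layout for a breadth computation; no read
  lengths, mapping errors, GC bias or mappability structure are
  modeled. At the default 20× the probability that an exonic base of a
  present gene falls below depth 2 is ~4×10⁻⁸, so generated breadths
  never enter the ambiguous band [residual_breadth, 0.95) and ground
  truth is unambiguous. With mean depth below ~8× that separation
  guarantee degrades, which is exactly the regime the 10× individual
  filter exists to exclude.
* **Gene pools** — the closed pool gives every individual an identical
  gene set; the open pool introduces Poisson(novelty_rate) new
  dispensable genes with each successive individual, each carried by
  every later individual independently with probability 0.5. The
  open pool has no closed-form asymptote parameter; the recovery tests
  therefore compare the fitted asymptote against the realized number of
  distinct genes in the matrix, which the accumulation curve attains at
  n = N.
* **Contigs** — sequences are random nucleotides; the PAF records
  realize *planned* identity/coverage values rather than being
  recomputed from the sequences (draws keep a margin away from the
  0.90/0.80/0.90 thresholds so integer rounding of matches and
  endpoints cannot flip a planned label, and boundary cases are pinned
  to round lengths where the ratios are exact).

Passing tests on these data show that the implementation applies its
rules exactly and recovers known structure; they do not show robustness
to alignment artifacts, CNV-induced intermediate breadths, or reference
bias in real resequencing data.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen to finish in
seconds while keeping every boundary case observable: 50×60 for
end-to-end recovery, N = 100 individuals × 200 iterations for
rarefaction, 1,000 genes × 5–10 replicates for the null false-positive
rate of the scan (n = 24 vs 121, mirroring the Bezoar-vs-native
comparison), 200 contigs for curation. Determinism is enforced
throughout: every stochastic routine takes an explicit seed, streams
are derived via `numpy.random.SeedSequence`, and identical seeds
reproduce output files byte for byte.

Known limitations: the caller is strictly binary (no CNV dosage or
partial-loss calls); per-exon PAV is out of scope; the saturation model
is a single exponential and will underestimate the asymptote of
mixtures with very slow accumulation components; and the self-redundancy
rule assumes the aligner reports both orientations of each contig pair,
as all-vs-all aligners typically do.
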