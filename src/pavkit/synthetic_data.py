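"""Synthetic cohorts with known ground truth for the PAV pipeline.

Every downstream stage (presence calling, classification, rarefaction,
selection scan, contig curation) is exercised against data generated
here, where the truth is known by construction:

* gene models on one synthetic chromosome, with multi-transcript genes
  to exercise longest-transcript selection;
* a presence matrix drawn from per-population gene frequencies covering
  fixed, nearly-fixed, intermediate and rare genes;
* per-base depth tracks in the samtools-depth dialect (zero rows
  omitted): present genes get Poisson per-base depth, absent genes a
  contiguous low-level residual block kept strictly below the 5%
  absence-call threshold, so breadths never land in the ambiguous band;
* closed/open gene pools with known totals for rarefaction tests;
* contig FASTA + PAF fixtures realizing planned identity/coverage
  values, with a per-contig keep/drop oracle.

All generators are deterministic: the same seed reproduces the same
files byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignmentRecord, GeneModel, PopulationMap, Transcript, write_bed12
from .presence_caller import _union_intervals

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ContigFixture",
    "default_frequency_spectrum",
    "simulate_gene_models",
    "simulate_presence",
    "simulate_depth",
    "simulate_gene_pools",
    "simulate_contigs_and_alignments",
]

CHROM = "chrS1"


class ConfigurationError(ValueError):
    """A simulation parameter is outside its valid range."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    mean_depth is the expected per-base depth (x) over present genes;
    absent_residual_breadth is the fraction of an absent gene's exonic
    bases that still receive depth >= 2 (background noise), and must stay
    below the 0.05 calling threshold so truth is unambiguous.
    """

    n_genes: int = 50
    n_individuals_per_population: Mapping[str, int] = field(
        default_factory=lambda: {"Bezoar": 20, "Native": 20, "Dairy": 20}
    )
    population_classes: Mapping[str, str] = field(
        default_factory=lambda: {"Bezoar": "wild", "Native": "native", "Dairy": "improved"}
    )
    frequency_spectrum: np.ndarray | None = None  # (n_genes, n_populations)
    mean_depth: float = 20.0
    absent_residual_breadth: float = 0.02
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (100, 300)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        for pop, n in self.n_individuals_per_population.items():
            if n < 0:
                raise ConfigurationError(f"n_individuals_per_population[{pop!r}] must be >= 0")
            if pop not in self.population_classes:
                raise ConfigurationError(f"population_classes missing entry for {pop!r}")
        if self.mean_depth < 0:
            raise ConfigurationError("mean_depth must be >= 0")
        if not 0 <= self.absent_residual_breadth < 0.05:
            raise ConfigurationError(
                "absent_residual_breadth must lie in [0, 0.05) to stay below "
                "the absence-call threshold"
            )
        for name, (lo, hi) in (
            ("exons_per_gene", self.exons_per_gene),
            ("exon_length", self.exon_length),
        ):
            if lo < 1 or hi < lo:
                raise ConfigurationError(f"{name} range ({lo}, {hi}) is invalid")
        if self.frequency_spectrum is not None:
            spec = np.asarray(self.frequency_spectrum, dtype=float)
            if spec.shape != (self.n_genes, len(self.n_individuals_per_population)):
                raise ConfigurationError(
                    "frequency_spectrum must have shape (n_genes, n_populations)"
                )
            if np.any((spec < 0) | (spec > 1)):
                raise ConfigurationError("frequency_spectrum values must lie in [0, 1]")

    @property
    def populations(self) -> list[str]:
        return list(self.n_individuals_per_population)

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    def individual_ids(self) -> list[str]:
        out = []
        for pop, n in self.n_individuals_per_population.items():
            out.extend(f"{pop}_{i:03d}" for i in range(n))
        return out


@dataclass
class GroundTruth:
    """The generated presence matrix (genes x individuals) plus labels."""

    presence: pd.DataFrame
    population_map: PopulationMap


def default_frequency_spectrum(config: SimulationConfig) -> np.ndarray:
    """Canonical per-gene, per-population presence frequencies.

    Mixture: ~78% of genes fixed everywhere, ~8% nearly fixed
    (0.97-0.999), ~10% intermediate (0.1-0.9, drawn independently per
    population so populations differ), ~4% rare (< 0.03).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n_pops = len(config.populations)
    spectrum = np.empty((config.n_genes, n_pops))
    kinds = rng.choice(4, size=config.n_genes, p=[0.78, 0.08, 0.10, 0.04])
    for i, kind in enumerate(kinds):
        if kind == 0:
            spectrum[i] = 1.0
        elif kind == 1:
            spectrum[i] = rng.uniform(0.97, 0.999, size=n_pops)
        elif kind == 2:
            spectrum[i] = rng.uniform(0.10, 0.90, size=n_pops)
        else:
            spectrum[i] = rng.uniform(0.0, 0.03, size=n_pops)
    return spectrum


def simulate_gene_models(config: SimulationConfig) -> tuple[list[GeneModel], str]:
    """Non-overlapping gene models on one synthetic chromosome.

    The first gene (and a random ~30% of the rest) carries a second,
    strictly shorter transcript so longest-transcript selection has an
    unambiguous oracle.  Returns the models and their BED12 text.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    exon_lo, exon_hi = config.exons_per_gene
    len_lo, len_hi = config.exon_length
    models: list[GeneModel] = []
    cursor = 1000
    for i in range(config.n_genes):
        gid = f"g{i:04d}"
        n_exons = int(rng.integers(exon_lo, exon_hi + 1))
        sizes = rng.integers(len_lo, len_hi + 1, size=n_exons)
        gaps = rng.integers(50, 501, size=max(n_exons - 1, 0))
        exons = []
        pos = cursor
        for j, size in enumerate(sizes):
            exons.append((pos, pos + int(size)))
            pos += int(size) + (int(gaps[j]) if j < len(gaps) else 0)
        transcripts = [Transcript(f"{gid}.t1", tuple(exons))]
        want_alt = i == 0 or rng.random() < 0.3
        if want_alt:
            if n_exons >= 2:
                alt_exons = tuple(exons[:-1])  # drop the last exon: strictly shorter
            else:
                start, end = exons[0]
                alt_len = max((end - start) * 3 // 5, 1)
                alt_exons = ((start, start + alt_len),)
            transcripts.append(Transcript(f"{gid}.t2", alt_exons))
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(GeneModel(gid, CHROM, strand, tuple(transcripts)))
        cursor = exons[-1][1] + int(rng.integers(200, 1001))
    return models, write_bed12(models)


def simulate_presence(config: SimulationConfig) -> GroundTruth:
    """Independent Bernoulli presence draws at each gene's population frequency."""
    spectrum = (
        np.asarray(config.frequency_spectrum, dtype=float)
        if config.frequency_spectrum is not None
        else default_frequency_spectrum(config)
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    popmap = PopulationMap()
    columns: dict[str, np.ndarray] = {}
    for p_idx, (pop, n) in enumerate(config.n_individuals_per_population.items()):
        cls = config.population_classes[pop]
        freqs = spectrum[:, p_idx]
        for i in range(n):
            ind = f"{pop}_{i:03d}"
            popmap.add(ind, pop, cls)
            columns[ind] = rng.random(config.n_genes) < freqs
    presence = pd.DataFrame(columns, index=config.gene_ids(), dtype=bool)
    return GroundTruth(presence=presence, population_map=popmap)


def _gene_exon_union(model: GeneModel) -> tuple[tuple[int, int], ...]:
    intervals = [iv for tx in model.transcripts for iv in tx.exons]
    return _union_intervals(intervals)


def simulate_depth(
    truth: GroundTruth,
    models: Sequence[GeneModel],
    config: SimulationConfig,
    out_dir,
) -> dict[str, Path]:
    """One samtools-depth TSV per individual; zero-depth rows omitted.

    Present genes receive per-base Poisson(mean_depth) over the gene's
    exon union; absent genes a contiguous block of depth 2 spanning
    ``floor(absent_residual_breadth * exonic_length)`` bases at the start
    of the gene body — the simplest adversarial layout for the breadth
    computation.
    """
    model_ids = [m.gene_id for m in models]
    if sorted(model_ids) != sorted(truth.presence.index):
        raise ValueError("gene ids in ground truth and gene models differ")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 19]))

    exonic_positions = {}  # gene -> 0-based positions over the exon union
    for model in models:
        union = _gene_exon_union(model)
        exonic_positions[model.gene_id] = np.concatenate(
            [np.arange(s, e, dtype=np.int64) for s, e in union]
        )

    paths: dict[str, Path] = {}
    for individual in truth.presence.columns:
        pos_chunks, depth_chunks = [], []
        present = truth.presence[individual]
        for model in models:  # models are in coordinate order
            positions = exonic_positions[model.gene_id]
            if present[model.gene_id]:
                depths = rng.poisson(config.mean_depth, size=positions.size)
            else:
                depths = np.zeros(positions.size, dtype=np.int64)
                block = int(config.absent_residual_breadth * positions.size)
                depths[:block] = 2
            nz = depths > 0
            pos_chunks.append(positions[nz])
            depth_chunks.append(depths[nz])
        path = out_dir / f"{individual}.depth.tsv"
        if pos_chunks:
            table = pd.DataFrame(
                {
                    "chrom": CHROM,
                    "pos": np.concatenate(pos_chunks) + 1,  # 1-based on disk
                    "depth": np.concatenate(depth_chunks),
                }
            )
        else:
            table = pd.DataFrame(columns=["chrom", "pos", "depth"])
        table.to_csv(path, sep="\t", header=False, index=False)
        paths[individual] = path
    return paths


def simulate_gene_pools(
    core_size: int,
    pool_model: str,
    novelty_rate: float = 0.0,
    n_individuals: int = 30,
    seed: int = 0,
    carry_prob: float = 0.5,
) -> pd.DataFrame:
    """Presence matrix of a closed or open gene pool for rarefaction tests.

    closed: every individual carries exactly the ``core_size`` core genes.
    open: additionally, individual i introduces Poisson(novelty_rate)
    new dispensable genes, each carried by every later individual
    independently with probability ``carry_prob``.
    """
    if core_size < 0:
        raise ConfigurationError("core_size must be >= 0")
    if novelty_rate < 0:
        raise ConfigurationError("novelty_rate must be >= 0")
    if not 0 <= carry_prob <= 1:
        raise ConfigurationError("carry_prob must lie in [0, 1]")
    if pool_model not in ("closed", "open"):
        raise ConfigurationError(f"unknown pool_model {pool_model!r}")
    if n_individuals < 1:
        raise ConfigurationError("n_individuals must be >= 1")
    individuals = [f"ind{i:03d}" for i in range(n_individuals)]
    rows: list[np.ndarray] = [np.ones(n_individuals, dtype=bool)] * core_size
    gene_ids = [f"core{i:04d}" for i in range(core_size)]
    if pool_model == "open":
        rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
        disp = 0
        for i in range(n_individuals):
            for _ in range(int(rng.poisson(novelty_rate))):
                row = np.zeros(n_individuals, dtype=bool)
                row[i] = True
                if i + 1 < n_individuals:
                    row[i + 1 :] = rng.random(n_individuals - i - 1) < carry_prob
                rows.append(row)
                gene_ids.append(f"disp{disp:05d}")
                disp += 1
    matrix = (
        np.vstack(rows) if rows else np.zeros((0, n_individuals), dtype=bool)
    )
    return pd.DataFrame(matrix, index=gene_ids, columns=individuals, dtype=bool)


# ---------------------------------------------------------------------------
# Contig / alignment fixtures
# ---------------------------------------------------------------------------

@dataclass
class ContigFixture:
    sequences: dict[str, str]
    lengths: dict[str, int]
    ref_paf: list[AlignmentRecord]
    self_paf: list[AlignmentRecord]
    oracle: pd.DataFrame  # contig_id -> category, keep, reason


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _ref_alignment(cid: str, length: int, identity: float, coverage: float) -> AlignmentRecord:
    qend = int(round(coverage * length))
    block = qend
    matches = int(round(identity * block))
    return AlignmentRecord(
        query_id=cid, query_len=length, query_start=0, query_end=qend,
        strand="+", target_id="ref_chr1", target_len=10_000_000,
        target_start=1000, target_end=1000 + block, matches=matches, block_len=block,
    )


def simulate_contigs_and_alignments(
    n_contigs: int = 200,
    redundancy_plan: Mapping[str, int] | None = None,
    seed: int = 0,
) -> ContigFixture:
    """FASTA + PAF fixtures spanning every contig-filter boundary case.

    The plan allots contigs to categories {short, reference_redundant,
    self_redundant, clean}; deterministic boundary contigs are placed
    first (length exactly 500 and 501; identity/coverage exactly at the
    0.90/0.80 reference rule and the 0.90/0.90 self rule; an identical
    twin pair of equal length).  The oracle records the planned
    keep/drop label and reason for every contig.
    """
    if n_contigs < 8:
        raise ConfigurationError("n_contigs must be >= 8 to cover the boundary cases")
    if redundancy_plan is None:
        n_short = n_contigs // 5
        n_ref = n_contigs // 4
        n_self = n_contigs // 4
        redundancy_plan = {
            "short": n_short,
            "reference_redundant": n_ref,
            "self_redundant": n_self,
            "clean": n_contigs - n_short - n_ref - n_self,
        }
    for cat, count in redundancy_plan.items():
        if cat not in ("short", "reference_redundant", "self_redundant", "clean"):
            raise ConfigurationError(f"unknown plan category {cat!r}")
        if count < 0:
            raise ConfigurationError(f"plan count for {cat!r} must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))

    sequences: dict[str, str] = {}
    lengths: dict[str, int] = {}
    ref_paf: list[AlignmentRecord] = []
    self_paf: list[AlignmentRecord] = []
    oracle_rows: list[dict] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"ctg{counter:04d}"

    def add_contig(cid: str, length: int, category: str, keep: bool, reason: str,
                   sequence: str | None = None) -> None:
        sequences[cid] = sequence if sequence is not None else _random_seq(rng, length)
        lengths[cid] = length
        oracle_rows.append(
            {"contig_id": cid, "category": category, "keep": keep, "reason": reason}
        )

    # short contigs (dropped): first one exactly at the 500 bp boundary
    for i in range(redundancy_plan["short"]):
        length = 500 if i == 0 else int(rng.integers(100, 501))
        add_contig(new_id(), length, "short", False, "short")

    # reference-redundant contigs: first exactly at identity 0.90 / coverage 0.80
    for i in range(redundancy_plan["reference_redundant"]):
        length = 1000 if i == 0 else int(rng.integers(600, 3001))
        if i == 0:
            identity, coverage = 0.90, 0.80
        else:
            # draws stay clear of the 0.90/0.80 boundary so integer rounding
            # of matches/qend cannot flip the planned label
            identity = float(rng.uniform(0.92, 0.99))
            coverage = float(rng.uniform(0.82, 0.99))
        cid = new_id()
        add_contig(cid, length, "reference_redundant", False, "reference_redundant")
        ref_paf.append(_ref_alignment(cid, length, identity, coverage))

    # self-redundant contigs: each the shorter copy of a longer clean partner
    clean_budget = redundancy_plan["clean"]
    for i in range(redundancy_plan["self_redundant"]):
        if i == 0:
            # round lengths make the 0.90/0.90 boundary exact after rounding
            short_len, long_len = 1000, 1500
        else:
            short_len = int(rng.integers(600, 1500))
            long_len = short_len + int(rng.integers(200, 800))
        dup_id = new_id()
        partner_id = new_id()
        add_contig(partner_id, long_len, "clean", True, "kept")
        clean_budget -= 1
        if i == 0:
            identity, coverage = 0.90, 0.90  # exactly at the self rule boundary
        else:
            identity = float(rng.uniform(0.92, 0.995))
            coverage = float(rng.uniform(0.92, 1.0))
        add_contig(dup_id, short_len, "self_redundant", False, "self_redundant")
        qend = int(round(coverage * short_len))
        matches = int(round(identity * qend))
        self_paf.append(
            AlignmentRecord(dup_id, short_len, 0, qend, "+", partner_id, long_len,
                            0, qend, matches, qend)
        )
        # reciprocal hit: the longer partner is only partially covered, so it stays
        self_paf.append(
            AlignmentRecord(partner_id, long_len, 0, qend, "+", dup_id, short_len,
                            0, qend, matches, qend)
        )

    # identical twin pair: same length, lexicographically larger id removed
    twin_a, twin_b = new_id(), new_id()
    twin_len = 900
    twin_seq = _random_seq(rng, twin_len)
    add_contig(twin_a, twin_len, "clean", True, "kept", sequence=twin_seq)
    add_contig(twin_b, twin_len, "self_redundant", False, "self_redundant",
               sequence=twin_seq)
    for query, target in ((twin_a, twin_b), (twin_b, twin_a)):
        self_paf.append(
            AlignmentRecord(query, twin_len, 0, twin_len, "+", target, twin_len,
                            0, twin_len, twin_len, twin_len)
        )

    # clean contigs: a 501 bp boundary keeper, near-miss alignments, unaligned rest
    n_clean_remaining = max(clean_budget - 2, 0)
    near_misses = [(0.95, 0.10), (0.95, 0.75), (0.89, 0.85)]
    for i in range(n_clean_remaining):
        length = 501 if i == 0 else int(rng.integers(600, 3001))
        cid = new_id()
        add_contig(cid, length, "clean", True, "kept")
        if 1 <= i <= len(near_misses):
            identity, coverage = near_misses[i - 1]
            ref_paf.append(_ref_alignment(cid, length, identity, coverage))

    oracle = pd.DataFrame(oracle_rows).set_index("contig_id")
    return ContigFixture(
        sequences=sequences, lengths=lengths, ref_paf=ref_paf,
        self_paf=self_paf, oracle=oracle,
    )
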