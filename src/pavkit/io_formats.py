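"""Readers and writers for the formats the PAV pipeline touches.

Coordinate conventions
----------------------
All intervals held in memory are 0-based half-open ``[start, end)``.
BED12 is natively 0-based half-open; GFF3 (1-based closed) and
samtools-depth positions (1-based) are converted at the file boundary,
so no other module ever sees a 1-based coordinate.

BED12 gene/transcript dialect: the BED ``name`` field is
``gene_id|transcript_id``.  A name without ``|`` denotes a
single-transcript gene whose transcript id equals the gene id.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Transcript",
    "GeneModel",
    "DepthTrack",
    "PopulationMap",
    "AlignmentRecord",
    "ParseError",
    "StructuralError",
    "read_gene_models",
    "write_bed12",
    "read_depth",
    "read_population_map",
    "write_population_map",
    "read_presence_matrix",
    "write_presence_matrix",
    "read_paf",
    "write_paf",
    "read_fasta",
    "write_fasta",
]

POPULATION_CLASSES = ("wild", "native", "improved")


class ParseError(ValueError):
    """A line of an input file violates its format; carries the line number."""


class StructuralError(ValueError):
    """The file parses line-by-line but the record structure is inconsistent."""


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted, non-overlapping

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.exons:
            if not 0 <= start < end:
                raise StructuralError(
                    f"transcript {self.transcript_id}: bad exon [{start}, {end})"
                )
            if start < prev_end:
                raise StructuralError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end
        if not self.exons:
            raise StructuralError(f"transcript {self.transcript_id} has no exons")

    @property
    def exonic_length(self) -> int:
        return sum(end - start for start, end in self.exons)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise StructuralError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.transcripts:
            raise StructuralError(f"gene {self.gene_id} has no transcripts")

    @property
    def start(self) -> int:
        return min(t.exons[0][0] for t in self.transcripts)


class DepthTrack:
    """Sparse per-base read depth for one individual.

    Positions absent from the input file have depth 0 (the samtools-depth
    default dialect omits zero rows).  Positions are stored 0-based.
    """

    def __init__(self, individual_id: str,
                 per_chrom: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None):
        self.individual_id = individual_id
        # chrom -> (sorted 0-based positions int64, depths int64)
        self.per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = dict(per_chrom or {})

    def depth_at(self, chrom: str, pos: int) -> int:
        """Depth at a 0-based position; 0 where nothing was listed."""
        if chrom not in self.per_chrom:
            return 0
        positions, depths = self.per_chrom[chrom]
        i = int(np.searchsorted(positions, pos))
        if i < len(positions) and positions[i] == pos:
            return int(depths[i])
        return 0

    def total_depth(self) -> int:
        """Sum of depth over all listed positions (numerator of mean depth)."""
        return int(sum(int(d.sum()) for _, d in self.per_chrom.values()))


@dataclass
class PopulationMap:
    """individual_id -> (population, class); class is wild/native/improved."""

    assignments: dict[str, tuple[str, str]] = field(default_factory=dict)

    def add(self, individual_id: str, population: str, cls: str) -> None:
        if individual_id in self.assignments:
            raise StructuralError(f"individual {individual_id} listed twice")
        if cls not in POPULATION_CLASSES:
            raise StructuralError(
                f"individual {individual_id}: unknown class {cls!r} "
                f"(expected one of {POPULATION_CLASSES})"
            )
        self.assignments[individual_id] = (population, cls)

    def individuals(self) -> list[str]:
        return list(self.assignments)

    def population_of(self, individual_id: str) -> str:
        return self.assignments[individual_id][0]

    def class_of(self, individual_id: str) -> str:
        return self.assignments[individual_id][1]

    def members(self, population: str) -> list[str]:
        out = [i for i, (pop, _) in self.assignments.items() if pop == population]
        if not out:
            raise KeyError(f"population {population!r} has no individuals in the map")
        return out

    def members_of_class(self, cls: str) -> list[str]:
        if cls not in POPULATION_CLASSES:
            raise KeyError(f"unknown class {cls!r} (expected one of {POPULATION_CLASSES})")
        return [i for i, (_, c) in self.assignments.items() if c == cls]


@dataclass(frozen=True)
class AlignmentRecord:
    """One PAF alignment; query coordinates are 0-based half-open."""

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    matches: int
    block_len: int
    mapq: int = 60

    def __post_init__(self) -> None:
        if not 0 <= self.query_start < self.query_end <= self.query_len:
            raise StructuralError(
                f"alignment {self.query_id}->{self.target_id}: query interval "
                f"[{self.query_start}, {self.query_end}) outside [0, {self.query_len}]"
            )
        if self.matches > self.block_len:
            raise StructuralError(
                f"alignment {self.query_id}->{self.target_id}: matches > block_len"
            )


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def _split_bed_name(name: str) -> tuple[str, str]:
    if "|" in name:
        gene_id, transcript_id = name.split("|", 1)
        return gene_id, transcript_id
    return name, name


def _parse_bed12_line(line: str, lineno: int):
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ParseError(f"line {lineno}: BED12 needs 12 columns, got {len(fields)}")
    try:
        chrom = fields[0]
        chrom_start = int(fields[1])
        strand = fields[5] if fields[5] in ("+", "-", ".") else "."
        block_count = int(fields[9])
        block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None
    if len(block_sizes) != block_count or len(block_starts) != block_count:
        raise ParseError(f"line {lineno}: blockCount does not match block lists")
    gene_id, transcript_id = _split_bed_name(fields[3])
    exons = tuple(
        (chrom_start + off, chrom_start + off + size)
        for off, size in zip(block_starts, block_sizes)
    )
    return chrom, strand, gene_id, Transcript(transcript_id, exons)


def _read_bed12(handle: io.TextIOBase) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    seen_transcripts: set[str] = set()
    for lineno, line in enumerate(handle, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        chrom, strand, gene_id, transcript = _parse_bed12_line(line, lineno)
        if transcript.transcript_id in seen_transcripts:
            raise StructuralError(
                f"line {lineno}: duplicate transcript_id {transcript.transcript_id!r}"
            )
        seen_transcripts.add(transcript.transcript_id)
        rec = genes.setdefault(gene_id, {"chrom": chrom, "strand": strand, "tx": []})
        if rec["chrom"] != chrom:
            raise StructuralError(f"gene {gene_id} spans chromosomes {rec['chrom']}/{chrom}")
        rec["tx"].append(transcript)
    return [
        GeneModel(gid, rec["chrom"], rec["strand"], tuple(rec["tx"]))
        for gid, rec in genes.items()
    ]


def _gff3_attributes(field9: str, lineno: int) -> dict[str, str]:
    attrs = {}
    for part in field9.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ParseError(f"line {lineno}: malformed GFF3 attribute {part!r}")
        key, value = part.split("=", 1)
        attrs[key] = value
    return attrs


def _read_gff3(handle: io.TextIOBase) -> list[GeneModel]:
    gene_meta: dict[str, tuple[str, str]] = {}          # gene -> (chrom, strand)
    tx_parent: dict[str, str] = {}                      # transcript -> gene
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in enumerate(handle, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise ParseError(f"line {lineno}: GFF3 needs 9 columns, got {len(fields)}")
        chrom, _, ftype, start_s, end_s, _, strand, _, attr_s = fields
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer coordinates") from None
        # 1-based closed -> 0-based half-open
        start, end = start1 - 1, end1
        attrs = _gff3_attributes(attr_s, lineno)
        if ftype == "gene":
            gid = attrs.get("ID")
            if gid is None:
                raise ParseError(f"line {lineno}: gene without ID attribute")
            gene_meta[gid] = (chrom, strand if strand in ("+", "-") else ".")
        elif ftype in ("mRNA", "transcript"):
            tid, parent = attrs.get("ID"), attrs.get("Parent")
            if tid is None or parent is None:
                raise ParseError(f"line {lineno}: transcript without ID/Parent")
            if tid in tx_parent:
                raise StructuralError(f"line {lineno}: duplicate transcript_id {tid!r}")
            tx_parent[tid] = parent
            tx_exons.setdefault(tid, [])
        elif ftype == "exon":
            parent = attrs.get("Parent")
            if parent is None:
                raise ParseError(f"line {lineno}: exon without Parent")
            tx_exons.setdefault(parent, []).append((start, end))
    models = []
    for gid, (chrom, strand) in gene_meta.items():
        transcripts = []
        for tid, parent in tx_parent.items():
            if parent != gid:
                continue
            exons = sorted(tx_exons.get(tid, []))
            transcripts.append(Transcript(tid, tuple(exons)))
        if transcripts:
            models.append(GeneModel(gid, chrom, strand, tuple(transcripts)))
    orphans = set(tx_parent.values()) - set(gene_meta)
    if orphans:
        raise StructuralError(f"transcripts reference unknown gene(s): {sorted(orphans)}")
    return models


def read_gene_models(path, format: str = "bed12") -> list[GeneModel]:
    """Read gene models from BED12 or GFF3, ordered by (chrom, start, gene_id)."""
    with open(path) as handle:
        if format == "bed12":
            models = _read_bed12(handle)
        elif format == "gff3":
            models = _read_gff3(handle)
        else:
            raise ValueError(f"unknown gene-model format {format!r}")
    models.sort(key=lambda m: (m.chrom, m.start, m.gene_id))
    return models


def write_bed12(models: Iterable[GeneModel], path=None) -> str:
    """Write one BED12 line per transcript (name = ``gene|transcript``)."""
    lines = []
    for model in models:
        for tx in model.transcripts:
            start = tx.exons[0][0]
            end = tx.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in tx.exons)
            offsets = ",".join(str(s - start) for s, e in tx.exons)
            lines.append(
                "\t".join(
                    [
                        model.chrom,
                        str(start),
                        str(end),
                        f"{model.gene_id}|{tx.transcript_id}",
                        "0",
                        model.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(tx.exons)),
                        sizes,
                        offsets,
                    ]
                )
            )
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        with open(path, "w") as handle:
            handle.write(text)
    return text


# ---------------------------------------------------------------------------
# Depth tracks
# ---------------------------------------------------------------------------

def read_depth(path, individual_id: str | None = None) -> DepthTrack:
    """Read a 3-column samtools-depth TSV (chrom, 1-based pos, depth).

    Unlisted positions are depth 0.  Positions are converted to 0-based.
    """
    per_chrom_pos: dict[str, list[int]] = {}
    per_chrom_depth: dict[str, list[int]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ParseError(f"line {lineno}: expected 3 columns, got {len(fields)}")
            chrom, pos_s, depth_s = fields
            try:
                pos1, depth = int(pos_s), int(depth_s)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer position or depth") from None
            if pos1 < 1:
                raise ParseError(f"line {lineno}: position {pos1} < 1")
            if depth < 0:
                raise ParseError(f"line {lineno}: negative depth {depth}")
            per_chrom_pos.setdefault(chrom, []).append(pos1 - 1)
            per_chrom_depth.setdefault(chrom, []).append(depth)
    per_chrom = {}
    for chrom, positions in per_chrom_pos.items():
        pos = np.asarray(positions, dtype=np.int64)
        dep = np.asarray(per_chrom_depth[chrom], dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        per_chrom[chrom] = (pos[order], dep[order])
    if individual_id is None:
        individual_id = str(path)
    return DepthTrack(individual_id, per_chrom)


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------

def read_population_map(path) -> PopulationMap:
    popmap = PopulationMap()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if lineno == 1 and fields[:1] == ["individual_id"]:
                continue
            if len(fields) != 3:
                raise ParseError(f"line {lineno}: expected 3 columns, got {len(fields)}")
            popmap.add(*fields)
    return popmap


def write_population_map(popmap: PopulationMap, path) -> None:
    with open(path, "w") as handle:
        handle.write("individual_id\tpopulation\tclass\n")
        for ind, (pop, cls) in popmap.assignments.items():
            handle.write(f"{ind}\t{pop}\t{cls}\n")


# ---------------------------------------------------------------------------
# Presence matrix
# ---------------------------------------------------------------------------

def write_presence_matrix(matrix: pd.DataFrame, path) -> None:
    """TSV: first column gene_id, one 0/1 column per individual."""
    out = matrix.astype(int)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_presence_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if df.empty and len(df.columns) >= 0:
        return df.astype(bool)
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"presence matrix cell ({df.index[i]}, {df.columns[j]}) = "
            f"{values[i, j]!r} is not 0/1"
        )
    return df.astype(bool)


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------

def read_paf(path) -> list[AlignmentRecord]:
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ParseError(f"line {lineno}: PAF needs 12 columns, got {len(fields)}")
            try:
                records.append(
                    AlignmentRecord(
                        query_id=fields[0],
                        query_len=int(fields[1]),
                        query_start=int(fields[2]),
                        query_end=int(fields[3]),
                        strand=fields[4],
                        target_id=fields[5],
                        target_len=int(fields[6]),
                        target_start=int(fields[7]),
                        target_end=int(fields[8]),
                        matches=int(fields[9]),
                        block_len=int(fields[10]),
                        mapq=int(fields[11]),
                    )
                )
            except ValueError as exc:
                if isinstance(exc, StructuralError):
                    raise
                raise ParseError(f"line {lineno}: {exc}") from None
    return records


def write_paf(records: Sequence[AlignmentRecord], path) -> None:
    with open(path, "w") as handle:
        for r in records:
            handle.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id, r.query_len, r.query_start, r.query_end,
                        r.strand, r.target_id, r.target_len, r.target_start,
                        r.target_end, r.matches, r.block_len, r.mapq,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA (thin Biopython wrappers so callers stay format-agnostic)
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
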