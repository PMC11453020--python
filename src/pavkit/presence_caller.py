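"""Coverage-breadth gene presence/absence calling.

A gene is called *absent* in an individual when fewer than 5% of the
exonic bases of its gene body (the longest transcript) are covered by at
least two reads; otherwise it is *present*.  The 5% threshold is strict
("less than"), so a breadth of exactly 0.05 is a presence call.
Individuals whose genome-wide mean depth is below 10x are excluded
before calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import DepthTrack, GeneModel

__all__ = [
    "CallerConfig",
    "GeneBody",
    "select_gene_body",
    "filter_individuals_by_depth",
    "exon_breadth",
    "call_presence",
    "build_presence_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds of the absence rule.

    min_depth
        Per-base depth a position must reach to count as covered (reads).
    absence_breadth_threshold
        Breadth below which a gene is absent (fraction of exonic bases).
    min_individual_mean_depth
        Genome-wide mean depth an individual needs to be retained (x).
    """

    min_depth: int = 2
    absence_breadth_threshold: float = 0.05
    min_individual_mean_depth: float = 10.0

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0 < self.absence_breadth_threshold < 1:
            raise ValueError("absence_breadth_threshold must be in (0, 1)")


@dataclass(frozen=True)
class GeneBody:
    """Exon set of a gene's longest transcript; the coverage denominator."""

    gene_id: str
    chrom: str
    exons: tuple[tuple[int, int], ...]  # unioned, sorted, 0-based half-open
    exonic_length: int


def _union_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def select_gene_body(model: GeneModel) -> GeneBody:
    """Pick the longest transcript as the gene body.

    Length is total exonic length; ties go to the lexicographically
    smallest transcript id.  Overlapping exons within the chosen
    transcript are unioned so no base is counted twice.
    """
    best = min(model.transcripts, key=lambda t: (-t.exonic_length, t.transcript_id))
    exons = _union_intervals(best.exons)
    return GeneBody(
        gene_id=model.gene_id,
        chrom=model.chrom,
        exons=exons,
        exonic_length=sum(e - s for s, e in exons),
    )


def filter_individuals_by_depth(
    tracks: Mapping[str, DepthTrack],
    config: CallerConfig,
    total_reference_length: int,
) -> list[str]:
    """Retain individuals whose mean depth over the whole reference is high enough.

    The denominator is the total reference length, not just covered
    positions, matching the usual meaning of "average sequencing depth".
    """
    if total_reference_length is None or total_reference_length <= 0:
        raise ValueError("total_reference_length must be a positive integer")
    retained = []
    for individual_id, track in tracks.items():
        mean = track.total_depth() / total_reference_length
        if mean >= config.min_individual_mean_depth:
            retained.append(individual_id)
    return retained


def exon_breadth(track: DepthTrack, body: GeneBody, min_depth: int = 2) -> float:
    """Fraction of the gene body's exonic bases with depth >= min_depth."""
    covered = 0
    chrom_data = track.per_chrom.get(body.chrom)
    if chrom_data is None:
        return 0.0
    positions, depths = chrom_data
    for start, end in body.exons:
        lo = int(np.searchsorted(positions, start, side="left"))
        hi = int(np.searchsorted(positions, end, side="left"))
        if hi > lo:
            covered += int((depths[lo:hi] >= min_depth).sum())
    return covered / body.exonic_length


def call_presence(breadth: float, config: CallerConfig) -> bool:
    """True (present) unless breadth falls strictly below the threshold."""
    if not 0.0 <= breadth <= 1.0:
        raise ValueError(f"breadth {breadth} outside [0, 1]")
    return breadth >= config.absence_breadth_threshold


def build_presence_matrix(
    tracks: Mapping[str, DepthTrack],
    bodies: Sequence[GeneBody],
    config: CallerConfig,
    individuals: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One presence call per (gene, individual); genes x individuals boolean.

    ``individuals`` restricts the matrix to a retained subset; every
    retained individual must have a depth track (no silent imputation).
    """
    if individuals is None:
        individuals = list(tracks)
    missing = [ind for ind in individuals if ind not in tracks]
    if missing:
        raise KeyError(f"no depth track for individual(s): {missing}")
    if not individuals:
        logger.warning("no retained individuals; presence matrix is empty")
    calls = np.zeros((len(bodies), len(individuals)), dtype=bool)
    for j, individual_id in enumerate(individuals):
        track = tracks[individual_id]
        for i, body in enumerate(bodies):
            calls[i, j] = call_presence(
                exon_breadth(track, body, config.min_depth), config
            )
    return pd.DataFrame(
        calls, index=[b.gene_id for b in bodies], columns=list(individuals)
    )
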