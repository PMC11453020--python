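"""Map-to-pan nonreference contig curation.

Assembled contigs destined for the pan-genome are filtered in three
composable steps, in order:

1. length — only contigs longer than 500 bp (>= 501) are retained;
2. reference redundancy — contigs aligning to the reference with
   identity >= 90% and query coverage >= 80% are excluded;
3. self redundancy — in all-vs-all alignments, a contig covered >= 90%
   at identity >= 90% by a longer (kept) contig is removed; identical
   lengths keep the lexicographically smaller id.

Coverage of a contig is the fraction of its bases inside the union of
its aligned query intervals; identity is the block-length-weighted mean
of per-alignment matches/block_len.  Both definitions are deterministic
and independent of alignment order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import AlignmentRecord

__all__ = [
    "ContigAlignmentSummary",
    "filter_by_length",
    "summarize_alignments",
    "filter_reference_redundant",
    "filter_self_redundant",
    "run_contig_filters",
]


@dataclass(frozen=True)
class ContigAlignmentSummary:
    contig_id: str
    coverage_fraction: float
    identity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage_fraction <= 1.0 and 0.0 <= self.identity <= 1.0):
            raise ValueError(f"contig {self.contig_id}: summary outside [0, 1]")


def filter_by_length(lengths: Mapping[str, int], min_exclusive: int = 500) -> set[str]:
    """Contig ids retained by the length rule: strictly longer than 500 bp."""
    return {cid for cid, length in lengths.items() if length > min_exclusive}


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    current_start = current_end = None
    for start, end in sorted(intervals):
        if current_end is None or start > current_end:
            if current_end is not None:
                total += current_end - current_start
            current_start, current_end = start, end
        else:
            current_end = max(current_end, end)
    if current_end is not None:
        total += current_end - current_start
    return total


def summarize_alignments(
    records: Sequence[AlignmentRecord],
    contig_ids: Iterable[str] | None = None,
) -> dict[str, ContigAlignmentSummary]:
    """Per-query coverage (interval union) and weighted identity.

    Contigs listed in ``contig_ids`` but without alignments get coverage
    0 and identity 0 (vacuously non-redundant).
    """
    by_query: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_query.setdefault(rec.query_id, []).append(rec)
    summaries: dict[str, ContigAlignmentSummary] = {}
    for query_id, recs in by_query.items():
        qlen = recs[0].query_len
        if any(r.query_len != qlen for r in recs):
            raise ValueError(f"contig {query_id}: inconsistent query_len across PAF records")
        covered = _union_length((r.query_start, r.query_end) for r in recs)
        block_total = sum(r.block_len for r in recs)
        identity = (sum(r.matches for r in recs) / block_total) if block_total else 0.0
        summaries[query_id] = ContigAlignmentSummary(query_id, covered / qlen, identity)
    if contig_ids is not None:
        for cid in contig_ids:
            summaries.setdefault(cid, ContigAlignmentSummary(cid, 0.0, 0.0))
    return summaries


def filter_reference_redundant(
    summaries: Mapping[str, ContigAlignmentSummary],
    min_identity: float = 0.90,
    min_coverage: float = 0.80,
) -> set[str]:
    """Contigs excluded as redundant with the reference (both bounds inclusive)."""
    return {
        cid
        for cid, s in summaries.items()
        if s.identity >= min_identity and s.coverage_fraction >= min_coverage
    }


def _pair_summaries(
    records: Sequence[AlignmentRecord],
) -> dict[tuple[str, str], ContigAlignmentSummary]:
    by_pair: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for rec in records:
        if rec.query_id == rec.target_id:
            continue  # trivial self-hit
        by_pair.setdefault((rec.query_id, rec.target_id), []).append(rec)
    out = {}
    for (query_id, target_id), recs in by_pair.items():
        qlen = recs[0].query_len
        covered = _union_length((r.query_start, r.query_end) for r in recs)
        block_total = sum(r.block_len for r in recs)
        identity = (sum(r.matches for r in recs) / block_total) if block_total else 0.0
        out[(query_id, target_id)] = ContigAlignmentSummary(
            query_id, covered / qlen, identity
        )
    return out


def filter_self_redundant(
    records: Sequence[AlignmentRecord],
    lengths: Mapping[str, int],
    min_identity: float = 0.90,
    min_coverage: float = 0.90,
) -> set[str]:
    """Contigs removed as redundant copies of longer kept contigs.

    Contigs are processed in decreasing length (ties: lexicographically
    smaller id first, so it survives); a contig is removed when its own
    coverage against any already-kept contig reaches the thresholds.
    Removed contigs cannot knock out later ones, resolving cascades.
    """
    pairs = _pair_summaries(records)
    order = sorted(lengths, key=lambda cid: (-lengths[cid], cid))
    kept: set[str] = set()
    removed: set[str] = set()
    for cid in order:
        redundant_vs = [
            target
            for (query, target), s in pairs.items()
            if query == cid
            and target in kept
            and s.identity >= min_identity
            and s.coverage_fraction >= min_coverage
        ]
        if redundant_vs:
            removed.add(cid)
        else:
            kept.add(cid)
    return removed


def run_contig_filters(
    lengths: Mapping[str, int],
    ref_records: Sequence[AlignmentRecord] = (),
    self_records: Sequence[AlignmentRecord] = (),
    exclude_list: Iterable[str] = (),
    min_length_exclusive: int = 500,
    ref_min_identity: float = 0.90,
    ref_min_coverage: float = 0.80,
    self_min_identity: float = 0.90,
    self_min_coverage: float = 0.90,
) -> pd.DataFrame:
    """Compose the filters in order and record a per-contig drop reason.

    Returns a frame indexed by contig_id with ``kept`` (bool) and
    ``reason`` in {kept, short, reference_redundant, self_redundant, listed}.
    ``exclude_list`` accommodates externally produced exclusions (e.g. a
    contamination screen run elsewhere).
    """
    reasons = {cid: "kept" for cid in lengths}
    for cid in exclude_list:
        if cid in reasons:
            reasons[cid] = "listed"

    survivors = {cid for cid in lengths if reasons[cid] == "kept"}
    long_enough = filter_by_length(
        {cid: lengths[cid] for cid in survivors}, min_exclusive=min_length_exclusive
    )
    for cid in survivors - long_enough:
        reasons[cid] = "short"
    survivors = long_enough

    ref_summaries = summarize_alignments(
        [r for r in ref_records if r.query_id in survivors], contig_ids=survivors
    )
    for cid in filter_reference_redundant(
        ref_summaries, ref_min_identity, ref_min_coverage
    ):
        reasons[cid] = "reference_redundant"
    survivors = {cid for cid in survivors if reasons[cid] == "kept"}

    for cid in filter_self_redundant(
        [r for r in self_records if r.query_id in survivors and r.target_id in survivors],
        {cid: lengths[cid] for cid in survivors},
        self_min_identity,
        self_min_coverage,
    ):
        reasons[cid] = "self_redundant"

    report = pd.DataFrame(
        {
            "length": [lengths[cid] for cid in lengths],
            "reason": [reasons[cid] for cid in lengths],
        },
        index=pd.Index(list(lengths), name="contig_id"),
    )
    report["kept"] = report["reason"] == "kept"
    return report
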