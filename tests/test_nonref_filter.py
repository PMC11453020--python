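"""Nonreference-contig curation: length, reference- and self-redundancy."""

import pytest

from pavkit import nonref_filter as nf
from pavkit.io_formats import AlignmentRecord


def ref_hit(cid, qlen, qstart, qend, identity):
    block = qend - qstart
    return AlignmentRecord(cid, qlen, qstart, qend, "+", "ref", 10**6, 0, block,
                           int(round(identity * block)), block)


def self_hit(query, qlen, qend, target, tlen, identity=0.95):
    matches = int(round(identity * qend))
    return AlignmentRecord(query, qlen, 0, qend, "+", target, tlen, 0, qend,
                           matches, qend)


class TestLength:
    def test_boundary_500_dropped_501_retained(self):
        kept = nf.filter_by_length({"a": 500, "b": 501, "c": 4000})
        assert kept == {"b", "c"}

    def test_empty_input(self):
        assert nf.filter_by_length({}) == set()


class TestSummaries:
    def test_union_coverage(self):
        records = [ref_hit("c1", 200, 0, 100, 0.95), ref_hit("c1", 200, 50, 150, 0.95)]
        summary = nf.summarize_alignments(records)["c1"]
        assert summary.coverage_fraction == pytest.approx(150 / 200)

    def test_single_alignment_identity(self):
        summary = nf.summarize_alignments([ref_hit("c1", 200, 0, 100, 0.90)])["c1"]
        assert summary.identity == pytest.approx(0.90)

    def test_weighted_identity(self):
        records = [
            AlignmentRecord("c1", 300, 0, 100, "+", "ref", 10**6, 0, 100, 100, 100),
            AlignmentRecord("c1", 300, 100, 300, "+", "ref", 10**6, 0, 200, 100, 200),
        ]
        summary = nf.summarize_alignments(records)["c1"]
        assert summary.identity == pytest.approx(200 / 300)

    def test_unaligned_contig_vacuous(self):
        summaries = nf.summarize_alignments([], contig_ids=["lonely"])
        assert summaries["lonely"].coverage_fraction == 0.0
        assert summaries["lonely"].identity == 0.0

    def test_inconsistent_query_len_rejected(self):
        records = [ref_hit("c1", 200, 0, 100, 0.9), ref_hit("c1", 300, 0, 100, 0.9)]
        with pytest.raises(ValueError, match="query_len"):
            nf.summarize_alignments(records)


class TestReferenceRedundancy:
    @pytest.mark.parametrize(
        "identity,coverage,excluded",
        [
            (0.95, 0.85, True),
            (0.95, 0.10, False),  # high identity alone does not exclude
            (0.90, 0.80, True),   # both boundaries inclusive
            (0.89, 0.99, False),
            (0.99, 0.79, False),
        ],
    )
    def test_and_rule_with_inclusive_bounds(self, identity, coverage, excluded):
        summaries = {"c": nf.ContigAlignmentSummary("c", coverage, identity)}
        result = nf.filter_reference_redundant(summaries)
        assert (("c" in result) is excluded)


class TestSelfRedundancy:
    def test_shorter_contig_removed(self):
        lengths = {"long": 2000, "short": 1000}
        records = [
            self_hit("short", 1000, 950, "long", 2000, identity=0.92),
            self_hit("long", 2000, 950, "short", 1000, identity=0.92),
        ]
        assert nf.filter_self_redundant(records, lengths) == {"short"}

    def test_identical_twins_keep_lexicographically_smaller(self):
        lengths = {"twinA": 900, "twinB": 900}
        records = [
            self_hit("twinA", 900, 900, "twinB", 900, identity=1.0),
            self_hit("twinB", 900, 900, "twinA", 900, identity=1.0),
        ]
        assert nf.filter_self_redundant(records, lengths) == {"twinB"}

    def test_disjoint_contigs_untouched(self):
        lengths = {"a": 1000, "b": 900}
        records = [self_hit("b", 900, 200, "a", 1000)]  # only 22% covered
        assert nf.filter_self_redundant(records, lengths) == set()

    def test_cascade_resolved_longest_first(self):
        # c covers b, b covers a; b dies to c, and a dies to c only if covered by c
        lengths = {"c": 3000, "b": 2000, "a": 1000}
        records = [
            self_hit("b", 2000, 1900, "c", 3000),
            self_hit("a", 1000, 950, "b", 2000),
        ]
        # a's only redundancy partner b is itself removed, so a survives
        assert nf.filter_self_redundant(records, lengths) == {"b"}

    def test_idempotent(self):
        lengths = {"long": 2000, "short": 1000}
        records = [self_hit("short", 1000, 950, "long", 2000)]
        removed = nf.filter_self_redundant(records, lengths)
        survivors = {c: l for c, l in lengths.items() if c not in removed}
        surviving_records = [
            r for r in records
            if r.query_id in survivors and r.target_id in survivors
        ]
        assert nf.filter_self_redundant(surviving_records, survivors) == set()


class TestComposition:
    def test_report_reasons_in_filter_order(self):
        lengths = {"tiny": 400, "refdup": 1000, "dup": 1000, "keeper": 2000}
        ref_records = [ref_hit("refdup", 1000, 0, 900, 0.95)]
        self_records = [
            self_hit("dup", 1000, 950, "keeper", 2000),
            self_hit("keeper", 2000, 950, "dup", 1000),
        ]
        report = nf.run_contig_filters(lengths, ref_records, self_records)
        assert report.loc["tiny", "reason"] == "short"
        assert report.loc["refdup", "reason"] == "reference_redundant"
        assert report.loc["dup", "reason"] == "self_redundant"
        assert report.loc["keeper", "reason"] == "kept"
        assert report["kept"].sum() == 1

    def test_exclude_list_applied_first(self):
        report = nf.run_contig_filters({"a": 1000}, exclude_list=["a"])
        assert report.loc["a", "reason"] == "listed"
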