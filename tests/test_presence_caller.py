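"""Breadth-based presence calling: gene body, breadth, thresholds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pavkit import presence_caller as pc
from pavkit.io_formats import DepthTrack, GeneModel, Transcript

from oracles import breadth_per_base


def make_track(individual, chrom, depth_by_pos0):
    positions = np.array(sorted(depth_by_pos0), dtype=np.int64)
    depths = np.array([depth_by_pos0[p] for p in positions], dtype=np.int64)
    return DepthTrack(individual, {chrom: (positions, depths)})


class TestGeneBody:
    def test_longest_transcript_wins(self):
        model = GeneModel(
            "g1", "chr1", "+",
            (
                Transcript("t_short", ((0, 300),)),
                Transcript("t_long", ((1000, 1500),)),
            ),
        )
        body = pc.select_gene_body(model)
        assert body.exons == ((1000, 1500),)
        assert body.exonic_length == 500

    def test_single_transcript_is_itself(self):
        model = GeneModel("g1", "chr1", ".", (Transcript("t1", ((5, 10),)),))
        assert pc.select_gene_body(model).exonic_length == 5

    def test_tie_broken_by_smaller_transcript_id(self):
        model = GeneModel(
            "g1", "chr1", "+",
            (
                Transcript("tB", ((0, 400),)),
                Transcript("tA", ((1000, 1400),)),
            ),
        )
        assert pc.select_gene_body(model).exons == ((1000, 1400),)

    def test_overlapping_exons_rejected_and_adjacent_unioned(self):
        from pavkit.io_formats import StructuralError

        with pytest.raises(StructuralError, match="overlap"):
            Transcript("t0", ((0, 60), (50, 100)))
        # book-ended exons merge in the gene body so no base counts twice
        model = GeneModel(
            "g1", "chr1", "+", (Transcript("t1", ((0, 60), (60, 100))),)
        )
        body = pc.select_gene_body(model)
        assert body.exons == ((0, 100),)
        assert body.exonic_length == 100


class TestBreadthAndCall:
    def test_hand_counted_breadth(self):
        # exon [0,100); depth 5 at 1-based positions 1-4 = 0-based 0-3
        track = make_track("i", "chr1", {p: 5 for p in range(4)})
        body = pc.GeneBody("g", "chr1", ((0, 100),), 100)
        assert pc.exon_breadth(track, body, min_depth=2) == pytest.approx(0.04)

    def test_uniform_depth_two_is_full_breadth(self):
        track = make_track("i", "chr1", {p: 2 for p in range(50)})
        body = pc.GeneBody("g", "chr1", ((0, 50),), 50)
        assert pc.exon_breadth(track, body, 2) == 1.0

    def test_depth_below_min_counts_zero(self):
        track = make_track("i", "chr1", {p: 1 for p in range(50)})
        body = pc.GeneBody("g", "chr1", ((0, 50),), 50)
        assert pc.exon_breadth(track, body, 2) == 0.0

    @pytest.mark.parametrize(
        "breadth,expected",
        [(0.04, False), (0.05, True), (0.0499, False), (1.0, True), (0.0, False)],
    )
    def test_absence_threshold_is_strict(self, breadth, expected):
        assert pc.call_presence(breadth, pc.CallerConfig()) is expected

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(st.tuples(st.integers(0, 80), st.integers(1, 20)), min_size=1, max_size=4),
        st.dictionaries(st.integers(0, 120), st.integers(0, 6), max_size=40),
    )
    def test_breadth_matches_per_base_oracle(self, raw_exons, depth_by_pos):
        exons = []
        cursor = 0
        for offset, length in raw_exons:  # build sorted non-overlapping exons
            start = cursor + offset
            exons.append((start, start + length))
            cursor = start + length + 1
        body = pc.GeneBody("g", "chr1", tuple(exons), sum(e - s for s, e in exons))
        track = make_track("i", "chr1", depth_by_pos or {0: 0})
        fast = pc.exon_breadth(track, body, 2)
        slow = breadth_per_base(track, exons, 2, "chr1")
        assert fast == pytest.approx(slow)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.dictionaries(st.integers(0, 60), st.integers(0, 5), max_size=30),
        st.dictionaries(st.integers(0, 60), st.integers(1, 5), max_size=10),
    )
    def test_adding_depth_never_flips_present_to_absent(self, base, extra):
        config = pc.CallerConfig()
        body = pc.GeneBody("g", "chr1", ((0, 61),), 61)
        before = pc.exon_breadth(make_track("i", "chr1", base or {0: 0}), body, 2)
        boosted = dict(base)
        for pos, add in extra.items():
            boosted[pos] = boosted.get(pos, 0) + add
        after = pc.exon_breadth(make_track("i", "chr1", boosted), body, 2)
        assert after >= before
        if pc.call_presence(before, config):
            assert pc.call_presence(after, config)


class TestIndividualFilter:
    def test_mean_depth_boundary_inclusive(self):
        config = pc.CallerConfig()
        track = make_track("i", "chr1", {p: 10 for p in range(100)})  # total 1000
        assert pc.filter_individuals_by_depth({"i": track}, config, 100) == ["i"]
        assert pc.filter_individuals_by_depth({"i": track}, config, 101) == []

    def test_empty_track_dropped(self):
        track = DepthTrack("i", {})
        assert pc.filter_individuals_by_depth({"i": track}, pc.CallerConfig(), 100) == []

    def test_missing_denominator_is_error(self):
        with pytest.raises(ValueError, match="total_reference_length"):
            pc.filter_individuals_by_depth({}, pc.CallerConfig(), 0)


class TestMatrix:
    def test_matrix_recovers_ground_truth(self, cohort):
        truth = cohort["truth"].presence
        matrix = cohort["matrix"]
        pd.testing.assert_frame_equal(
            matrix.loc[truth.index, truth.columns], truth
        )

    def test_missing_track_is_hard_error(self, cohort):
        with pytest.raises(KeyError, match="ghost"):
            pc.build_presence_matrix(
                cohort["tracks"], cohort["bodies"], pc.CallerConfig(),
                individuals=["ghost"],
            )

    def test_zero_retained_individuals_gives_empty_matrix(self, cohort, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="pavkit.presence_caller"):
            matrix = pc.build_presence_matrix(
                cohort["tracks"], cohort["bodies"], pc.CallerConfig(), individuals=[]
            )
        assert matrix.shape == (len(cohort["bodies"]), 0)
        assert any("no retained individuals" in r.message for r in caplog.records)
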