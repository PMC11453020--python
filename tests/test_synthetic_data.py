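"""Ground-truth generators: determinism, separation, planned oracles."""

import numpy as np
import pytest

from pavkit import nonref_filter as nf
from pavkit import presence_caller as pc
from pavkit import synthetic_data as sd
from pavkit.io_formats import read_depth


class TestConfig:
    def test_invalid_ranges_name_the_field(self):
        with pytest.raises(sd.ConfigurationError, match="exon_length"):
            sd.SimulationConfig(exon_length=(0, 10))
        with pytest.raises(sd.ConfigurationError, match="absent_residual_breadth"):
            sd.SimulationConfig(absent_residual_breadth=0.05)
        with pytest.raises(sd.ConfigurationError, match="frequency_spectrum"):
            sd.SimulationConfig(n_genes=2, frequency_spectrum=np.ones((3, 3)))

    def test_frequencies_must_be_probabilities(self):
        with pytest.raises(sd.ConfigurationError, match="\\[0, 1\\]"):
            sd.SimulationConfig(n_genes=1, frequency_spectrum=np.full((1, 3), 1.5))


class TestGeneModels:
    def test_deterministic_bed_text(self):
        config = sd.SimulationConfig(n_genes=10, seed=1)
        models_a, bed_a = sd.simulate_gene_models(config)
        models_b, bed_b = sd.simulate_gene_models(config)
        assert bed_a == bed_b and models_a == models_b
        assert bed_a.count("\n") >= 10  # one BED12 record per transcript

    def test_genes_do_not_overlap(self):
        models, _ = sd.simulate_gene_models(sd.SimulationConfig(n_genes=30, seed=2))
        spans = sorted(
            (min(t.exons[0][0] for t in m.transcripts),
             max(t.exons[-1][1] for t in m.transcripts))
            for m in models
        )
        for (_, end_prev), (start_next, _) in zip(spans, spans[1:]):
            assert start_next > end_prev

    def test_single_exon_genes_have_span_length(self):
        config = sd.SimulationConfig(n_genes=8, exons_per_gene=(1, 1), seed=3)
        models, _ = sd.simulate_gene_models(config)
        for model in models:
            for tx in model.transcripts:
                assert len(tx.exons) == 1
                start, end = tx.exons[0]
                assert tx.exonic_length == end - start

    def test_alternative_transcript_exists_and_is_shorter(self):
        models, _ = sd.simulate_gene_models(sd.SimulationConfig(n_genes=5, seed=4))
        first = models[0]
        assert len(first.transcripts) >= 2
        lengths = sorted(t.exonic_length for t in first.transcripts)
        assert lengths[0] < lengths[-1]
        body = pc.select_gene_body(first)
        assert body.exonic_length == lengths[-1]


class TestPresence:
    def test_fixed_frequencies(self):
        spectrum = np.tile([[1.0], [0.0]], (1, 3))
        config = sd.SimulationConfig(n_genes=2, frequency_spectrum=spectrum, seed=5)
        truth = sd.simulate_presence(config)
        assert truth.presence.iloc[0].all()
        assert not truth.presence.iloc[1].any()

    def test_realized_frequency_within_binomial_bound(self):
        n = 1000
        config = sd.SimulationConfig(
            n_genes=1,
            n_individuals_per_population={"Native": n},
            population_classes={"Native": "native"},
            frequency_spectrum=np.array([[0.5]]),
            seed=6,
        )
        truth = sd.simulate_presence(config)
        realized = truth.presence.iloc[0].mean()
        assert abs(realized - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_population_map_matches_matrix(self):
        config = sd.SimulationConfig(n_genes=3, seed=7)
        truth = sd.simulate_presence(config)
        assert set(truth.presence.columns) == set(truth.population_map.individuals())


@pytest.fixture(scope="module")
def small_run(tmp_path_factory):
    config = sd.SimulationConfig(
        n_genes=12,
        n_individuals_per_population={"Native": 4},
        population_classes={"Native": "native"},
        seed=8,
    )
    models, _ = sd.simulate_gene_models(config)
    truth = sd.simulate_presence(config)
    out = tmp_path_factory.mktemp("depth")
    paths = sd.simulate_depth(truth, models, config, out)
    return config, models, truth, paths


class TestDepth:
    def test_breadths_separate_present_from_absent(self, small_run):
        config, models, truth, paths = small_run
        bodies = {m.gene_id: pc.select_gene_body(m) for m in models}
        for ind, path in paths.items():
            track = read_depth(path, ind)
            for gid, body in bodies.items():
                breadth = pc.exon_breadth(track, body, 2)
                if truth.presence.loc[gid, ind]:
                    assert breadth >= 0.95
                else:
                    assert breadth <= config.absent_residual_breadth

    def test_byte_identical_reruns(self, small_run, tmp_path):
        config, models, truth, paths = small_run
        again = sd.simulate_depth(truth, models, config, tmp_path)
        for ind, path in paths.items():
            assert path.read_bytes() == again[ind].read_bytes()

    def test_zero_mean_depth_silences_present_genes(self, tmp_path):
        config = sd.SimulationConfig(
            n_genes=4,
            n_individuals_per_population={"Native": 2},
            population_classes={"Native": "native"},
            mean_depth=0.0,
            absent_residual_breadth=0.0,
            seed=9,
        )
        models, _ = sd.simulate_gene_models(config)
        truth = sd.simulate_presence(config)
        paths = sd.simulate_depth(truth, models, config, tmp_path)
        for ind, path in paths.items():
            assert read_depth(path, ind).total_depth() == 0

    def test_mismatched_gene_ids_rejected(self, small_run, tmp_path):
        config, models, truth, _ = small_run
        with pytest.raises(ValueError, match="gene ids"):
            sd.simulate_depth(truth, models[:-1], config, tmp_path)


class TestGenePools:
    def test_closed_pool_identical_individuals(self):
        matrix = sd.simulate_gene_pools(100, "closed", n_individuals=30, seed=10)
        assert matrix.shape == (100, 30)
        assert matrix.all().all()

    def test_open_pool_accumulates(self):
        matrix = sd.simulate_gene_pools(
            20, "open", novelty_rate=3.0, n_individuals=50, seed=11
        )
        # cumulative union over individuals strictly exceeds the core
        union = matrix.to_numpy().any(axis=1).sum()
        assert union > 20
        # every individual still carries the core
        assert matrix.iloc[:20].all().all()

    def test_single_individual_pool(self):
        matrix = sd.simulate_gene_pools(
            5, "open", novelty_rate=2.0, n_individuals=1, seed=12
        )
        assert matrix.shape[1] == 1

    def test_negative_rate_rejected(self):
        with pytest.raises(sd.ConfigurationError, match="novelty_rate"):
            sd.simulate_gene_pools(5, "open", novelty_rate=-1, n_individuals=3, seed=1)


@pytest.fixture(scope="module")
def fixture():
    return sd.simulate_contigs_and_alignments(n_contigs=60, seed=13)


class TestContigFixture:
    def test_oracle_covers_boundary_cases(self, fixture):
        lengths = fixture.lengths
        assert 500 in lengths.values() and 501 in lengths.values()
        boundary_ref = [
            r for r in fixture.ref_paf
            if r.matches / r.block_len == pytest.approx(0.90)
            and (r.query_end - r.query_start) / r.query_len == pytest.approx(0.80)
        ]
        assert boundary_ref

    def test_sequences_match_declared_lengths(self, fixture):
        for cid, seq in fixture.sequences.items():
            assert len(seq) == fixture.lengths[cid]

    def test_planned_labels_are_consistent(self, fixture):
        oracle = fixture.oracle
        assert set(oracle["category"]) <= {
            "short", "reference_redundant", "self_redundant", "clean"
        }
        assert (oracle.loc[oracle["category"] == "clean", "keep"]).all()
        assert (~oracle.loc[oracle["category"] != "clean", "keep"]).all()

    def test_filters_reproduce_oracle(self, fixture):
        report = nf.run_contig_filters(
            fixture.lengths, fixture.ref_paf, fixture.self_paf
        )
        oracle = fixture.oracle
        assert (report.loc[oracle.index, "kept"] == oracle["keep"]).all()

    def test_deterministic(self):
        one = sd.simulate_contigs_and_alignments(n_contigs=40, seed=14)
        two = sd.simulate_contigs_and_alignments(n_contigs=40, seed=14)
        assert one.sequences == two.sequences
        assert one.ref_paf == two.ref_paf and one.self_paf == two.self_paf
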