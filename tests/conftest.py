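"""Shared fixtures: a small synthetic cohort run end-to-end once per session."""

import pytest

from pavkit import io_formats as iof
from pavkit import presence_caller as pc
from pavkit import synthetic_data as sd


@pytest.fixture(scope="session")
def cohort_config():
    # 50 genes x 60 individuals (20 wild / 20 native / 20 improved),
    # 20x depth, 2% residual breadth for absent genes
    return sd.SimulationConfig(seed=42, absent_residual_breadth=0.02, mean_depth=20.0)


@pytest.fixture(scope="session")
def cohort(cohort_config, tmp_path_factory):
    """Models, ground truth, depth tracks and called matrix for one cohort."""
    out = tmp_path_factory.mktemp("depth")
    models, _ = sd.simulate_gene_models(cohort_config)
    truth = sd.simulate_presence(cohort_config)
    paths = sd.simulate_depth(truth, models, cohort_config, out)
    tracks = {ind: iof.read_depth(path, ind) for ind, path in paths.items()}
    bodies = [pc.select_gene_body(m) for m in models]
    matrix = pc.build_presence_matrix(tracks, bodies, pc.CallerConfig())
    return {
        "config": cohort_config,
        "models": models,
        "truth": truth,
        "paths": paths,
        "tracks": tracks,
        "bodies": bodies,
        "matrix": matrix,
    }
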