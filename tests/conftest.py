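import numpy as np
import pytest

from degentraj.config import PipelineConfig
from degentraj.pipeline import run_pipeline
from degentraj.simulate import Population, SyntheticSpec, simulate_counts, simulate_dataset


@pytest.fixture(scope="session")
def default_spec():
    """Standard validation scenario: five populations, 3-stage rod trajectory,
    planted pattern genes, doublets and low-quality cells, coupled mutant cones."""
    return SyntheticSpec(doublet_rate=0.05, lowq_rate=0.03,
                         coupled_population="cone_rd10", seed=1)


@pytest.fixture(scope="session")
def default_dataset(default_spec):
    return simulate_dataset(default_spec)


@pytest.fixture(scope="session")
def singlet_dataset():
    """Singlets only (no artifacts), for stages that assume clean input."""
    return simulate_counts(SyntheticSpec(seed=2))


@pytest.fixture(scope="session")
def homogeneous_dataset():
    """One homogeneous population with null (trajectory-independent) genes,
    for statistical calibration checks."""
    spec = SyntheticSpec(
        populations=[Population("pop", 400)], trajectory_population="pop",
        stage_centers=(0.5,), stage_weights=(1.0,), stage_names=("s",),
        stage_genotypes=("wt",), pattern_genes={}, n_background_genes=2000,
        marker_genes_per_population=0, background_base_log_mean=0.0,
        background_base_log_sigma=0.8, coupled_population=None, seed=11)
    return simulate_counts(spec)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full end-to-end pipeline run on the standard synthetic scenario."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(
        out_dir=str(out), seed=1,
        synthetic={"doublet_rate": 0.05, "lowq_rate": 0.03,
                   "coupled_population": "cone_rd10"})
    return run_pipeline(cfg)
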