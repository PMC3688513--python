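import pytest

from linccat.expression import build_expression_matrix
from linccat.filters import run_cascade
from linccat.simulate import SimConfig, simulate


def small_sim_config(seed: int = 5) -> SimConfig:
    """A lighter feature load for tests that re-simulate many times."""
    return SimConfig(
        seed=seed,
        counts={
            "true_lincRNA": 30,
            "protein_coding": 16,
            "short_decoy": 8,
            "proximity_decoy": 8,
            "pseudogene": 6,
            "small_ncRNA": 6,
            "utr_extension_victim": 6,
            "large_orf_decoy": 10,
            "orf_neighbor_decoy": 5,
            "extended_gene_decoy": 4,
            "low_expression_decoy": 6,
        },
    )


@pytest.fixture(scope="session")
def default_sim():
    return simulate(SimConfig(seed=42))


@pytest.fixture(scope="session")
def default_matrix(default_sim):
    s = default_sim
    return build_expression_matrix(
        s.reads_by_dataset, s.candidates + s.genes, s.datasets
    )


@pytest.fixture(scope="session")
def cascade_result(default_sim, default_matrix):
    s = default_sim
    return run_cascade(
        s.candidates, s.catalog, s.transcript_sequences(), default_matrix
    )


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_sim_config())


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    from linccat.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline") / "run"
    return run_pipeline(PipelineConfig(out_dir=str(out)))
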