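import numpy as np
import pytest

from ervography.cli_reporting import run_pipeline
from ervography.io_core import PipelineConfig, SpeciesTree
from ervography.synthetic_data import ERVModel, default_branch_rates, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tree():
    return SpeciesTree.default_catarrhini()


@pytest.fixture(scope="session")
def config():
    return PipelineConfig(rng_seed=1)


@pytest.fixture(scope="session")
def small_model():
    """Scaled-down element (LTR 400 nt, internal 2000 nt) for fast tests."""
    return ERVModel.random(np.random.default_rng(7), ltr_len=400, internal_len=2000)


@pytest.fixture(scope="session")
def small_sim(tree, small_model, config):
    """30 planted loci over the 6-species tree, 3 LTR recombinations, no deletions."""
    rng = np.random.default_rng(1)
    return simulate(tree, small_model, default_branch_rates(tree), config, rng,
                    background_len=900_000, n_events=30, n_recombinations=3)


@pytest.fixture(scope="session")
def small_pipeline(small_sim, tree, small_model, config):
    return run_pipeline(small_sim.genomes, tree, small_model, config)
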