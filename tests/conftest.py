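import logging

import pytest

from spongeclip.pipeline import PipelineConfig, run_all
from spongeclip.seeds import default_families
from spongeclip.simulate import SimConfig

logging.getLogger("spongeclip").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def families():
    return default_families()


@pytest.fixture(scope="session")
def family_by_id(families):
    return {f.family_id: f for f in families}


@pytest.fixture(scope="session")
def small_sim():
    """A reduced simulation for fast unit tests (not the study conditions)."""
    return SimConfig(rng_seed=3, n_genes=60, n_true_targets=12)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default simulation conditions, seed 1."""
    outdir = tmp_path_factory.mktemp("default_run")
    return run_all(PipelineConfig(), outdir, seed=1), outdir
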