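import logging

import numpy as np
import pytest

from gbscall.pipeline import RunConfig, run_pipeline
from gbscall.sim import SimConfig, simulate

logging.getLogger("gbscall").setLevel(logging.WARNING)


TINY = SimConfig(
    n_fragments=120, n_snps=30, n_indels=12, n_individuals=8,
    depth_range=(20, 30), error_rate=0.011, seed=7,
)

CLEAN = SimConfig(
    n_fragments=150, n_snps=40, n_indels=15, n_individuals=10,
    depth_range=(20, 30), error_rate=0.0, seed=3,
)


@pytest.fixture(scope="session")
def tiny_sim():
    """In-memory simulation at toy scale with realistic error."""
    return simulate(TINY)


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free simulation for exact-recovery properties."""
    return simulate(CLEAN)


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """Full pipeline artifacts for the toy simulation."""
    out = tmp_path_factory.mktemp("tiny_run")
    cfg = RunConfig(sim=TINY, write_sam=True)
    res = run_pipeline(cfg, out)
    return cfg, res


@pytest.fixture(scope="session")
def clean_run(tmp_path_factory):
    """Full pipeline artifacts for the error-free simulation."""
    out = tmp_path_factory.mktemp("clean_run")
    cfg = RunConfig(sim=CLEAN)
    res = run_pipeline(cfg, out)
    return cfg, res


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
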