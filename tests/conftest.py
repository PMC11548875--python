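import warnings

import numpy as np
import pytest

from icipipe.config import PipelineConfig
from icipipe.pipeline import run_pipeline
from icipipe.simulate import SimConfig, simulate_cohort

warnings.filterwarnings("ignore", category=UserWarning)

#: generator overrides for a desk-light cohort without tumor perturbations
SMALL_SIM = dict(
    n_genes=300, cells_per_sample=120, cnv_events=[], tumor_program_panel={}
)


@pytest.fixture(scope="session")
def default_ctx():
    """One full-default pipeline run (seed 1), shared across recovery tests."""
    return run_pipeline(PipelineConfig(seed=1), write=False)


@pytest.fixture(scope="session")
def small_cohort():
    """Small effect-free cohort with truth labels (no CNV, no programs)."""
    cfg = SimConfig(seed=7, **SMALL_SIM)
    cohort, truth, contigs = simulate_cohort(cfg)
    return cohort, truth, contigs


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
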