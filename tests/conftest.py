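"""Shared fixtures: one default simulated data set and its pipeline run.

Both are session-scoped — the simulation (seed 1) and the full pipeline
over it are the reference workload for the end-to-end recovery tests.
"""

import numpy as np
import pytest

from singlecopy.pipeline import PipelineResult, run_all
from singlecopy.simulate import SimConfig, SimResult, simulate


@pytest.fixture(scope="session")
def sim_result() -> SimResult:
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(sim_result) -> PipelineResult:
    return run_all(sim_result.genome_set, sim_result.positions)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
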