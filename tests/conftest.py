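"""Shared fixtures: one seeded synthetic dataset and one full pipeline run
per session (both deterministic), plus a default config."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lncnet.config import RunConfig
from lncnet.pipeline import run_all
from lncnet.simulate import SimulationSpec, simulate_dataset
from lncnet.types import ExpressionMatrix


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def dataset():
    return simulate_dataset(SimulationSpec(rng_seed=0))


@pytest.fixture(scope="session")
def pipeline_result(dataset, config):
    return run_all(config=config, dataset=dataset)


@pytest.fixture()
def small_counts() -> ExpressionMatrix:
    rng = np.random.default_rng(11)
    df = pd.DataFrame(
        rng.poisson(50, size=(20, 6)),
        index=[f"f{i}" for i in range(20)],
        columns=["CK1", "CK2", "CK3", "DR1", "DR2", "DR3"],
    )
    return ExpressionMatrix(values=df, groups={c: c[:2] for c in df.columns})
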