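"""Shared setup for the analysis drivers: one seeded dataset, one config.

Every driver regenerates the simulated dataset deterministically (cheap)
and re-runs the upstream stages it depends on in memory, so the scripts can
be run independently and in any order.
"""

from __future__ import annotations

import sys
from pathlib import Path

from lncnet.config import RunConfig
from lncnet.simulate import SimulationSpec, simulate_dataset

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
RESULTS = Path(__file__).resolve().parent.parent / "results"


def load() -> tuple:
    config = RunConfig(rng_seed=SEED)
    dataset = simulate_dataset(SimulationSpec(rng_seed=SEED))
    return dataset, config
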