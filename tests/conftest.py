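from __future__ import annotations

import random

import pytest

from selexevo.classify import DASE_PROGENITOR_SCAFFOLD, DASE_SCAFFOLD
from selexevo.pool_io_qc import PoolTable
from selexevo.selexsim import (
    SimulationConfig,
    default_rounds,
    pool_tables_from_truth,
    simulate_experiment,
)

#: Desk-scale replicate scenario: planted suboptimal-pocket progenitor
#: (lower bulge GAUACU, activity 0.2), optimal variant absent from the
#: starting library, pressure stepped up at round 7.
N_REPLICATES = 20
REPLICATE_CONFIG = dict(
    library_size=20_000,
    rounds=default_rounds(n_rounds=10, depth=5_000, step_round=7),
)


@pytest.fixture(scope="session")
def sim_replicates():
    """20 seeded replicate simulations with per-round sampled pools."""
    out = []
    for rep in range(N_REPLICATES):
        config = SimulationConfig(seed=1000 + rep, **REPLICATE_CONFIG)
        result = simulate_experiment(config)
        pools = pool_tables_from_truth(result)
        out.append((result, pools))
    return out


@pytest.fixture
def small_pool() -> PoolTable:
    return PoolTable(
        round_label="p1",
        entries={"AAA": 5, "AAC": 2, "GGG": 1},
    )


@pytest.fixture
def scaffolds() -> tuple[str, str]:
    return DASE_SCAFFOLD, DASE_PROGENITOR_SCAFFOLD


def random_rna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(length))


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))
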