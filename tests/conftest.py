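import numpy as np
import pytest
from hypothesis import settings

import ibrnet as ib

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cell_cycle_wt():
    return ib.load_cell_cycle("wild-type")


@pytest.fixture(scope="session")
def cell_cycle_mut():
    return ib.load_cell_cycle("p27-mutant")


@pytest.fixture(scope="session")
def baseline_state():
    return ib.StateHyperparameters()  # a=1, b=100, a_c=b_c=10


@pytest.fixture(scope="session")
def baseline_obs():
    return ib.ObservationHyperparameters()  # alpha0=100, beta0=1e4, kappa0=100, mu0=10, delta0=40


@pytest.fixture(scope="session")
def cell_cycle_pair(baseline_state, baseline_obs):
    return ib.build_cell_cycle_pair(baseline_state, baseline_obs)


@pytest.fixture
def moderate_obs():
    """Small hyperparameters where linear-space arithmetic stays in range,
    used against numerical-quadrature oracles."""
    return ib.ObservationHyperparameters(alpha0=3.0, beta0=2.0, kappa0=1.5, mu0=0.0, delta0=1.0)


def identity_network(n):
    return ib.BooleanNetwork(
        genes=[f"g{i}" for i in range(n)],
        functions=[ib.GeneFunction(target=f"g{i}", regulators=(i,), table=(0, 1)) for i in range(n)],
        label="identity",
    )


def toy_network_n2():
    """Two genes: g0 copies g1, g1 = g0 OR g1."""
    return ib.BooleanNetwork(
        genes=["g0", "g1"],
        functions=[
            ib.GeneFunction(target="g0", regulators=(1,), table=(0, 1)),
            ib.GeneFunction(target="g1", regulators=(0, 1), table=(0, 1, 1, 1)),
        ],
        label="toy2",
    )


def toy_network_n3():
    """Three genes with mixed logic: g0 = NOT g2, g1 = g0 XOR g1, g2 = g0 AND g1."""
    return ib.BooleanNetwork(
        genes=["g0", "g1", "g2"],
        functions=[
            ib.GeneFunction(target="g0", regulators=(2,), table=(1, 0)),
            ib.GeneFunction(target="g1", regulators=(0, 1), table=(0, 1, 1, 0)),
            ib.GeneFunction(target="g2", regulators=(0, 1), table=(0, 0, 0, 1)),
        ],
        label="toy3",
    )


def random_network(n, rng, max_indeg=2):
    funcs = []
    for i in range(n):
        k = int(rng.integers(0, max_indeg + 1))
        regs = tuple(int(r) for r in rng.choice(n, size=k, replace=False))
        table = tuple(int(v) for v in rng.integers(0, 2, size=2**k))
        funcs.append(ib.GeneFunction(target=f"g{i}", regulators=regs, table=table))
    return ib.BooleanNetwork(genes=[f"g{i}" for i in range(n)], functions=funcs, label="random")
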