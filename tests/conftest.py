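import numpy as np
import pytest

import shelfweb as sw


def make_chain_inputs(landings=0.1):
    """Producer → consumer1 → consumer2 chain with a detritus pool.

    Hand-solvable: EE = (0.2, 0.5, 0.5) when all EE are unknown.
    """
    groups = [
        sw.GroupInput("prod", "producer", biomass=10, pb=5),
        sw.GroupInput("c1", "consumer", biomass=1, pb=2, qb=10),
        sw.GroupInput("c2", "consumer", biomass=0.2, pb=1, qb=5,
                      landings=landings),
        sw.GroupInput("det", "detritus", biomass=1.0),
    ]
    names = [g.name for g in groups]
    dc = np.zeros((4, 4))
    dc[0, 1] = 1.0  # c1 eats prod
    dc[1, 2] = 1.0  # c2 eats c1
    return sw.EcopathInputs(groups, sw.DietMatrix(names, dc))


@pytest.fixture
def chain_inputs():
    return make_chain_inputs()


@pytest.fixture
def chain_model(chain_inputs):
    return sw.solve_balance(chain_inputs)


@pytest.fixture
def synthetic_web():
    return sw.generate_foodweb(sw.WebGenConfig(seed=42))


@pytest.fixture
def synthetic_model(synthetic_web):
    return sw.solve_balance(synthetic_web.inputs)
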