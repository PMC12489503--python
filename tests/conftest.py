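import numpy as np
import pytest

from protocrm.core import (ChemicalSystem, Ecology, FeedSchedule,
                           MetabolicNetwork, ProtocellType, SimulationConfig)


@pytest.fixture
def chem4():
    """Four chemicals: two fed nutrients (v=1), two by-products (v=0.5)."""
    return ChemicalSystem(
        growth_values=np.array([1.0, 1.0, 0.5, 0.5]),
        feed=FeedSchedule.constant([200.0, 200.0, 0.0, 0.0]),
        dilution_rate=0.1,
    )


def make_type(type_id=0, diet=(0, 1), byproducts=(2, 3),
              weights=((0.4, 0.0), (0.0, 0.4)), enzymes=(30.0, 30.0),
              enzyme_costs=0.1, maintenance=10.0, e_budget=60.0,
              regulation=None, reg_enabled=False, parent_id=None,
              birth_time=0.0):
    return ProtocellType(
        type_id=type_id, parent_id=parent_id, birth_time=birth_time,
        metabolism=MetabolicNetwork(tuple(diet), tuple(byproducts),
                                    np.asarray(weights, float)),
        enzymes=np.asarray(enzymes, float),
        enzyme_costs=enzyme_costs, maintenance=maintenance,
        e_budget=e_budget, regulation=regulation, reg_enabled=reg_enabled,
    )


@pytest.fixture
def single_type_ecology(chem4):
    eco = Ecology(chem4, [make_type()], initial_counts=[100])
    return eco


@pytest.fixture
def config():
    return SimulationConfig()
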