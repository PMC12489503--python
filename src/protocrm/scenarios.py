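"""Ready-made reactor scenarios: the three minimal protocell ecologies.

All three case studies share the same chemical palette: two externally fed
nutrients (chemicals 0 and 1, growth value 1) and two metabolic by-products
(chemicals 2 and 3, growth value 0.5).  Feeds are either constant at 200
concentration units each or anti-phase sine waves between 40 and 200 units at
one of three printed periods (slow 2.5e6, medium 2.5e5, fast 2.5e4 time
units).

Case 1 ("single species"): one founding type that imports nutrient 0 and/or
nutrient 1 and excretes by-products 2 and 3.

Case 2 ("minimal mutualism"): two founding types in a symmetric cross-feeding
loop — p0 eats nutrient 0 plus p1's by-product 3 and excretes by-product 2;
p1 eats nutrient 1 plus by-product 2 and excretes by-product 3.

Case 3 ("binary asymmetric ecology"): cross-feeding plus competition — p0
eats nutrients 0 and 1 and excretes by-product 2; p1 eats nutrient 1 (shared
with p0) and by-product 2, excreting by-product 3.  The initial metabolic
weights shipped here are a representative validated stand-in (overridable);
survival of this ecology is known to be sensitive to them.
"""

from __future__ import annotations

import numpy as np

from .core import (ChemicalSystem, Ecology, FeedChannel, FeedSchedule,
                   MetabolicNetwork, ProtocellType, SimulationConfig,
                   StructuralError)
from .regulation import RegulatoryNetwork

__all__ = [
    "FORCING_PERIODS", "feed_value", "constant_feeds", "antiphase_sine_feeds",
    "make_feeds", "build_case_study",
]

FORCING_PERIODS = {"slow": 2.5e6, "medium": 2.5e5, "fast": 2.5e4}

#: default per-chemical growth values: fed nutrients worth 1, by-products 0.5
GROWTH_VALUES = (1.0, 1.0, 0.5, 0.5)
FEED_LEVEL = 200.0
SINE_LOW, SINE_HIGH = 40.0, 200.0
DILUTION_RATE = 0.1
MAINTENANCE = 10.0
ENZYME_COST = 0.1


def feed_value(schedule: FeedSchedule, i: int, tau: float) -> float:
    """Feed concentration of chemical ``i`` at time ``tau``."""
    return schedule.value(i, tau)


def constant_feeds(levels) -> FeedSchedule:
    return FeedSchedule.constant(levels)


def antiphase_sine_feeds(n_chemicals: int = 4, low: float = SINE_LOW,
                         high: float = SINE_HIGH,
                         period: float = FORCING_PERIODS["medium"]) -> FeedSchedule:
    """Nutrients 0 and 1 as sine waves 180 degrees out of phase; rest unfed."""
    channels = [
        FeedChannel("sine", low=low, high=high, period=period, phase_deg=0.0),
        FeedChannel("sine", low=low, high=high, period=period, phase_deg=180.0),
    ]
    channels += [FeedChannel("constant", level=0.0)] * (n_chemicals - 2)
    return FeedSchedule(tuple(channels))


def make_feeds(forcing: str = "constant", n_chemicals: int = 4) -> FeedSchedule:
    if forcing == "constant":
        levels = [FEED_LEVEL, FEED_LEVEL] + [0.0] * (n_chemicals - 2)
        return constant_feeds(levels)
    if forcing in FORCING_PERIODS:
        return antiphase_sine_feeds(n_chemicals, period=FORCING_PERIODS[forcing])
    raise StructuralError(
        f"unknown forcing {forcing!r}; expected constant/slow/medium/fast")


def _founder(type_id, diet, byproducts, weights, config, reg):
    d = len(diet)
    return ProtocellType(
        type_id=type_id, parent_id=None, birth_time=0.0,
        metabolism=MetabolicNetwork(tuple(diet), tuple(byproducts),
                                    np.asarray(weights, float)),
        enzymes=np.full(d, config.e_budget / d),  # equal split on the budget
        enzyme_costs=np.full(d, ENZYME_COST),
        maintenance=MAINTENANCE,
        e_budget=config.e_budget,
        budget_weights=np.ones(d),
        regulation=RegulatoryNetwork.disabled(d, k_tau=config.k_tau) if reg else None,
        reg_enabled=bool(reg),
    )


def build_case_study(case: int, reg: bool = False, forcing: str = "constant",
                     n0: int = 100, config: SimulationConfig | None = None,
                     case3_weights=None):
    """Construct one of the three study ecologies.

    Parameters
    ----------
    case : 1, 2 or 3 (see module docstring).
    reg : False for the -REG control (no regulatory networks, ever), True for
        +REG (types start with a disabled network that evolution may enable).
    forcing : "constant", "slow", "medium" or "fast".
    n0 : founding individuals per type (default 100).
    config : optional SimulationConfig to take kinetic defaults from.
    case3_weights : optional (w_p0, w_p1) override for the case-3 stand-in
        metabolic weights.

    Returns ``(ecology, config)``; every founding metabolism is validated
    against the thermodynamic rule at construction.
    """
    cfg = config if config is not None else SimulationConfig()
    feeds = make_feeds(forcing)
    chem = ChemicalSystem(np.array(GROWTH_VALUES), feeds, DILUTION_RATE)

    if case == 1:
        types = [
            _founder(0, (0, 1), (2, 3), [[0.4, 0.0], [0.0, 0.4]], cfg, reg),
        ]
    elif case == 2:
        types = [
            _founder(0, (0, 3), (2,), [[0.4], [0.4]], cfg, reg),
            _founder(1, (1, 2), (3,), [[0.4], [0.4]], cfg, reg),
        ]
    elif case == 3:
        if case3_weights is None:
            w_p0 = [[0.4], [0.3]]   # nutrients 0, 1 -> by-product 2
            w_p1 = [[0.3], [0.4]]   # nutrient 1, by-product 2 -> by-product 3
        else:
            w_p0, w_p1 = case3_weights
        types = [
            _founder(0, (0, 1), (2,), w_p0, cfg, reg),
            _founder(1, (1, 2), (3,), w_p1, cfg, reg),
        ]
    else:
        raise StructuralError(f"unknown case study {case!r}; expected 1, 2 or 3")

    ecology = Ecology(chem, types, initial_counts=[n0] * len(types))
    return ecology, cfg
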