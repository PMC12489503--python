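"""Domain types and pure kinetic primitives for the protocell chemostat model.

The model couples a well-stirred flow reactor (chemostat, dilution rate ``mu``)
to a population of protocell "types".  Each type is defined by a metabolic
network mapping imported nutrients to excreted by-products, a vector of
import/processing enzyme levels (Monod uptake, half-saturation fixed at one
concentration unit), and optionally a small regulatory network that modulates
the rate of change of those enzyme levels.

Two hard physical constraints are enforced everywhere:

* **Thermodynamic validity** — a metabolism may not emit more "growth value"
  than it takes in.  Each chemical ``i`` carries a growth value ``v_i > 0``;
  the usable value per unit of nutrient ``n`` is
  ``delta_v_n = v_n - sum_i M[n, i] * v_i`` and must be strictly positive for
  every nutrient, so no operating metabolism can create value from nothing.
* **Enzyme budget** — total weighted enzyme content is capped,
  ``sum_n w_n * E_n <= E_budget``, forcing an allocation trade-off between
  nutrient preferences.  Projection back onto the feasible set is
  multiplicative (ratios, i.e. preferences, are preserved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .regulation import RegulatoryNetwork

__all__ = [
    "ProtocrmError",
    "StructuralError",
    "DomainError",
    "IntegrationError",
    "FeedChannel",
    "FeedSchedule",
    "ChemicalSystem",
    "MetabolicNetwork",
    "ValidationReport",
    "ProtocellType",
    "Ecology",
    "SimulationConfig",
    "monod_uptake_rate",
    "net_growth_value",
    "validate_metabolism",
    "enforce_enzyme_budget",
]


class ProtocrmError(Exception):
    """Base class for all package errors."""


class StructuralError(ProtocrmError):
    """Shape, index or wiring mismatch in model structure."""


class DomainError(ProtocrmError):
    """Numerically invalid input (negative concentration, bad parameter)."""


class IntegrationError(ProtocrmError):
    """Failure during trajectory integration; carries a state dump."""


# ---------------------------------------------------------------------------
# Feeds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeedChannel:
    """Feed law for a single chemical: constant level or sinusoid.

    A sinusoid oscillates between ``low`` and ``high`` with period ``period``
    (time units) and a phase offset in degrees:
    ``f(tau) = mid + amp * sin(2*pi*tau/period + phase)`` with
    ``mid = (low + high) / 2`` and ``amp = (high - low) / 2``.
    """

    kind: str = "constant"  # "constant" | "sine"
    level: float = 0.0
    low: float = 0.0
    high: float = 0.0
    period: float = 1.0
    phase_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sine"):
            raise StructuralError(f"unknown feed kind {self.kind!r}")
        if self.kind == "constant":
            if self.level < 0:
                raise DomainError("constant feed level must be >= 0")
        else:
            if self.low > self.high:
                raise DomainError("sine feed requires low <= high")
            if self.low < 0:
                raise DomainError("sine feed must stay >= 0")
            if self.period <= 0:
                raise DomainError("sine feed period must be > 0")

    def value(self, tau: float) -> float:
        if self.kind == "constant":
            return self.level
        mid = 0.5 * (self.low + self.high)
        amp = 0.5 * (self.high - self.low)
        return mid + amp * math.sin(
            2.0 * math.pi * tau / self.period + math.radians(self.phase_deg)
        )


@dataclass(frozen=True)
class FeedSchedule:
    """Per-chemical feed laws for the reactor inflow."""

    channels: tuple[FeedChannel, ...]

    @classmethod
    def constant(cls, levels: Sequence[float]) -> "FeedSchedule":
        return cls(tuple(FeedChannel("constant", level=float(v)) for v in levels))

    @property
    def n_chemicals(self) -> int:
        return len(self.channels)

    @property
    def is_constant(self) -> bool:
        return all(ch.kind == "constant" for ch in self.channels)

    def value(self, i: int, tau: float) -> float:
        if not 0 <= i < len(self.channels):
            raise StructuralError(f"no feed channel for chemical {i}")
        return self.channels[i].value(tau)

    def values(self, tau: float) -> np.ndarray:
        return np.array([ch.value(tau) for ch in self.channels], dtype=float)

    def min_period(self) -> float | None:
        periods = [ch.period for ch in self.channels if ch.kind == "sine"]
        return min(periods) if periods else None


# ---------------------------------------------------------------------------
# Chemicals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChemicalSystem:
    """The reactor chemicals: growth values, feed schedule, dilution rate.

    ``growth_values[i]`` is the scalar worth ``v_i`` of one concentration unit
    of chemical ``i`` toward biomass production; it is the currency of the
    thermodynamic bookkeeping.  ``dilution_rate`` is the chemostat flow rate
    ``mu`` (per time unit); every species in the tank, chemical or protocell,
    is washed out at this rate.
    """

    growth_values: np.ndarray
    feed: FeedSchedule
    dilution_rate: float

    def __post_init__(self) -> None:
        gv = np.asarray(self.growth_values, dtype=float)
        object.__setattr__(self, "growth_values", gv)
        if gv.ndim != 1 or gv.size == 0:
            raise StructuralError("growth_values must be a non-empty 1-D vector")
        if np.any(gv <= 0):
            raise DomainError("all chemical growth values must be > 0")
        if self.feed.n_chemicals != gv.size:
            raise StructuralError(
                f"feed schedule has {self.feed.n_chemicals} channels for "
                f"{gv.size} chemicals"
            )
        if self.dilution_rate <= 0:
            raise DomainError("dilution rate mu must be > 0")

    @property
    def n_chemicals(self) -> int:
        return int(self.growth_values.size)


# ---------------------------------------------------------------------------
# Metabolism
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetabolicNetwork:
    """Weighted bipartite map from imported nutrients to excreted by-products.

    ``weights[a, b]`` is the stoichiometric weight from the ``a``-th nutrient
    in ``nutrient_set`` to the ``b``-th chemical in ``byproduct_set``: per unit
    of nutrient processed, that many concentration units of the by-product are
    excreted to the reactor.
    """

    nutrient_set: tuple[int, ...]
    byproduct_set: tuple[int, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        nset = tuple(int(i) for i in self.nutrient_set)
        bset = tuple(int(i) for i in self.byproduct_set)
        object.__setattr__(self, "nutrient_set", nset)
        object.__setattr__(self, "byproduct_set", bset)
        w = np.asarray(self.weights, dtype=float).reshape(len(nset), len(bset))
        object.__setattr__(self, "weights", w)
        if len(set(nset)) != len(nset) or len(set(bset)) != len(bset):
            raise StructuralError("duplicate chemical index in diet")
        if set(nset) & set(bset):
            raise StructuralError("nutrient and by-product sets must be disjoint")
        if np.any(w < 0):
            raise DomainError("metabolic weights must be >= 0")

    @property
    def n_nutrients(self) -> int:
        return len(self.nutrient_set)

    def delta_v(self, growth_values: np.ndarray) -> np.ndarray:
        """Usable growth value per unit of each nutrient, ``v_n - M @ v_byp``."""
        gv = np.asarray(growth_values, dtype=float)
        hi = max(self.nutrient_set + self.byproduct_set, default=-1)
        if hi >= gv.size:
            raise StructuralError(
                f"metabolism references chemical {hi} but only {gv.size} exist"
            )
        v_n = gv[list(self.nutrient_set)]
        if not self.byproduct_set:
            return v_n.copy()
        v_b = gv[list(self.byproduct_set)]
        return v_n - self.weights @ v_b


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of a thermodynamic check; falsy when violations exist."""

    ok: bool
    violations: tuple[tuple[int, float], ...] = ()  # (chemical index, delta_v)

    def __bool__(self) -> bool:
        return self.ok

    def describe(self) -> str:
        if self.ok:
            return "ok"
        parts = [
            f"nutrient {i}: usable growth value {dv:.6g} <= 0"
            for i, dv in self.violations
        ]
        return "thermodynamic violation: " + "; ".join(parts)


def validate_metabolism(
    metabolism: MetabolicNetwork, chemicals: ChemicalSystem
) -> ValidationReport:
    """Check that a metabolism cannot create growth value from nothing.

    Accepts iff ``delta_v_n > 0`` for every nutrient ``n``: the value of each
    processed nutrient strictly exceeds the total value of the by-products it
    emits, so value inflow to the metabolism exceeds outflow at any reactor
    composition.
    """
    dv = metabolism.delta_v(chemicals.growth_values)
    bad = [
        (metabolism.nutrient_set[a], float(dv[a]))
        for a in range(metabolism.n_nutrients)
        if dv[a] <= 0
    ]
    return ValidationReport(ok=not bad, violations=tuple(bad))


# ---------------------------------------------------------------------------
# Kinetic primitives
# ---------------------------------------------------------------------------


def monod_uptake_rate(enzyme, concentration):
    """Monod uptake rate ``E * c / (1 + c)``.

    Half-saturation is fixed at one concentration unit; the enzyme level sets
    the saturating maximum.  Accepts scalars or arrays (elementwise).
    """
    E = np.asarray(enzyme, dtype=float)
    c = np.asarray(concentration, dtype=float)
    if np.any(E < 0) or np.any(c < 0):
        raise DomainError("enzyme level and concentration must be >= 0")
    out = E * c / (1.0 + c)
    return float(out) if out.ndim == 0 else out


def net_growth_value(ptype: "ProtocellType", concentrations) -> float:
    """Net growth value per unit time, ``lambda_sigma``, for one protocell type.

    Uptake value through all diet nutrients, minus the fixed self-maintenance
    cost and the running cost of the enzymes themselves.  May be negative
    (starving protocells).
    """
    c = np.asarray(concentrations, dtype=float)
    if c.ndim != 1:
        raise StructuralError("concentrations must be a 1-D vector")
    diet = list(ptype.metabolism.nutrient_set)
    if diet and max(diet) >= c.size:
        raise StructuralError(
            f"type {ptype.type_id} imports chemical {max(diet)} but the state "
            f"has only {c.size} chemicals"
        )
    c_diet = c[diet]
    uptake = monod_uptake_rate(ptype.enzymes, c_diet)
    dv = ptype.delta_v_cached
    return float(uptake @ dv - ptype.maintenance - ptype.enzymes @ ptype.enzyme_costs)


def enforce_enzyme_budget(enzymes, costs, budget: float) -> np.ndarray:
    """Project an enzyme vector onto the budget constraint ``costs @ E <= budget``.

    Feasible vectors are returned unchanged; infeasible ones are rescaled
    multiplicatively so the constraint holds with equality, preserving the
    ratios between enzyme levels (i.e. nutrient preferences).
    """
    E = np.asarray(enzymes, dtype=float)
    w = np.asarray(costs, dtype=float)
    if E.shape != w.shape:
        raise StructuralError("enzyme and cost vectors must have the same shape")
    if np.any(E < 0):
        raise DomainError("enzyme levels must be >= 0")
    if np.any(w < 0):
        raise DomainError("budget costs must be >= 0")
    if budget < 0:
        raise DomainError("enzyme budget must be >= 0")
    total = float(w @ E)
    if total <= budget:
        return E.copy()
    if total <= 0:
        raise StructuralError(
            "cannot project onto the budget: total enzyme cost is zero but "
            "the constraint is violated"
        )
    return E * (budget / total)


# ---------------------------------------------------------------------------
# Protocell types
# ---------------------------------------------------------------------------


@dataclass
class ProtocellType:
    """One protocell "sub-species".

    All individuals of a type are identical (standard consumer-resource
    assumption): they share the metabolism, the current enzyme levels and the
    regulatory network.  Enzyme levels are mutable state (regulation moves
    them within a lifetime; mutation moves the heritable baseline at
    speciation); everything else is fixed at creation.

    ``enzyme_costs`` is the metabolic running cost per enzyme unit per time
    entering the net growth value; ``budget_weights``/``e_budget`` define the
    separate hard cap on total enzyme content.
    """

    type_id: int
    parent_id: Optional[int]
    birth_time: float
    metabolism: MetabolicNetwork
    enzymes: np.ndarray
    enzyme_costs: np.ndarray
    maintenance: float
    e_budget: float
    budget_weights: np.ndarray | None = None
    regulation: Optional["RegulatoryNetwork"] = None
    reg_enabled: bool = False
    _delta_v: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _growth_values: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        d = self.metabolism.n_nutrients
        self.enzymes = np.asarray(self.enzymes, dtype=float).reshape(d)
        self.enzyme_costs = np.broadcast_to(
            np.asarray(self.enzyme_costs, dtype=float), (d,)
        ).copy()
        if self.budget_weights is None:
            self.budget_weights = np.ones(d)
        else:
            self.budget_weights = np.broadcast_to(
                np.asarray(self.budget_weights, dtype=float), (d,)
            ).copy()
        if np.any(self.enzymes < 0):
            raise DomainError("enzyme levels must be >= 0")
        if np.any(self.enzyme_costs < 0) or np.any(self.budget_weights < 0):
            raise DomainError("enzyme costs must be >= 0")
        if self.e_budget <= 0:
            raise DomainError("enzyme budget must be > 0")
        if self.maintenance < 0:
            raise DomainError("maintenance cost must be >= 0")
        if float(self.budget_weights @ self.enzymes) > self.e_budget * (1 + 1e-9):
            raise DomainError(
                f"type {self.type_id}: enzyme levels violate the budget "
                f"({float(self.budget_weights @ self.enzymes):.6g} > {self.e_budget:.6g})"
            )
        if self.regulation is not None and self.regulation.n_out != d:
            raise StructuralError(
                f"regulatory network has {self.regulation.n_out} outputs for "
                f"{d} import enzymes"
            )

    # delta_v is cached against the chemical system the ecology binds to.
    @property
    def delta_v_cached(self) -> np.ndarray:
        if self._delta_v is None:
            raise StructuralError(
                f"type {self.type_id} not bound to a chemical system; "
                "construct an Ecology first or call bind_chemistry()"
            )
        return self._delta_v

    def bind_chemistry(self, chemicals: ChemicalSystem) -> None:
        report = validate_metabolism(self.metabolism, chemicals)
        if not report:
            raise DomainError(f"type {self.type_id}: {report.describe()}")
        self._delta_v = self.metabolism.delta_v(chemicals.growth_values)
        self._growth_values = chemicals.growth_values

    def copy(self, **changes) -> "ProtocellType":
        new = replace(
            self,
            enzymes=self.enzymes.copy(),
            enzyme_costs=self.enzyme_costs.copy(),
            budget_weights=self.budget_weights.copy(),
            **changes,
        )
        return new


@dataclass
class Ecology:
    """A chemical system plus the founding protocell types.

    Validates every metabolism against the thermodynamic rule at construction
    and caches each type's usable growth values.  ``initial_counts`` gives the
    number of individuals per founding type for stochastic runs (default 100
    each, the standard initial condition).
    """

    chemicals: ChemicalSystem
    types: list[ProtocellType]
    initial_counts: list[int] | None = None

    def __post_init__(self) -> None:
        ids = [t.type_id for t in self.types]
        if len(set(ids)) != len(ids):
            raise StructuralError("duplicate protocell type ids")
        for t in self.types:
            for i in t.metabolism.nutrient_set + t.metabolism.byproduct_set:
                if not 0 <= i < self.chemicals.n_chemicals:
                    raise StructuralError(
                        f"type {t.type_id} references chemical {i} out of range"
                    )
            t.bind_chemistry(self.chemicals)
        if self.initial_counts is None:
            self.initial_counts = [100] * len(self.types)
        if len(self.initial_counts) != len(self.types):
            raise StructuralError("initial_counts must match the number of types")

    @property
    def n_chemicals(self) -> int:
        return self.chemicals.n_chemicals


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Global kinetic, evolutionary and numerical parameters.

    Attributes
    ----------
    g : biomass conversion factor; per-capita division rate is ``g * lambda``.
    e_div : mean number of divisions per mutated (speciating) division.
    e_budget : maximum total weighted enzyme content per protocell.
    k_tau : regulatory response timescale multiplying the enzyme derivative.
    p_mut, sigma_m, sigma_nn, sigma_e : mutation kernel — each metabolic
        weight / network parameter / enzyme baseline is perturbed with
        probability ``p_mut`` by additive Gaussian noise of the given width.
    dt : hybrid tau-leap step (time units); adaptively shortened.
    dt_out : trajectory sampling interval.
    b0 : biomass of one individual (``p_sigma = n_sigma * b0``).
    """

    g: float = 0.05
    e_div: float = 100.0
    e_budget: float = 60.0
    k_tau: float = 0.01
    p_mut: float = 0.3
    sigma_m: float = 0.05
    sigma_nn: float = 0.1
    sigma_e: float = 1.0
    dt: float = 0.5
    dt_out: float = 10.0
    tau_end: float = 10_000.0
    seed: int = 0
    b0: float = 0.02
    mutations_enabled: bool = True
    burn_in: float = 0.2

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise DomainError("g must be > 0")
        if self.e_div < 1:
            raise DomainError("e_div must be >= 1")
        if self.e_budget <= 0:
            raise DomainError("e_budget must be > 0")
        if self.dt <= 0 or self.dt_out <= 0:
            raise DomainError("dt and dt_out must be > 0")
        if self.b0 <= 0:
            raise DomainError("b0 must be > 0")
        if not 0 <= self.p_mut <= 1:
            raise DomainError("p_mut must be in [0, 1]")
        if not 0 <= self.burn_in < 1:
            raise DomainError("burn_in must be in [0, 1)")
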