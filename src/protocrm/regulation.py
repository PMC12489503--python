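"""Neural-ODE enzyme regulation: the protocell "short-term memory".

Each protocell type may carry a small perceptron (one hidden layer of five
tanh nodes, linear output clamped at zero) whose outputs are *production
rates* of its import enzymes.  Enzyme levels then follow

    dE_i/dtau = k_tau * ( NN_i([E, c_diet/(1+c_diet)]) - k_i * E_i
                          - xi_max(E) + xi_min(E) ),

i.e. network-driven production, first-order decay with constant ``k_i``, and
two conditional forcing terms that keep the state physical: ``xi_min``
cancels inward flux at the ``E_i = 0`` floor, and ``xi_max`` projects the
derivative onto the enzyme-budget face ``sum w_i E_i = E_budget`` whenever the
unconstrained derivative points outward.  Both are realized exactly as
derivative projections, so feasibility is preserved by construction.

Inputs to the network are the host's own enzyme levels concatenated with the
concentrations of its diet nutrients, each concentration squashed as
``c / (1 + c)`` so all external inputs live in ``[0, 1)``.

The all-zero network with zero decay constants gives a derivative that is
identically zero — freshly created types are regulatorily inert until
evolution tinkers with the weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .core import StructuralError

if TYPE_CHECKING:  # pragma: no cover
    from .core import ProtocellType

__all__ = [
    "RegulatoryNetwork",
    "nn_forward",
    "regulatory_inputs",
    "enzyme_rate",
    "enzyme_derivative",
    "enzyme_step",
    "integrate_enzymes",
    "is_functionally_disabled",
]

N_HIDDEN = 5


@dataclass
class RegulatoryNetwork:
    """Weights, biases, decay constants and timescale of one regulator.

    ``w_in`` is (hidden x n_in) with ``n_in = 2 * n_out`` (enzyme levels plus
    normalized diet concentrations); ``w_out`` is (n_out x hidden).  ``decay``
    holds the per-enzyme first-order decay constants ``k_i >= 0`` and
    ``k_tau > 0`` sets the overall response timescale.
    """

    w_in: np.ndarray
    b_hidden: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray
    decay: np.ndarray
    k_tau: float = 0.01

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.b_hidden = np.asarray(self.b_hidden, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        self.b_out = np.asarray(self.b_out, dtype=float)
        self.decay = np.asarray(self.decay, dtype=float)
        h, n_in = self.w_in.shape
        n_out = self.w_out.shape[0]
        if self.b_hidden.shape != (h,):
            raise StructuralError("hidden bias shape mismatch")
        if self.w_out.shape != (n_out, h):
            raise StructuralError("output weight shape mismatch")
        if self.b_out.shape != (n_out,) or self.decay.shape != (n_out,):
            raise StructuralError("output bias / decay shape mismatch")
        if np.any(self.decay < 0):
            raise StructuralError("decay constants must be >= 0")
        if self.k_tau <= 0:
            raise StructuralError("k_tau must be > 0")

    @property
    def n_in(self) -> int:
        return int(self.w_in.shape[1])

    @property
    def n_out(self) -> int:
        return int(self.w_out.shape[0])

    @classmethod
    def disabled(cls, n_enzymes: int, k_tau: float = 0.01,
                 hidden: int = N_HIDDEN) -> "RegulatoryNetwork":
        """The all-zero (inert) network a fresh +REG type starts with."""
        n_in = 2 * n_enzymes
        return cls(
            w_in=np.zeros((hidden, n_in)),
            b_hidden=np.zeros(hidden),
            w_out=np.zeros((n_enzymes, hidden)),
            b_out=np.zeros(n_enzymes),
            decay=np.zeros(n_enzymes),
            k_tau=k_tau,
        )

    def copy(self) -> "RegulatoryNetwork":
        return RegulatoryNetwork(
            self.w_in.copy(), self.b_hidden.copy(), self.w_out.copy(),
            self.b_out.copy(), self.decay.copy(), self.k_tau,
        )


def nn_forward(net: RegulatoryNetwork, inputs) -> np.ndarray:
    """Forward pass: tanh hidden layer, linear output clamped at zero.

    The clamp makes outputs valid production rates (>= 0) and guarantees that
    the all-zero network produces exactly nothing.
    """
    x = np.asarray(inputs, dtype=float)
    if x.shape != (net.n_in,):
        raise StructuralError(
            f"regulatory input has shape {x.shape}, expected ({net.n_in},)"
        )
    if not np.all(np.isfinite(x)):
        raise StructuralError("regulatory inputs must be finite")
    h = np.tanh(net.w_in @ x + net.b_hidden)
    return np.maximum(net.w_out @ h + net.b_out, 0.0)


def regulatory_inputs(enzymes: np.ndarray, c_diet: np.ndarray) -> np.ndarray:
    """Assemble the network input vector ``[E, c/(1+c)]``."""
    c = np.asarray(c_diet, dtype=float)
    return np.concatenate([np.asarray(enzymes, dtype=float), c / (1.0 + c)])


def _project_feasible(deriv: np.ndarray, enzymes: np.ndarray,
                      weights: np.ndarray, budget: float,
                      eps: float = 1e-9) -> np.ndarray:
    """Apply the xi_min / xi_max forcing as exact derivative projections."""
    d = deriv.copy()
    # xi_min: no inward flux through the E_i = 0 floor.
    at_floor = enzymes <= eps
    d[at_floor & (d < 0)] = 0.0
    # xi_max: project onto the budget face when pointing outward.
    if float(weights @ enzymes) >= budget * (1.0 - 1e-9) and float(weights @ d) > 0:
        d = d - (float(weights @ d) / float(weights @ weights)) * weights
        # the projection may re-introduce inward flux at the floor
        mask = at_floor & (d < 0)
        if np.any(mask):
            d[mask] = 0.0
            if float(weights @ d) > 0:
                free = ~at_floor
                w_free = np.where(free, weights, 0.0)
                denom = float(w_free @ w_free)
                if denom > 0:
                    d = d - (float(weights @ d) / denom) * w_free
    return d


def enzyme_rate(net: RegulatoryNetwork, enzymes, c_diet,
                budget_weights, budget: float) -> np.ndarray:
    """Time derivative of the enzyme vector under one regulatory network."""
    E = np.asarray(enzymes, dtype=float)
    x = regulatory_inputs(E, c_diet)
    raw = nn_forward(net, x) - net.decay * E
    return net.k_tau * _project_feasible(raw, E, np.asarray(budget_weights, float),
                                         budget)


def _enzyme_rate_fast(net: RegulatoryNetwork, E: np.ndarray,
                      c_diet: np.ndarray, budget_weights: np.ndarray,
                      budget: float) -> np.ndarray:
    """Validation-free inner-loop variant of :func:`enzyme_rate` (same math)."""
    x = np.concatenate([E, c_diet / (1.0 + c_diet)])
    h = np.tanh(net.w_in @ x + net.b_hidden)
    raw = np.maximum(net.w_out @ h + net.b_out, 0.0) - net.decay * E
    return net.k_tau * _project_feasible(raw, E, budget_weights, budget)


def enzyme_derivative(ptype: "ProtocellType", concentrations) -> np.ndarray:
    """dE/dtau for a protocell type given the full reactor concentration vector.

    Returns the zero vector when regulation is disabled for the type
    (the -REG condition, or a functionally inert network).
    """
    d = ptype.metabolism.n_nutrients
    if not ptype.reg_enabled or ptype.regulation is None:
        return np.zeros(d)
    if is_functionally_disabled(ptype.regulation):
        return np.zeros(d)
    c = np.asarray(concentrations, dtype=float)
    c_diet = c[list(ptype.metabolism.nutrient_set)]
    return enzyme_rate(ptype.regulation, ptype.enzymes, c_diet,
                       ptype.budget_weights, ptype.e_budget)


def is_functionally_disabled(net: RegulatoryNetwork | None) -> bool:
    """True iff the enzyme derivative is identically zero over all inputs.

    Sufficient (and here, exact) test: the output layer is all-zero — the
    clamp at zero then annihilates whatever the hidden layer does — and all
    decay constants are zero.
    """
    if net is None:
        return True
    return (
        not np.any(net.w_out)
        and not np.any(net.b_out)
        and not np.any(net.decay)
    )


def enzyme_step(ptype: "ProtocellType", concentrations, dt: float) -> np.ndarray:
    """Advance a type's enzyme levels by one explicit Euler step, in place.

    After the step the state is clipped at zero and rescaled onto the budget
    if the (curvature-induced) overshoot left the feasible set.  This is the
    exact update the stochastic engine applies, exposed so that isolated
    replays reproduce engine enzyme dynamics bit-for-bit given the same
    concentration forcing.
    """
    dE = enzyme_derivative(ptype, concentrations)
    E = np.maximum(ptype.enzymes + dt * dE, 0.0)
    total = float(ptype.budget_weights @ E)
    if total > ptype.e_budget:
        E *= ptype.e_budget / total
    ptype.enzymes = E
    return E


def integrate_enzymes(ptype: "ProtocellType", times, c_series) -> np.ndarray:
    """Integrate the enzyme ODE alone against a recorded concentration forcing.

    ``times`` is increasing, ``c_series`` has one full concentration vector per
    time point.  Returns the (T x d) enzyme trajectory starting from the
    type's current levels; the type itself is left untouched.  Each Euler
    interval uses the concentrations recorded at its right endpoint — the
    same convention as the stochastic engine, where enzymes respond to the
    freshly advanced chemistry, so replaying a recorded run reproduces the
    engine's enzyme dynamics exactly.
    """
    times = np.asarray(times, dtype=float)
    c_series = np.asarray(c_series, dtype=float)
    if c_series.shape[0] != times.size:
        raise StructuralError("c_series must have one row per time point")
    probe = ptype.copy()
    out = np.empty((times.size, ptype.metabolism.n_nutrients))
    out[0] = probe.enzymes
    for k in range(1, times.size):
        enzyme_step(probe, c_series[k], float(times[k] - times[k - 1]))
        out[k] = probe.enzymes
    return out
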