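"""Deterministic ODE limit of the protocell consumer-resource model.

When the type set is fixed and populations are large, the stochastic model
reduces to a MacArthur-style consumer-resource system with chemostat inflow
and washout:

    dc_i/dtau = mu * (f_i(tau) - c_i) - gamma_i^nutrient + gamma_i^byproduct
    dp_s/dtau = p_s * (g * lambda_s - mu)
    dE_si/dtau = regulatory neural ODE (zero when regulation is disabled)

with Monod uptake ``E * c / (1 + c)`` and by-product excretion through each
type's metabolic weight matrix.  This module serves both as a fast simulation
mode and as the convergence oracle the stochastic engine is tested against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .core import Ecology, IntegrationError, StructuralError
from .regulation import enzyme_rate, is_functionally_disabled
from .trajectory import Trajectory

__all__ = ["ReactorState", "crm_rhs", "integrate", "steady_state"]


@dataclass
class ReactorState:
    """Instantaneous reactor state: time, chemicals, per-type biomass and enzymes."""

    tau: float
    concentrations: np.ndarray
    populations: dict[int, float]
    enzymes: dict[int, np.ndarray]

    def copy(self) -> "ReactorState":
        return ReactorState(
            self.tau,
            np.asarray(self.concentrations, float).copy(),
            dict(self.populations),
            {k: np.asarray(v, float).copy() for k, v in self.enzymes.items()},
        )

    @classmethod
    def initial(cls, ecology: Ecology, populations=None,
                concentrations=None) -> "ReactorState":
        """State at tau=0: feed-level chemicals, configured type biomasses."""
        c = (np.asarray(concentrations, float) if concentrations is not None
             else ecology.chemicals.feed.values(0.0))
        if populations is None:
            populations = {t.type_id: float(n) for t, n in
                           zip(ecology.types, ecology.initial_counts)}
        enz = {t.type_id: t.enzymes.copy() for t in ecology.types}
        return cls(0.0, c, dict(populations), enz)


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------


def _rates(ecology: Ecology, c: np.ndarray, populations, enzymes):
    """Shared flux computation: consumption, excretion, per-type lambda."""
    n_chem = ecology.n_chemicals
    cons = np.zeros(n_chem)
    prod = np.zeros(n_chem)
    lam = {}
    s = np.maximum(c, 0.0)
    s = s / (1.0 + s)
    for t in ecology.types:
        tid = t.type_id
        p = populations[tid]
        E = enzymes[tid]
        diet = list(t.metabolism.nutrient_set)
        upt = E * s[diet]                      # per unit biomass
        lam[tid] = float(upt @ t.delta_v_cached
                         - t.maintenance - E @ t.enzyme_costs)
        cons[diet] += p * upt
        if t.metabolism.byproduct_set:
            prod[list(t.metabolism.byproduct_set)] += p * (upt @ t.metabolism.weights)
    return cons, prod, lam


def crm_rhs(state: ReactorState, ecology: Ecology, config,
            tau: float | None = None) -> ReactorState:
    """Time derivatives of (c, p, E) packaged as a ReactorState.

    ``config`` supplies the biomass conversion factor ``g``.  Raises
    IntegrationError on non-finite input, with a state dump.
    """
    tau = state.tau if tau is None else tau
    c = np.asarray(state.concentrations, float)
    if not np.all(np.isfinite(c)) or any(
        not np.isfinite(v) for v in state.populations.values()
    ):
        raise IntegrationError(f"non-finite reactor state at tau={tau}: {state}")
    if np.any(c < -1e-6):
        raise IntegrationError(f"negative concentrations at tau={tau}: {c}")
    mu = ecology.chemicals.dilution_rate
    f = ecology.chemicals.feed.values(tau)
    cons, prod, lam = _rates(ecology, c, state.populations, state.enzymes)
    dc = mu * (f - c) - cons + prod
    dp = {tid: state.populations[tid] * (config.g * lam[tid] - mu)
          for tid in state.populations}
    dE = {}
    for t in ecology.types:
        tid = t.type_id
        if (t.reg_enabled and t.regulation is not None
                and not is_functionally_disabled(t.regulation)):
            c_diet = np.maximum(c[list(t.metabolism.nutrient_set)], 0.0)
            dE[tid] = enzyme_rate(t.regulation, state.enzymes[tid], c_diet,
                                  t.budget_weights, t.e_budget)
        else:
            dE[tid] = np.zeros(t.metabolism.n_nutrients)
    return ReactorState(tau, dc, dp, dE)


# ---------------------------------------------------------------------------
# Packing helpers
# ---------------------------------------------------------------------------


def _layout(ecology: Ecology):
    n_chem = ecology.n_chemicals
    tids = [t.type_id for t in ecology.types]
    dims = [t.metabolism.n_nutrients for t in ecology.types]
    offsets = np.cumsum([n_chem + len(tids)] + dims)
    return n_chem, tids, dims, offsets


def _pack(state: ReactorState, ecology: Ecology) -> np.ndarray:
    n_chem, tids, dims, _ = _layout(ecology)
    parts = [np.asarray(state.concentrations, float),
             np.array([state.populations[tid] for tid in tids])]
    parts += [np.asarray(state.enzymes[tid], float) for tid in tids]
    return np.concatenate(parts)


def _unpack(y: np.ndarray, tau: float, ecology: Ecology) -> ReactorState:
    n_chem, tids, dims, offsets = _layout(ecology)
    c = y[:n_chem]
    p = {tid: float(y[n_chem + k]) for k, tid in enumerate(tids)}
    enz = {}
    start = n_chem + len(tids)
    for tid, d in zip(tids, dims):
        enz[tid] = y[start:start + d]
        start += d
    return ReactorState(tau, c, p, enz)


def _has_active_regulation(ecology: Ecology) -> bool:
    return any(t.reg_enabled and t.regulation is not None
               and not is_functionally_disabled(t.regulation)
               for t in ecology.types)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def integrate(initial: ReactorState, ecology: Ecology, config, tau_end: float,
              dt_out: float | None = None, rtol: float = 1e-8,
              atol: float = 1e-10) -> Trajectory:
    """Integrate the deterministic model to ``tau_end``.

    Uses LSODA (adaptive, stiffness-switching).  Nonnegativity is preserved by
    clipping (with a warning) — Monod terms vanish at zero so clipping is
    dynamically consistent.  When regulation is active the enzyme-budget
    projection is applied at each output time (operator splitting).
    """
    dt_out = dt_out if dt_out is not None else config.dt_out
    t_eval = np.arange(initial.tau, tau_end + 0.5 * dt_out, dt_out)
    if t_eval[-1] < tau_end - 1e-9:
        t_eval = np.append(t_eval, tau_end)

    def fun(tau, y):
        st = _unpack(np.maximum(y, 0.0), tau, ecology)
        d = crm_rhs(st, ecology, config, tau)
        return _pack(d, ecology)

    y0 = _pack(initial, ecology)
    split = _has_active_regulation(ecology)
    ys = [y0]
    if not split:
        sol = solve_ivp(fun, (initial.tau, tau_end), y0, method="LSODA",
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"integration failed: {sol.message}; try a smaller output step")
        ys = sol.y.T
    else:
        y = y0
        for k in range(1, t_eval.size):
            sol = solve_ivp(fun, (t_eval[k - 1], t_eval[k]), y, method="LSODA",
                            rtol=rtol, atol=atol)
            if not sol.success:
                raise IntegrationError(
                    f"integration failed at tau={t_eval[k - 1]}: {sol.message}; "
                    "try a smaller output step")
            y = sol.y[:, -1].copy()
            st = _unpack(y, t_eval[k], ecology)
            for t in ecology.types:
                E = np.maximum(st.enzymes[t.type_id], 0.0)
                tot = float(t.budget_weights @ E)
                if tot > t.e_budget:
                    E *= t.e_budget / tot
                st.enzymes[t.type_id] = E
            y = _pack(st, ecology)
            ys.append(y)
        ys = np.asarray(ys)

    ys = np.asarray(ys)
    if np.min(ys) < -1e-6:
        warnings.warn("negative state values clipped to zero during integration")
    ys = np.maximum(ys, 0.0)

    n_chem, tids, dims, _ = _layout(ecology)
    pops = {tid: ys[:, n_chem + k] for k, tid in enumerate(tids)}
    enz = {}
    start = n_chem + len(tids)
    for tid, d in zip(tids, dims):
        enz[tid] = ys[:, start:start + d]
        start += d
    return Trajectory.from_dense(t_eval, ys[:, :n_chem], pops, enz, b0=None)


# ---------------------------------------------------------------------------
# Steady state
# ---------------------------------------------------------------------------


def steady_state(ecology: Ecology, config, tol: float = 1e-8,
                 pre_tau: float | None = None):
    """Find a coexistence equilibrium under constant feeds.

    Strategy: relax by integration toward the attractor, drop washed-out
    types, then polish with a Newton-type root solve and verify by a short
    stability integration.  Returns ``(state, info)`` where ``state`` is None
    when no populated equilibrium exists (e.g. the dilution rate exceeds the
    maximum attainable growth rate and every type washes out); ``info``
    carries the residual and a diagnosis string.
    """
    if not ecology.chemicals.feed.is_constant:
        raise StructuralError("steady_state requires constant feeds")
    mu = ecology.chemicals.dilution_rate
    f = ecology.chemicals.feed.values(0.0)

    if not ecology.types:
        state = ReactorState(0.0, f.copy(), {}, {})
        return state, {"residual": 0.0, "diagnosis": "empty ecology: c = f"}

    init = ReactorState.initial(ecology)
    pre_tau = pre_tau if pre_tau is not None else 300.0 / mu
    traj = integrate(init, ecology, config, pre_tau, dt_out=pre_tau / 50)
    last = traj.n_samples - 1
    surviving = [t for t in ecology.types
                 if traj.population(t.type_id)[last] > 1e-9]
    if not surviving:
        return None, {
            "residual": float("nan"),
            "diagnosis": "all types extinct: dilution exceeds attainable growth",
        }

    sub = Ecology(ecology.chemicals, [t.copy() for t in surviving],
                  initial_counts=[1] * len(surviving))
    for t, src in zip(sub.types, surviving):
        t.enzymes = traj.enzymes(src.type_id)[last].copy()
    guess = ReactorState(
        0.0, traj.chemicals[last].copy(),
        {t.type_id: float(traj.population(t.type_id)[last]) for t in surviving},
        {t.type_id: t.enzymes.copy() for t in sub.types},
    )

    def residual(y):
        st = _unpack(np.maximum(y, 0.0), 0.0, sub)
        return _pack(crm_rhs(st, sub, config), sub)

    sol = root(residual, _pack(guess, sub), method="hybr", tol=1e-12)
    res = float(np.max(np.abs(residual(sol.x))))
    if not sol.success or res >= tol or np.any(sol.x < -1e-8):
        return None, {"residual": res,
                      "diagnosis": "root polish did not converge"}
    state = _unpack(np.maximum(sol.x, 0.0), 0.0, sub)
    # stability check: a short integration must stay put
    check = integrate(state, sub, config, 10.0 / mu, dt_out=10.0 / mu)
    drift = float(np.max(np.abs(_pack(
        _unpack(_pack(state, sub), 0.0, sub), sub
    ) - np.concatenate([
        check.chemicals[-1],
        [check.population(t.type_id)[-1] for t in sub.types],
        *[check.enzymes(t.type_id)[-1] for t in sub.types],
    ]))))
    info = {"residual": res, "drift": drift,
            "diagnosis": "converged" if drift < 1e-4 * (1 + res) + 1e-3
            else "equilibrium unstable under integration"}
    if info["diagnosis"] != "converged":
        return None, info
    return state, info
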