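"""Hybrid stochastic engine: continuous chemistry, discrete protocell events.

Chemical concentrations and enzyme levels evolve continuously inside each
step; protocell division, washout, starvation death and speciation are
discrete events drawn per type and per channel as Poisson counts at rates
frozen over the step (tau-leaping).  Per capita, for a type with net growth
value ``lambda``:

    division rate    = max(0,  g * lambda)
    washout rate     = mu
    starvation rate  = max(0, -g * lambda)

so the expected per-capita net growth is ``g * lambda - mu``, recovering the
deterministic population equation in expectation.  Each division is a
discrete event; with probability ``1 / e_div`` one of the daughters carries
mutations and founds a new type in single copy (speciation).

The step length adapts so that total event counts stay a small fraction of
the population (rates change little across a step) and so that feed forcing
is well resolved.  Chemicals relax fast relative to everything else and are
advanced by a positivity-preserving exponential relaxation toward their
quasi-steady state.

Determinism: a single seeded generator; draws are consumed in fixed
(type-sorted, channel-sorted) order, so a (config, seed) pair reproduces the
event log exactly.
"""

from __future__ import annotations

import copy as _copy
import json
import math
from dataclasses import dataclass

import numpy as np

from .core import (Ecology, IntegrationError, ProtocellType, SimulationConfig,
                   StructuralError)
from .lineage import LineageTree, mutate_type
from .regulation import _enzyme_rate_fast, is_functionally_disabled
from .trajectory import Trajectory, TypeTrack

__all__ = [
    "EVENT_DIVISION", "EVENT_WASHOUT", "EVENT_STARVATION", "EVENT_SPECIATION",
    "EVENT_NAMES", "EventLog", "EventRecord", "SimResult",
    "per_capita_event_rates", "StochasticEngine", "run",
]

EVENT_DIVISION = 0
EVENT_WASHOUT = 1
EVENT_STARVATION = 2
EVENT_SPECIATION = 3
EVENT_NAMES = {
    EVENT_DIVISION: "division",
    EVENT_WASHOUT: "washout",
    EVENT_STARVATION: "starvation",
    EVENT_SPECIATION: "speciation",
}
_NAME_TO_KIND = {v: k for k, v in EVENT_NAMES.items()}


@dataclass(frozen=True)
class EventRecord:
    tau: float
    kind: str
    type_id: int
    count: int = 1
    child_id: int | None = None


class EventLog:
    """Append-only, time-ordered record of discrete events.

    Events of the same kind affecting the same type within one tau-leap step
    are aggregated into a single record with a ``count``; speciation records
    are individual and carry the child type id.  Storage is columnar.
    """

    def __init__(self) -> None:
        self.tau: list[float] = []
        self.kind: list[int] = []
        self.type_id: list[int] = []
        self.aux: list[int] = []  # count, or child id for speciations

    def append(self, tau: float, kind: int, type_id: int, aux: int) -> None:
        if self.tau and tau < self.tau[-1] - 1e-12:
            raise StructuralError("event log times must be nondecreasing")
        self.tau.append(tau)
        self.kind.append(kind)
        self.type_id.append(type_id)
        self.aux.append(aux)

    def __len__(self) -> int:
        return len(self.tau)

    def records(self):
        for tau, kind, tid, aux in zip(self.tau, self.kind, self.type_id, self.aux):
            if kind == EVENT_SPECIATION:
                yield EventRecord(tau, EVENT_NAMES[kind], tid, 1, aux)
            else:
                yield EventRecord(tau, EVENT_NAMES[kind], tid, aux, None)

    def count(self, kind: str, type_id: int | None = None) -> int:
        k = _NAME_TO_KIND[kind]
        tot = 0
        for kk, tid, aux in zip(self.kind, self.type_id, self.aux):
            if kk == k and (type_id is None or tid == type_id):
                tot += 1 if k == EVENT_SPECIATION else aux
        return tot

    def speciations_from(self, type_id: int) -> int:
        return sum(1 for k, t in zip(self.kind, self.type_id)
                   if k == EVENT_SPECIATION and t == type_id)

    def to_jsonl(self, path, provenance: dict | None = None) -> None:
        with open(path, "w") as fh:
            if provenance:
                fh.write(json.dumps({"_provenance": provenance}) + "\n")
            for r in self.records():
                obj = {"tau": r.tau, "event": r.kind, "type": r.type_id,
                       "count": r.count}
                if r.child_id is not None:
                    obj["child"] = r.child_id
                fh.write(json.dumps(obj) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "EventLog":
        log = cls()
        with open(path) as fh:
            for line in fh:
                obj = json.loads(line)
                if "_provenance" in obj:
                    continue
                kind = _NAME_TO_KIND[obj["event"]]
                aux = obj.get("child") if kind == EVENT_SPECIATION else obj["count"]
                log.append(obj["tau"], kind, obj["type"], int(aux))
        return log

    def identical(self, other: "EventLog") -> bool:
        return (self.tau == other.tau and self.kind == other.kind
                and self.type_id == other.type_id and self.aux == other.aux)


def per_capita_event_rates(lam: float, g: float, mu: float):
    """(division, washout, starvation) rates for one individual."""
    return max(0.0, g * lam), mu, max(0.0, -g * lam)


@dataclass
class SimResult:
    """Everything a stochastic run produces."""

    trajectory: Trajectory
    events: EventLog
    tree: LineageTree
    types: dict[int, ProtocellType]
    final_counts: dict[int, int]
    collapsed_at: float | None
    config: SimulationConfig
    seed: int | None = None
    divisions: int = 0
    speciations: int = 0


class _TypeState:
    """Engine-internal mutable record for one active type."""

    __slots__ = ("ptype", "n", "diet", "byp", "byp_ix", "reg_active")

    def __init__(self, ptype: ProtocellType, n: int):
        self.ptype = ptype
        self.n = int(n)
        self.diet = list(ptype.metabolism.nutrient_set)
        self.byp = list(ptype.metabolism.byproduct_set)
        self.byp_ix = np.ix_(self.byp, self.diet) if self.byp else None
        self.reg_active = (ptype.reg_enabled and ptype.regulation is not None
                           and not is_functionally_disabled(ptype.regulation))


class StochasticEngine:
    """Event-level simulator for one ecology under one configuration.

    The engine owns deep copies of the founding types (their enzyme state
    mutates during the run and variants are spawned from them), a lineage
    tree, an event log and a sparse trajectory recorder.
    """

    def __init__(self, ecology: Ecology, config: SimulationConfig,
                 seed: int | None = None,
                 initial_counts: dict[int, int] | None = None):
        self.ecology = ecology
        self.config = config
        self.seed = config.seed if seed is None else seed
        self.rng = np.random.default_rng(self.seed)
        self.mu = ecology.chemicals.dilution_rate
        self.feed = ecology.chemicals.feed
        self.n_chem = ecology.n_chemicals
        self.tau = 0.0
        self.c = self.feed.values(0.0)
        self.events = EventLog()
        self.tree = LineageTree()
        self.types: dict[int, ProtocellType] = {}
        self.active: dict[int, _TypeState] = {}
        self._next_id = 0
        self.divisions = 0
        self.speciations = 0
        self.collapsed_at: float | None = None
        for t, n0 in zip(ecology.types, ecology.initial_counts):
            p = _copy.deepcopy(t)
            p.bind_chemistry(ecology.chemicals)
            n = n0 if initial_counts is None else initial_counts.get(t.type_id, n0)
            self.types[p.type_id] = p
            self.active[p.type_id] = _TypeState(p, n)
            self.tree.add(p.type_id, p.parent_id if p.parent_id in self.types
                          else None, birth_time=p.birth_time)
            self._next_id = max(self._next_id, p.type_id + 1)
        # trajectory recording
        self._times: list[float] = []
        self._chem: list[np.ndarray] = []
        self._tracks: dict[int, TypeTrack] = {}
        self._forcing_cap = None
        self._last_total_rate: float | None = None
        period = self.feed.min_period()
        if period is not None:
            self._forcing_cap = period / 400.0

    # -- rates -------------------------------------------------------------

    def _lambdas(self, s: np.ndarray) -> dict[int, float]:
        lam = {}
        for tid in self.active:
            st = self.active[tid]
            t = st.ptype
            E = t.enzymes
            lam[tid] = float((E * s[st.diet]) @ t.delta_v_cached
                             - t.maintenance - E @ t.enzyme_costs)
        return lam

    def event_rates(self) -> dict[int, tuple[float, float, float]]:
        """Absolute per-type (division, washout, starvation) rates now."""
        s = self.c / (1.0 + self.c)
        lam = self._lambdas(s)
        out = {}
        for tid, st in self.active.items():
            div, wash, starve = per_capita_event_rates(
                lam[tid], self.config.g, self.mu)
            out[tid] = (st.n * div, st.n * wash, st.n * starve)
        return out

    # -- chemistry ---------------------------------------------------------

    def _advance_chemistry(self, dt: float) -> np.ndarray:
        """Advance the chemical ODE over one step; returns the step-averaged
        Monod saturation used to freeze event rates.

        Chemicals relax much faster than populations or enzymes, so within a
        step (populations and enzyme levels frozen) the chemical ODE is
        ``dc/dt = P(c) - L(c) * c`` with slowly varying ``P`` and ``L``.  The
        quasi-steady state is found by fixed-point iteration and the state is
        relaxed toward it exponentially — an A-stable, positivity-preserving
        update that reduces to explicit Euler when chemicals are slow.
        """
        b0 = self.config.b0
        c0 = self.c
        f = self.feed.values(self.tau + 0.5 * dt)
        # per-step aggregates: consumption capacity U_i = sum_types p * E and
        # the excretion matrix G[i, n] routing nutrient-n uptake to chemical i
        U = np.zeros(self.n_chem)
        G = None
        for st in self.active.values():
            p = st.n * b0
            if p == 0:
                continue
            E = st.ptype.enzymes
            U[st.diet] += p * E
            if st.byp_ix is not None:
                if G is None:
                    G = np.zeros((self.n_chem, self.n_chem))
                G[st.byp_ix] += p * (st.ptype.metabolism.weights.T * E)
        c = c0
        base = self.mu * f
        for _ in range(3):
            P = base if G is None else base + G @ (c / (1.0 + c))
            L = self.mu + U / (1.0 + c)
            c = P / L
        css = c
        L = self.mu + U / (1.0 + css)
        c_new = css + (c0 - css) * np.exp(-L * dt)
        self.c = c_new
        return 0.5 * (c0 / (1.0 + c0) + c_new / (1.0 + c_new))

    # -- stepping ----------------------------------------------------------

    def _choose_dt(self) -> float:
        dt = self.config.dt
        if self._forcing_cap is not None:
            dt = min(dt, self._forcing_cap)
        if self._last_total_rate is None:
            rates = self.event_rates()
            total = sum(sum(r) for r in rates.values())
        else:
            total = self._last_total_rate
        n_tot = sum(st.n for st in self.active.values())
        if total > 0:
            dt = min(dt, 0.1 * max(n_tot, 5) / total)
        return dt

    def step(self, dt: float | None = None) -> None:
        """Advance the hybrid state by (at most) one tau-leap step."""
        if dt is None:
            dt = self._choose_dt()
        s_bar = self._advance_chemistry(dt)
        lam = self._lambdas(s_bar)
        for v in lam.values():
            if not math.isfinite(v):
                raise IntegrationError(
                    f"non-finite growth value at tau={self.tau}: lam={lam}, "
                    f"c={self.c}")
        # continuous enzyme dynamics at the substep-mean concentrations
        c_bar = self.c
        for tid in sorted(self.active):
            st = self.active[tid]
            if not st.reg_active:
                continue
            t = st.ptype
            dE = _enzyme_rate_fast(t.regulation, t.enzymes, c_bar[st.diet],
                                   t.budget_weights, t.e_budget)
            E = np.maximum(t.enzymes + dt * dE, 0.0)
            tot = float(t.budget_weights @ E)
            if tot > t.e_budget:
                E *= t.e_budget / tot
            t.enzymes = E
        # discrete events at frozen rates, fixed draw order
        g = self.config.g
        newborns: list[ProtocellType] = []
        tau_next = self.tau + dt
        total_rate = 0.0
        for tid in sorted(self.active):
            st = self.active[tid]
            n = st.n
            if n == 0:
                continue
            div_r, wash_r, starve_r = per_capita_event_rates(lam[tid], g, self.mu)
            total_rate += n * (div_r + wash_r + starve_r)
            # exponential mean-matching: scale frozen rates so the expected
            # net change matches the exact linear birth-death mean over dt
            # (removes the first-order tau-leap bias; exact for pure death)
            net = (div_r - wash_r - starve_r) * dt
            phi = math.expm1(net) / net if abs(net) > 1e-12 else 1.0
            div_r, wash_r, starve_r = div_r * phi, wash_r * phi, starve_r * phi
            k = int(self.rng.poisson(n * div_r * dt)) if div_r > 0 else 0
            m = int(self.rng.binomial(k, 1.0 / self.config.e_div)) \
                if (k and self.config.mutations_enabled) else 0
            w = int(self.rng.poisson(n * wash_r * dt)) if wash_r > 0 else 0
            sv = int(self.rng.poisson(n * starve_r * dt)) if starve_r > 0 else 0
            avail = n + k - m
            if w + sv > avail:  # tau-leap overshoot: cap deaths at the living
                w = min(w, avail)
                sv = min(sv, avail - w)
            st.n = n + k - m - w - sv
            self.divisions += k
            if k:
                self.events.append(tau_next, EVENT_DIVISION, tid, k)
            if w:
                self.events.append(tau_next, EVENT_WASHOUT, tid, w)
            if sv:
                self.events.append(tau_next, EVENT_STARVATION, tid, sv)
            for _ in range(m):
                child = mutate_type(st.ptype, self.config, self.rng,
                                    self._next_id, tau_next)
                child.bind_chemistry(self.ecology.chemicals)
                self._next_id += 1
                self.speciations += 1
                newborns.append(child)
                self.events.append(tau_next, EVENT_SPECIATION, tid,
                                   child.type_id)
        for child in newborns:
            self.types[child.type_id] = child
            self.active[child.type_id] = _TypeState(child, 1)
            self.tree.add(child.type_id, child.parent_id,
                          birth_time=child.birth_time)
        for tid in [tid for tid, st in self.active.items() if st.n == 0]:
            self.tree.close(tid, tau_next)
            del self.active[tid]
        self._last_total_rate = total_rate
        self.tau = tau_next
        if not self.active and self.collapsed_at is None:
            self.collapsed_at = tau_next

    # -- recording ---------------------------------------------------------

    def _record_sample(self) -> None:
        idx = len(self._times)
        self._times.append(self.tau)
        self._chem.append(self.c.copy())
        for tid in sorted(self.active):
            st = self.active[tid]
            tr = self._tracks.get(tid)
            if tr is None:
                tr = self._tracks[tid] = TypeTrack(idx)
            elif tr.last_index != idx - 1:
                # type left and re-entered the record window; pad with zeros
                gap = idx - 1 - tr.last_index
                d = len(tr.enzymes[0])
                tr.pops.extend([0.0] * gap)
                tr.enzymes.extend([np.full(d, np.nan)] * gap)
            tr.pops.append(float(st.n))
            tr.enzymes.append(st.ptype.enzymes.copy())

    # -- driver ------------------------------------------------------------

    def run(self) -> SimResult:
        cfg = self.config
        self._record_sample()
        next_sample = cfg.dt_out
        while self.tau < cfg.tau_end - 1e-9:
            dt = min(self._choose_dt(), cfg.tau_end - self.tau)
            self.step(dt)
            if self.tau >= next_sample - 1e-9:
                self._record_sample()
                while next_sample <= self.tau + 1e-9:
                    next_sample += cfg.dt_out
            if self.collapsed_at is not None:
                self._record_sample()
                break
        if self._times[-1] < self.tau - 1e-9:
            self._record_sample()
        traj = Trajectory(np.array(self._times), np.array(self._chem),
                          self._tracks, b0=cfg.b0)
        return SimResult(
            trajectory=traj, events=self.events, tree=self.tree,
            types=self.types,
            final_counts={tid: st.n for tid, st in self.active.items()},
            collapsed_at=self.collapsed_at, config=cfg, seed=self.seed,
            divisions=self.divisions, speciations=self.speciations,
        )

    # -- checkpointing -----------------------------------------------------

    def checkpoint(self) -> dict:
        """Versioned snapshot of the full mutable state (without the log)."""
        from .serialize import type_to_dict
        return {
            "schema": 1,
            "tau": self.tau,
            "concentrations": self.c.tolist(),
            "counts": {str(tid): st.n for tid, st in self.active.items()},
            "types": {str(tid): type_to_dict(t) for tid, t in self.types.items()},
            "tree": self.tree.to_dict(),
            "next_id": self._next_id,
            "rng_state": self.rng.bit_generator.state,
            "divisions": self.divisions,
            "speciations": self.speciations,
            "last_total_rate": self._last_total_rate,
            "collapsed_at": self.collapsed_at,
        }

    def restore(self, snap: dict) -> None:
        from .serialize import type_from_dict
        if snap.get("schema") != 1:
            raise StructuralError("unknown checkpoint schema")
        self.tau = float(snap["tau"])
        self.c = np.asarray(snap["concentrations"], float)
        self.types = {int(k): type_from_dict(v) for k, v in snap["types"].items()}
        for t in self.types.values():
            t.bind_chemistry(self.ecology.chemicals)
        self.active = {}
        for k, n in snap["counts"].items():
            tid = int(k)
            self.active[tid] = _TypeState(self.types[tid], int(n))
        self.tree = LineageTree.from_dict(snap["tree"])
        self._next_id = int(snap["next_id"])
        self.rng.bit_generator.state = snap["rng_state"]
        self.divisions = int(snap["divisions"])
        self.speciations = int(snap["speciations"])
        self._last_total_rate = snap.get("last_total_rate")
        self.collapsed_at = snap.get("collapsed_at")


def run(ecology: Ecology, config: SimulationConfig,
        seed: int | None = None) -> SimResult:
    """Simulate one ecology to ``config.tau_end``; reproducible from (config, seed)."""
    return StochasticEngine(ecology, config, seed=seed).run()
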