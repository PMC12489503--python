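"""Variant creation and lineage analyses.

Mutation acts at division: with probability ``1/e_div`` one daughter founds a
new type whose metabolic weights, enzyme baseline and (when regulation is
allowed) neural-network parameters are each perturbed by small additive
Gaussian noise, subject to the hard constraints — the thermodynamic rule on
the metabolic matrix (resampled on violation) and the enzyme budget
(projected).  Diet sets are inherited exactly: major innovations (changes to
which chemicals are eaten or excreted) are structurally excluded.

The analyses operationalize the phylogeny-trunk view of an evolutionary run:
the *trunk* is the root-to-leaf path ending at the dominant surviving type
(largest time-integrated biomass over the final 10% of the run); a
*significant variant* is a non-root trunk node that itself produced a further
trunk node, i.e. a variant whose contribution to the lineage is long-term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .core import (Ecology, MetabolicNetwork, ProtocellType, SimulationConfig,
                   StructuralError, enforce_enzyme_budget)
from .trajectory import Trajectory

__all__ = [
    "LineageNode", "LineageTree", "mutate_type", "trunk",
    "significant_variants", "variants_per_period", "quasi_species_count",
    "lineage_enzyme_series", "count_evolvable_parameters",
    "enzyme_feed_correlation", "export_newick", "export_table",
    "tree_from_table",
]


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------


@dataclass
class LineageNode:
    type_id: int
    parent_id: Optional[int]
    birth_time: float
    extinction_time: Optional[float] = None  # None = alive
    children: list[int] = field(default_factory=list)

    @property
    def alive(self) -> bool:
        return self.extinction_time is None


class LineageTree:
    """Rooted forest of protocell types with birth/extinction bookkeeping."""

    def __init__(self) -> None:
        self.nodes: dict[int, LineageNode] = {}

    def add(self, type_id: int, parent_id: Optional[int],
            birth_time: float) -> LineageNode:
        if type_id in self.nodes:
            raise StructuralError(f"type {type_id} already in lineage tree")
        if parent_id is not None:
            parent = self.nodes.get(parent_id)
            if parent is None:
                raise StructuralError(f"unknown parent {parent_id}")
            if birth_time <= parent.birth_time and birth_time != 0.0:
                raise StructuralError("child must be born after its parent")
            parent.children.append(type_id)
        node = LineageNode(type_id, parent_id, birth_time)
        self.nodes[type_id] = node
        return node

    def close(self, type_id: int, tau: float) -> None:
        node = self.nodes[type_id]
        if tau < node.birth_time:
            raise StructuralError("extinction before birth")
        node.extinction_time = tau

    @property
    def roots(self) -> list[int]:
        return [tid for tid, n in self.nodes.items() if n.parent_id is None]

    def path_to_root(self, type_id: int) -> list[int]:
        """Node ids from the root down to ``type_id`` (birth order)."""
        path = []
        tid: Optional[int] = type_id
        while tid is not None:
            path.append(tid)
            tid = self.nodes[tid].parent_id
        return path[::-1]

    def alive_nodes(self) -> list[int]:
        return [tid for tid, n in self.nodes.items() if n.alive]

    def __len__(self) -> int:
        return len(self.nodes)

    def to_dict(self) -> dict:
        return {
            str(tid): {
                "parent": n.parent_id, "birth": n.birth_time,
                "extinction": n.extinction_time,
            } for tid, n in self.nodes.items()
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LineageTree":
        tree = cls()
        for tid_s, rec in sorted(data.items(), key=lambda kv: float(kv[1]["birth"])):
            tree.add(int(tid_s), rec["parent"], float(rec["birth"]))
            if rec.get("extinction") is not None:
                tree.close(int(tid_s), float(rec["extinction"]))
        return tree


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------

_MAX_THERMO_TRIES = 20


def _perturb(arr: np.ndarray, p: float, sigma: float,
             rng: np.random.Generator) -> np.ndarray:
    out = np.asarray(arr, dtype=float).copy()
    if out.size == 0 or sigma == 0 or p == 0:
        return out
    mask = rng.random(out.shape) < p
    out += mask * rng.normal(0.0, sigma, out.shape)
    return out


def mutate_type(parent: ProtocellType, config: SimulationConfig,
                rng: np.random.Generator, type_id: int,
                birth_time: float) -> ProtocellType:
    """Create a variant daughter type from ``parent``.

    The child inherits the parent's diet sets exactly.  Metabolic weights are
    perturbed and clipped at zero; if the perturbation breaks the
    thermodynamic rule it is resampled (up to 20 tries, then the weights are
    left unchanged).  The enzyme baseline is perturbed, clipped and projected
    back onto the budget.  Regulatory parameters (all weights, biases and
    decay constants) are perturbed only when the parent's regulation is
    enabled (-REG variants never touch the network).
    """
    meta = parent.metabolism
    gv = parent._growth_values
    if gv is None:
        raise StructuralError(
            "parent type must be bound to a chemical system before mutation")

    weights = meta.weights
    new_weights = weights.copy()
    if weights.size and meta.byproduct_set and config.sigma_m > 0 and config.p_mut > 0:
        v_n = gv[list(meta.nutrient_set)]
        v_byp = gv[list(meta.byproduct_set)]
        for _ in range(_MAX_THERMO_TRIES):
            cand = np.maximum(_perturb(weights, config.p_mut, config.sigma_m, rng),
                              0.0)
            if np.all(v_n - cand @ v_byp > 0):
                new_weights = cand
                break

    metabolism = MetabolicNetwork(meta.nutrient_set, meta.byproduct_set,
                                  new_weights)

    enzymes = np.maximum(
        _perturb(parent.enzymes, config.p_mut, config.sigma_e, rng), 0.0)
    enzymes = enforce_enzyme_budget(enzymes, parent.budget_weights,
                                    parent.e_budget)

    regulation = parent.regulation
    if regulation is not None:
        regulation = regulation.copy()
        if parent.reg_enabled:
            p, s = config.p_mut, config.sigma_nn
            regulation.w_in = _perturb(regulation.w_in, p, s, rng)
            regulation.b_hidden = _perturb(regulation.b_hidden, p, s, rng)
            regulation.w_out = _perturb(regulation.w_out, p, s, rng)
            regulation.b_out = _perturb(regulation.b_out, p, s, rng)
            regulation.decay = np.maximum(
                _perturb(regulation.decay, p, s, rng), 0.0)

    child = ProtocellType(
        type_id=type_id, parent_id=parent.type_id, birth_time=birth_time,
        metabolism=metabolism, enzymes=enzymes,
        enzyme_costs=parent.enzyme_costs.copy(),
        maintenance=parent.maintenance, e_budget=parent.e_budget,
        budget_weights=parent.budget_weights.copy(),
        regulation=regulation, reg_enabled=parent.reg_enabled,
    )
    return child


def count_evolvable_parameters(ptype: ProtocellType) -> int:
    """Diagnostic: number of heritable parameters mutation can act on.

    Counts the metabolic weight entries and the enzyme baseline, plus — when
    regulation is enabled — every network weight, bias and decay constant.
    The counting convention (e.g. whether structurally-zero weights count) is
    a modelling choice; this counts every entry the mutation kernel touches.
    """
    n = int(ptype.metabolism.weights.size) + int(ptype.enzymes.size)
    if ptype.reg_enabled and ptype.regulation is not None:
        net = ptype.regulation
        n += int(net.w_in.size + net.b_hidden.size + net.w_out.size
                 + net.b_out.size + net.decay.size)
    return n


# ---------------------------------------------------------------------------
# Trunk and variant statistics
# ---------------------------------------------------------------------------


def _terminal_node(tree: LineageTree, trajectory: Trajectory | None,
                   tau_end: float | None) -> int:
    if not len(tree):
        raise StructuralError("empty lineage tree")
    alive = tree.alive_nodes()
    if trajectory is not None and alive:
        tau_end = tau_end if tau_end is not None else float(trajectory.times[-1])
        t0 = tau_end - 0.1 * (tau_end - float(trajectory.times[0]))
        best, best_mass = None, -1.0
        for tid in sorted(alive, key=lambda t: tree.nodes[t].birth_time):
            mass = (trajectory.biomass_integral(tid, t0, tau_end)
                    if tid in trajectory.tracks else 0.0)
            if mass > best_mass + 1e-12:
                best, best_mass = tid, mass
        return best
    if len(alive) == 1:
        return alive[0]
    if not alive:  # all extinct: path ends at the last type to go extinct
        return max(tree.nodes, key=lambda t: (tree.nodes[t].extinction_time,
                                              -tree.nodes[t].birth_time))
    raise StructuralError(
        "multiple extant types: a trajectory is required to pick the trunk")


def trunk(tree: LineageTree, trajectory: Trajectory | None = None,
          tau_end: float | None = None) -> list[int]:
    """Root-to-leaf path ending at the dominant surviving type.

    Dominance is the time-integrated biomass over the final 10% of the run
    (ties broken by earliest birth).  If every type is extinct the path ends
    at the last type to go extinct.  Nodes are returned in birth order.
    """
    return tree.path_to_root(_terminal_node(tree, trajectory, tau_end))


def significant_variants(tree: LineageTree,
                         trajectory: Trajectory | None = None,
                         tau_end: float | None = None) -> set[int]:
    """Trunk variants that themselves produced a further trunk variant.

    These are exactly the non-root trunk nodes with a child on the trunk:
    variants whose contribution to the lineage is long-term.
    """
    path = trunk(tree, trajectory, tau_end)
    return set(path[1:-1])


def variants_per_period(tree: LineageTree, period: float,
                        tau_end: float | None = None,
                        trajectory: Trajectory | None = None):
    """Mean number of significant variants born per forcing period.

    Bins significant-variant birth times into consecutive windows of length
    ``period`` starting at tau=0 and returns ``(mean, per_window_counts)``
    over the complete windows.
    """
    if period <= 0:
        raise StructuralError("period must be > 0")
    if tau_end is None:
        if trajectory is None:
            raise StructuralError("need tau_end or a trajectory")
        tau_end = float(trajectory.times[-1])
    n_windows = int(math.floor(tau_end / period + 1e-9))
    if n_windows < 1:
        raise StructuralError(
            f"run length {tau_end} is shorter than one period {period}")
    sig = significant_variants(tree, trajectory, tau_end)
    counts = np.zeros(n_windows, dtype=int)
    for tid in sig:
        b = tree.nodes[tid].birth_time
        w = int(b // period)
        if 0 <= w < n_windows:
            counts[w] += 1
    return float(counts.mean()), counts


def quasi_species_count(trajectory: Trajectory, burn_in: float = 0.2):
    """Richness time series and its post-burn-in mean.

    Counts the types with at least one individual at each sample and averages
    after discarding the first ``burn_in`` fraction of the run.
    """
    counts = trajectory.richness()
    k0 = int(burn_in * trajectory.n_samples)
    window = counts[k0:] if counts.size > k0 else counts
    return counts, float(window.mean()) if window.size else float("nan")


def lineage_enzyme_series(trajectory: Trajectory, tree: LineageTree,
                          tau_end: float | None = None):
    """Enzyme levels read along the phylogeny trunk.

    At each sample time the series reports the enzymes of the unique trunk
    type assigned to that time: during the overlap of a trunk parent and its
    trunk child, the child is reported from its birth time onward.  Returns
    ``(times, E, source_ids, valid)`` where ``valid`` flags samples at which
    the assigned trunk type was actually recorded alive (gaps are flagged
    False rather than interpolated).
    """
    path = trunk(tree, trajectory, tau_end)
    times = trajectory.times
    births = [tree.nodes[tid].birth_time for tid in path]
    idx = np.searchsorted(births, times, side="right") - 1
    idx = np.clip(idx, 0, len(path) - 1)
    d = len(trajectory.tracks[path[-1]].enzymes[0])
    E = np.full((times.size, d), np.nan)
    source = np.empty(times.size, dtype=int)
    valid = np.zeros(times.size, dtype=bool)
    enz_cache = {tid: trajectory.enzymes(tid) for tid in path
                 if tid in trajectory.tracks}
    for k in range(times.size):
        tid = path[idx[k]]
        source[k] = tid
        arr = enz_cache.get(tid)
        if arr is not None and not np.any(np.isnan(arr[k])):
            E[k] = arr[k]
            valid[k] = True
        else:
            # fall back to the deepest ancestor on the trunk alive at this time
            for j in range(idx[k] - 1, -1, -1):
                anc = enz_cache.get(path[j])
                if anc is not None and not np.any(np.isnan(anc[k])):
                    E[k] = anc[k]
                    source[k] = path[j]
                    valid[k] = True
                    break
    return times, E, source, valid


def enzyme_feed_correlation(trajectory: Trajectory, tree: LineageTree,
                            ecology: Ecology, nutrients: Iterable[int],
                            tau_min: float = 0.0) -> float:
    """Mean in-phase Pearson correlation between trunk enzymes and their feeds.

    For each listed nutrient, correlates the trunk enzyme level for that
    nutrient with the feed concentration of the same nutrient over the samples
    after ``tau_min``.  A series with (near-)zero variance contributes zero —
    a non-responding enzyme is uncorrelated with its feed by definition.
    """
    times, E, _, valid = lineage_enzyme_series(trajectory, tree)
    mask = valid & (times >= tau_min)
    if mask.sum() < 3:
        return 0.0
    feed = ecology.chemicals.feed
    rs = []
    for slot, nut in enumerate(nutrients):
        e = E[mask, slot]
        f = np.array([feed.value(nut, t) for t in times[mask]])
        if np.std(e) < 1e-9 or np.std(f) < 1e-9:
            rs.append(0.0)
        else:
            rs.append(float(np.corrcoef(e, f)[0, 1]))
    return float(np.mean(rs)) if rs else 0.0


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_newick(tree: LineageTree, path,
                  significant: set[int] | None = None) -> None:
    """Write the lineage forest as annotated Newick via dendropy.

    Node labels are ``t<id>``; branch lengths are birth-time differences;
    birth, extinction and significance ride along as metadata annotations.
    """
    import dendropy

    significant = significant or set()
    ns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=ns)
    for root in sorted(tree.roots):
        t = dendropy.Tree(taxon_namespace=ns)
        dnodes = {}

        def build(tid, parent_dnode):
            node = tree.nodes[tid]
            if parent_dnode is None:
                dn = t.seed_node
            else:
                dn = parent_dnode.new_child()
            dn.label = f"t{tid}"
            if not node.children:  # leaves carry taxa so labels survive I/O
                dn.taxon = ns.new_taxon(f"t{tid}")
            if node.parent_id is not None:
                dn.edge.length = node.birth_time - tree.nodes[node.parent_id].birth_time
            dn.annotations.add_new("birth", node.birth_time)
            if node.extinction_time is not None:
                dn.annotations.add_new("extinction", node.extinction_time)
            dn.annotations.add_new("significant", tid in significant)
            dnodes[tid] = dn
            for ch in sorted(node.children):
                build(ch, dn)

        build(root, None)
        tl.append(t)
    tl.write(path=str(path), schema="newick", suppress_annotations=False,
             suppress_rooting=True, unquoted_underscores=True)


def export_table(tree: LineageTree, path,
                 trunk_path: list[int] | None = None,
                 significant: set[int] | None = None) -> None:
    """Flat TSV: node, parent, birth, extinction, on_trunk, significant."""
    trunk_set = set(trunk_path or [])
    significant = significant or set()
    with open(path, "w") as fh:
        fh.write("node\tparent\tbirth\textinction\ton_trunk\tsignificant\n")
        for tid in sorted(tree.nodes):
            n = tree.nodes[tid]
            ext = "" if n.extinction_time is None else f"{n.extinction_time:.6g}"
            parent = "" if n.parent_id is None else str(n.parent_id)
            fh.write(f"{tid}\t{parent}\t{n.birth_time:.6g}\t{ext}\t"
                     f"{int(tid in trunk_set)}\t{int(tid in significant)}\n")


def tree_from_table(path) -> LineageTree:
    """Rebuild a LineageTree from the flat TSV exported by export_table."""
    rows = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        col = {name: k for k, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append(parts)
    tree = LineageTree()
    rows.sort(key=lambda p: float(p[col["birth"]]))
    for p in rows:
        parent = p[col["parent"]]
        tree.add(int(p[col["node"]]), int(parent) if parent else None,
                 float(p[col["birth"]]))
    for p in rows:
        ext = p[col["extinction"]]
        if ext:
            tree.close(int(p[col["node"]]), float(ext))
    return tree
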