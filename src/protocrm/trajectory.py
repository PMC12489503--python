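"""Sampled reactor trajectories: sparse per-type storage, tidy TSV I/O.

A trajectory holds sampled times, reactor chemical concentrations, and — for
each protocell type that was alive at one or more sample points — its
population and enzyme levels over its recorded lifetime.  Per-type storage is
sparse (first sample index + contiguous rows) because evolutionary runs create
thousands of short-lived variant types.

Populations are stored in the run's native representation: individual counts
for stochastic runs (with the per-individual biomass ``b0`` attached) or
biomass concentrations for deterministic runs (``b0 is None``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import StructuralError

__all__ = ["TypeTrack", "Trajectory"]


@dataclass
class TypeTrack:
    """Recorded samples of one type over the contiguous span it was observed."""

    first_index: int
    pops: list = field(default_factory=list)
    enzymes: list = field(default_factory=list)

    @property
    def last_index(self) -> int:
        return self.first_index + len(self.pops) - 1


class Trajectory:
    """Time series of reactor state sampled on (possibly uneven) output times."""

    def __init__(self, times, chemicals, tracks: dict[int, TypeTrack],
                 b0: float | None = None, meta: dict | None = None):
        self.times = np.asarray(times, dtype=float)
        self.chemicals = np.asarray(chemicals, dtype=float)
        if self.chemicals.shape[0] != self.times.size:
            raise StructuralError("chemical samples must match sample times")
        self.tracks = tracks
        self.b0 = b0
        self.meta = meta or {}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dense(cls, times, chemicals, pops: dict[int, np.ndarray],
                   enzymes: dict[int, np.ndarray], b0: float | None = None,
                   meta: dict | None = None) -> "Trajectory":
        tracks = {}
        for tid, p in pops.items():
            tracks[tid] = TypeTrack(0, list(np.asarray(p, float)),
                                    [np.asarray(row, float) for row in enzymes[tid]])
        return cls(times, chemicals, tracks, b0=b0, meta=meta)

    # -- accessors ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    @property
    def type_ids(self) -> list[int]:
        return sorted(self.tracks)

    def population(self, tid: int) -> np.ndarray:
        """Full-length population series for a type (zero outside its span)."""
        tr = self.tracks[tid]
        out = np.zeros(self.n_samples)
        out[tr.first_index:tr.first_index + len(tr.pops)] = tr.pops
        return out

    def biomass(self, tid: int) -> np.ndarray:
        p = self.population(tid)
        return p * self.b0 if self.b0 is not None else p

    def enzymes(self, tid: int) -> np.ndarray:
        """Full-length (S x d) enzyme series for a type, NaN outside its span."""
        tr = self.tracks[tid]
        d = len(tr.enzymes[0])
        out = np.full((self.n_samples, d), np.nan)
        out[tr.first_index:tr.first_index + len(tr.enzymes)] = tr.enzymes
        return out

    def alive(self, tid: int) -> np.ndarray:
        """Boolean series: type present with positive population."""
        thr = 1.0 if self.b0 is not None else 1e-9
        return self.population(tid) >= thr

    def richness(self) -> np.ndarray:
        """Number of coexisting types at each sample."""
        out = np.zeros(self.n_samples, dtype=int)
        for tid in self.tracks:
            out += self.alive(tid)
        return out

    def biomass_integral(self, tid: int, t0: float, t1: float) -> float:
        """Time-integrated biomass of a type over [t0, t1] (trapezoid)."""
        mask = (self.times >= t0) & (self.times <= t1)
        if mask.sum() < 2:
            mask = (self.times >= t0)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(self.biomass(tid)[mask], self.times[mask]))

    # -- tidy I/O ----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: (time, variable, id, value).

        ``variable`` is one of ``chemical`` (id = chemical index),
        ``population`` (id = type id) or ``enzyme`` (id = "tid:slot").
        """
        rows = []
        n_chem = self.chemicals.shape[1]
        for i in range(n_chem):
            rows.append(pd.DataFrame({
                "time": self.times, "variable": "chemical", "id": str(i),
                "value": self.chemicals[:, i],
            }))
        for tid, tr in sorted(self.tracks.items()):
            sl = slice(tr.first_index, tr.first_index + len(tr.pops))
            t = self.times[sl]
            rows.append(pd.DataFrame({
                "time": t, "variable": "population", "id": str(tid),
                "value": np.asarray(tr.pops, float),
            }))
            earr = np.asarray(tr.enzymes, float)
            for j in range(earr.shape[1]):
                rows.append(pd.DataFrame({
                    "time": t, "variable": "enzyme", "id": f"{tid}:{j}",
                    "value": earr[:, j],
                }))
        return pd.concat(rows, ignore_index=True)

    def write_tsv(self, path, provenance: dict | None = None) -> None:
        with open(path, "w") as fh:
            for key, val in {**self.meta, **(provenance or {})}.items():
                fh.write(f"# {key}={val}\n")
            if self.b0 is not None:
                fh.write(f"# b0={self.b0}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "Trajectory":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val
                pos = fh.tell()
            df = pd.read_csv(fh, sep="\t", dtype={"id": str})
        b0 = float(meta.pop("b0")) if "b0" in meta else None
        times = np.unique(df["time"].to_numpy())
        index = {t: k for k, t in enumerate(times)}
        chem = df[df["variable"] == "chemical"]
        n_chem = chem["id"].astype(int).max() + 1
        chemicals = np.zeros((times.size, n_chem))
        for i, sub in chem.groupby("id"):
            for t, v in zip(sub["time"], sub["value"]):
                chemicals[index[t], int(i)] = v
        tracks: dict[int, TypeTrack] = {}
        pops = df[df["variable"] == "population"]
        for tid_s, sub in pops.groupby("id"):
            tid = int(tid_s)
            sub = sub.sort_values("time")
            first = index[sub["time"].iloc[0]]
            tracks[tid] = TypeTrack(first, list(sub["value"].to_numpy(float)), [])
        enz = df[df["variable"] == "enzyme"]
        per_type: dict[int, dict[int, np.ndarray]] = {}
        for eid, sub in enz.groupby("id"):
            tid_s, _, slot_s = eid.partition(":")
            per_type.setdefault(int(tid_s), {})[int(slot_s)] = (
                sub.sort_values("time")["value"].to_numpy(float))
        for tid, slots in per_type.items():
            d = max(slots) + 1
            n = len(slots[0])
            earr = np.column_stack([slots[j] for j in range(d)])
            tracks[tid].enzymes = [earr[k] for k in range(n)]
        counts = pops["value"]
        if b0 is not None and np.allclose(counts, np.round(counts)):
            for tr in tracks.values():
                tr.pops = [float(v) for v in tr.pops]
        return cls(times, chemicals, tracks, b0=b0, meta=meta)
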