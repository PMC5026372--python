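"""Persistent homology of coactivity filtrations; Betti timelines; T_min.

The coactivity complex grows as exploration proceeds; its homology over Z2
is tracked along the birth-time filtration.  Dimension-0 bars are computed
with a union-find over the vertex/edge sequence; dimension-1 bars by
standard boundary-matrix reduction of the triangle columns (columns stored
as integer bitmasks over the filtration-ordered edges).  Only the
2-skeleton is considered, so the barcode holds dimensions 0 and 1.

An interval (dim, birth, death) is *alive* at time t when birth <= t < death.
Pairs with birth == death (a simplex killed in the same window it appears)
are never observable in any Betti timeline and are dropped from the barcode.

The learning time T_min of a session is the earliest sampled moment from
which the Betti numbers (b0, b1) stably equal the target — (1, 1) for a
connected arena with one obstacle — through the end of the session.  If the
target is never stably reached, the map has not formed and the session is
flagged as diverged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .complexes import FilteredComplex

INF = float("inf")


@dataclass(frozen=True)
class Barcode:
    """Persistence intervals (dim, birth, death); death = inf for survivors."""

    intervals: tuple[tuple[int, float, float], ...]

    def in_dim(self, dim: int) -> list[tuple[float, float]]:
        return [(b, d) for k, b, d in self.intervals if k == dim]

    def betti_at(self, t: float, dim: int) -> int:
        return sum(1 for k, b, d in self.intervals if k == dim and b <= t < d)


@dataclass(frozen=True)
class BettiTimeline:
    times: np.ndarray
    b0: np.ndarray
    b1: np.ndarray


@dataclass(frozen=True)
class LearningResult:
    """T_min: earliest stable time at which (b0, b1) matches the target."""

    t_min: float | None
    target_betti: tuple[int, int]
    grid_step: float

    @property
    def diverged(self) -> bool:
        return self.t_min is None


def persistent_homology(fc: FilteredComplex) -> Barcode:
    """Z2 persistence of the birth-time filtration of a 2-skeleton complex.

    Simplexes are processed in (birth, dim, vertex) order.  Vertices create
    dimension-0 classes; an edge either merges two components (killing the
    younger one, elder rule) or creates a dimension-1 class; a triangle
    kills the youngest independent cycle in its reduced boundary.  Raises
    ``ValueError`` on a non-face-closed input.
    """
    if not fc.is_face_closed():
        raise ValueError("input filtration is not face-closed")

    ordered = fc.sorted_simplexes()
    vertices = [(s, b) for s, b in ordered if len(s) == 1]
    edges = [(s, b) for s, b in ordered if len(s) == 2]
    triangles = [(s, b) for s, b in ordered if len(s) == 3]

    intervals: list[tuple[int, float, float]] = []

    # --- H0 by union-find with the elder rule
    parent: dict = {}
    comp_birth: dict = {}

    def find(v):
        root = v
        while parent[root] != root:
            root = parent[root]
        while parent[v] != root:
            parent[v], v = root, parent[v]
        return root

    for (v,), b in vertices:
        parent[v] = v
        comp_birth[v] = b

    positive_edge: dict[tuple, bool] = {}
    for (u, v), b in edges:
        ru, rv = find(u), find(v)
        if ru == rv:
            positive_edge[(u, v)] = True  # creates a 1-cycle
            continue
        positive_edge[(u, v)] = False
        # the younger component dies at b
        if comp_birth[ru] < comp_birth[rv] or (
            comp_birth[ru] == comp_birth[rv] and ru <= rv
        ):
            elder, younger = ru, rv
        else:
            elder, younger = rv, ru
        if comp_birth[younger] < b:
            intervals.append((0, comp_birth[younger], b))
        parent[younger] = elder
    roots = {find(v) for v in parent}
    for r in roots:
        intervals.append((0, comp_birth[r], INF))

    # --- H1 by reduction of triangle boundary columns over edge bitmasks
    edge_rank = {s: i for i, (s, _) in enumerate(edges)}
    edge_birth = [b for _, b in edges]
    low_to_col: dict[int, int] = {}
    paired_edges: set[int] = set()
    for (i, j, k), b in triangles:
        col = (
            (1 << edge_rank[(i, j)])
            | (1 << edge_rank[(i, k)])
            | (1 << edge_rank[(j, k)])
        )
        while col:
            low = col.bit_length() - 1
            other = low_to_col.get(low)
            if other is None:
                break
            col ^= other
        if col:
            low = col.bit_length() - 1
            low_to_col[low] = col
            paired_edges.add(low)
            if edge_birth[low] < b:
                intervals.append((1, edge_birth[low], b))
        # else: the triangle creates a 2-cycle (not tracked in the 2-skeleton)

    for s, idx in edge_rank.items():
        if positive_edge[s] and idx not in paired_edges:
            intervals.append((1, edge_birth[idx], INF))

    intervals.sort(key=lambda iv: (iv[0], iv[1], iv[2]))
    return Barcode(tuple(intervals))


def betti_timeline(barcode: Barcode, grid: np.ndarray) -> BettiTimeline:
    """Betti numbers b0(t), b1(t) sampled on ``grid`` (interval counting)."""
    grid = np.asarray(grid, dtype=float)
    b0 = np.zeros(grid.size, dtype=int)
    b1 = np.zeros(grid.size, dtype=int)
    for dim, birth, death in barcode.intervals:
        alive = (grid >= birth) & (grid < death)
        if dim == 0:
            b0 += alive
        elif dim == 1:
            b1 += alive
    return BettiTimeline(grid, b0, b1)


def default_grid(duration: float, step: float = 15.0) -> np.ndarray:
    """Sampling grid for Betti timelines (15 s resolution by default)."""
    return np.arange(step, duration + step / 2, step)


def learning_time(
    timeline: BettiTimeline, target: tuple[int, int] = (1, 1)
) -> LearningResult:
    """Earliest sampled t* from which (b0, b1) == target through session end.

    Transient hits do not count; if the target is not stably reached by the
    last sample the result is flagged diverged.
    """
    if timeline.times.size == 0:
        raise ValueError("timeline is empty")
    ok = (timeline.b0 == target[0]) & (timeline.b1 == target[1])
    step = (
        float(timeline.times[1] - timeline.times[0])
        if timeline.times.size > 1
        else 0.0
    )
    # last index where ok is False; stable region starts after it
    bad = np.nonzero(~ok)[0]
    if bad.size == 0:
        return LearningResult(float(timeline.times[0]), target, step)
    first_stable = bad[-1] + 1
    if first_stable >= timeline.times.size:
        return LearningResult(None, target, step)
    return LearningResult(float(timeline.times[first_stable]), target, step)


def count_loops(barcode: Barcode, dim: int = 1) -> int:
    """Total number of dim-1 intervals (finite and infinite) in the barcode.

    This counts every topological loop observed at any moment of learning,
    the measure of "topological noise" accumulated in a session.
    """
    return sum(1 for k, _, _ in barcode.intervals if k == dim)


# ---------------------------------------------------------------- CSV I/O

def barcode_to_csv(barcode: Barcode, path) -> None:
    pd.DataFrame(
        [
            (d, b, ("inf" if math.isinf(dd) else dd))
            for d, b, dd in barcode.intervals
        ],
        columns=["dim", "birth_s", "death_s"],
    ).to_csv(path, index=False)


def barcode_from_csv(path) -> Barcode:
    df = pd.read_csv(path)
    ivs = tuple(
        (int(r.dim), float(r.birth_s), INF if str(r.death_s) == "inf" else float(r.death_s))
        for r in df.itertuples()
    )
    return Barcode(ivs)


def timeline_to_csv(tl: BettiTimeline, path) -> None:
    pd.DataFrame({"t_s": tl.times, "b0": tl.b0, "b1": tl.b1}).to_csv(path, index=False)
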