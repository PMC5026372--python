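"""Coactivity detection and the two filtered coactivity complexes.

A downstream readout neuron integrates place-cell inputs over a window of
width ``w``.  Sliding that window over the session (half-overlapping steps by
default) yields coactivity events: the sets of cells that each fired at
least once inside one window.

Two complexes are built from these events, both restricted to the
2-skeleton (vertices, edges, triangles):

* the *simplicial* coactivity complex (coincidence-detector readout): every
  event of p cells contributes the faces of the (p-1)-simplex, each face
  born at the end of the first window in which its full vertex set co-fired;
* the *clique* coactivity complex (integrator readout): pairwise coactivity
  defines a graph, and every 3-clique whose edges all appeared within a
  working-memory horizon (default 10 min) becomes a triangle born when its
  last edge appeared.

Both are filtrations: faces are always present no later than their cofaces.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .spiking import SpikeTrain

#: default working-memory horizon for clique assembly, seconds
DEFAULT_HORIZON = 600.0


class CoactivityEvent(NamedTuple):
    cells: frozenset
    window_start: float
    window_end: float


@dataclass
class FilteredComplex:
    """Simplexes (sorted vertex tuples, dims 0-2) mapped to birth times."""

    simplexes: dict[tuple, float] = field(default_factory=dict)
    max_dim: int = 2

    def add(self, simplex: tuple, birth: float) -> None:
        """Insert keeping the earliest birth."""
        old = self.simplexes.get(simplex)
        if old is None or birth < old:
            self.simplexes[simplex] = birth

    def count(self, dim: int, t: float = float("inf")) -> int:
        return sum(
            1 for s, b in self.simplexes.items() if len(s) == dim + 1 and b <= t
        )

    def sorted_simplexes(self) -> list[tuple[tuple, float]]:
        """Filtration order: by (birth, dim, vertices) — deterministic."""
        return sorted(self.simplexes.items(), key=lambda kv: (kv[1], len(kv[0]), kv[0]))

    def is_face_closed(self) -> bool:
        for s, b in self.simplexes.items():
            if len(s) == 1:
                continue
            for face in itertools.combinations(s, len(s) - 1):
                fb = self.simplexes.get(face)
                if fb is None or fb > b + 1e-12:
                    return False
        return True

    @property
    def end_time(self) -> float:
        return max(self.simplexes.values(), default=0.0)


@dataclass
class CoactivityGraph:
    """Pairwise coactivity graph.

    ``edges`` maps (i, j) to the first-coactivity time; ``observations``
    keeps every window end at which the pair co-fired (ascending), which is
    what a readout integrator with a finite working-memory span sees.
    """

    vertices: set = field(default_factory=set)
    edges: dict[tuple, float] = field(default_factory=dict)
    observations: dict[tuple, list] = field(default_factory=dict)

    def add_edge(self, i, j, t: float) -> None:
        if i == j:
            raise ValueError("self-loops are not allowed")
        key = (i, j) if i < j else (j, i)
        old = self.edges.get(key)
        if old is None or t < old:
            self.edges[key] = t
        obs = self.observations.setdefault(key, [])
        if not obs or t > obs[-1]:
            obs.append(t)
        else:
            import bisect

            bisect.insort(obs, t)
        self.vertices.add(i)
        self.vertices.add(j)


def detect_coactivity(
    trains: Sequence[SpikeTrain],
    w: float,
    step: float | None = None,
    t_end: float | None = None,
    min_spikes: int = 1,
) -> list[CoactivityEvent]:
    """Slide windows of width ``w`` (step ``w/2`` by default) over the session.

    Every window in which at least two distinct cells produced
    ``min_spikes`` spikes or more emits one event holding exactly the active
    cells.  Windows are [start, start + w); starts are 0, step, 2*step, ...
    up to ``t_end`` (default: last spike time).  Deterministic.
    """
    if w <= 0:
        raise ValueError("window width w must be positive")
    step = w / 2.0 if step is None else step
    if step <= 0:
        raise ValueError("step must be positive")

    active = [tr for tr in trains if tr.n > 0]
    if not active:
        return []
    times = np.concatenate([tr.times for tr in active])
    cells = np.concatenate([np.full(tr.n, tr.cell_id) for tr in active])
    order = np.argsort(times, kind="stable")
    times, cells = times[order], cells[order]

    if t_end is None:
        t_end = float(times[-1])
    n_win = int(np.floor(t_end / step)) + 1
    starts = np.arange(n_win) * step
    lo = np.searchsorted(times, starts, side="left")
    hi = np.searchsorted(times, starts + w, side="left")

    events: list[CoactivityEvent] = []
    prev_key: tuple | None = None
    for s, a, b in zip(starts, lo, hi):
        if b - a < 2:
            continue
        window_cells = cells[a:b]
        if min_spikes <= 1:
            uniq = np.unique(window_cells)
        else:
            ids, counts = np.unique(window_cells, return_counts=True)
            uniq = ids[counts >= min_spikes]
        if uniq.size < 2:
            continue
        key = tuple(int(c) for c in uniq)
        # skip windows whose active set repeats the previous window's: they
        # contribute no new simplex and no earlier birth
        if key == prev_key:
            continue
        prev_key = key
        events.append(CoactivityEvent(frozenset(key), float(s), float(s + w)))
    return events


def build_simplicial_complex(
    events: Iterable[CoactivityEvent], max_dim: int = 2
) -> FilteredComplex:
    """Coincidence-detector complex: events contribute their <=2-dim faces.

    The birth of a simplex is the end of the first window in which its full
    vertex set co-fired; inserting every face of every event enforces face
    closure with monotone births.
    """
    fc = FilteredComplex(max_dim=max_dim)
    add = fc.add
    for ev in events:
        verts = sorted(ev.cells)
        birth = ev.window_end
        for v in verts:
            add((v,), birth)
        for e in itertools.combinations(verts, 2):
            add(e, birth)
        if max_dim >= 2:
            for tri in itertools.combinations(verts, 3):
                add(tri, birth)
    return fc


def build_coactivity_graph(
    trains: Sequence[SpikeTrain],
    w: float,
    step: float | None = None,
    t_end: float | None = None,
    events: Sequence[CoactivityEvent] | None = None,
) -> CoactivityGraph:
    """Pairwise coactivity graph G: edge (i, j) iff i, j co-fired in a window.

    Edge time = end of the first such window.  Precomputed ``events`` (from
    :func:`detect_coactivity` with the same parameters) may be passed in.
    """
    if events is None:
        events = detect_coactivity(trains, w, step=step, t_end=t_end)
    g = CoactivityGraph()
    for ev in events:
        verts = sorted(ev.cells)
        for i, j in itertools.combinations(verts, 2):
            g.add_edge(i, j, ev.window_end)
    return g


def _clique_birth(obs_a, obs_b, obs_c, horizon: float) -> float | None:
    """Earliest time at which all three edges have been observed within one
    ``horizon``-length working-memory window; None if that never happens."""
    ia = ib = ic = 0
    na, nb, nc = len(obs_a), len(obs_b), len(obs_c)
    while ia < na and ib < nb and ic < nc:
        ta, tb, tc = obs_a[ia], obs_b[ib], obs_c[ic]
        hi = max(ta, tb, tc)
        lo = min(ta, tb, tc)
        if hi - lo <= horizon:
            return hi
        # advance the earliest observation
        if lo == ta:
            ia += 1
        elif lo == tb:
            ib += 1
        else:
            ic += 1
    return None


def build_clique_complex(
    graph: CoactivityGraph, horizon: float = DEFAULT_HORIZON
) -> FilteredComplex:
    """Integrator complex: cliques of G become simplexes.

    Vertices are born with their first incident edge.  A 3-clique becomes a
    triangle as soon as its three pairwise connections have all been
    observed within one working-memory span of length ``horizon``
    (connections may be accumulated over time, but only re-observations
    within the span count); its birth is the completing observation.  A
    graph built without observation lists degenerates to the first-birth
    rule: the triangle forms iff the three edge births span at most
    ``horizon``, born at the latest one.
    """
    fc = FilteredComplex()
    vertex_birth: dict = {}
    adj: dict = {v: set() for v in graph.vertices}
    for (i, j), t in graph.edges.items():
        fc.add((i, j), t)
        for v in (i, j):
            old = vertex_birth.get(v)
            if old is None or t < old:
                vertex_birth[v] = t
        adj[i].add(j)
        adj[j].add(i)
    for v, t in vertex_birth.items():
        fc.add((v,), t)

    edges = graph.edges
    obs = graph.observations

    def edge_obs(a, b):
        key = (a, b) if a < b else (b, a)
        got = obs.get(key)
        return got if got else [edges[key]]

    for (i, j), t_ij in edges.items():
        common = adj[i] & adj[j]
        for k in common:
            if k <= j:
                continue  # each triangle once, via its two smallest vertices
            birth = _clique_birth(
                edge_obs(i, j), edge_obs(i, k), edge_obs(j, k), horizon
            )
            if birth is not None:
                fc.add((i, j, k), birth)
    return fc


def count_simplexes(fc: FilteredComplex, dim: int, t: float = float("inf")) -> int:
    """Number of simplexes of dimension ``dim`` with birth <= t."""
    if not (0 <= dim <= fc.max_dim):
        raise ValueError(f"dim must be in [0, {fc.max_dim}]")
    return fc.count(dim, t)


# ------------------------------------------------------------- text I/O

def complex_to_text(fc: FilteredComplex, path) -> None:
    """One simplex per line: 'v1[,v2[,v3]] <tab> birth_s', ascending birth."""
    with open(path, "w") as fh:
        for simplex, birth in sorted(fc.simplexes.items(), key=lambda kv: (kv[1], kv[0])):
            fh.write(",".join(str(v) for v in simplex) + f"\t{birth:.6f}\n")


def complex_from_text(path) -> FilteredComplex:
    fc = FilteredComplex()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            verts, birth = line.split("\t")
            fc.add(tuple(int(v) for v in verts.split(",")), float(birth))
    return fc


def graph_to_csv(graph: CoactivityGraph, path) -> None:
    import pandas as pd

    rows = sorted((i, j, t) for (i, j), t in graph.edges.items())
    pd.DataFrame(rows, columns=["i", "j", "t_s"]).to_csv(path, index=False)
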