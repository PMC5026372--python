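"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: dense GF(2) Gaussian elimination for
homology, full column-by-column reduction for persistence, and exhaustive
window enumeration for coactivity — quadratic/cubic algorithms that are
easy to verify by eye and feasible only on tiny inputs.
"""

from __future__ import annotations

import itertools

import numpy as np

INF = float("inf")


# ---------------------------------------------------------- linear algebra

def gf2_rank(M: np.ndarray) -> int:
    """Rank over GF(2) by plain Gaussian elimination."""
    A = (np.array(M, dtype=np.uint8) % 2).copy()
    rank = 0
    rows, cols = A.shape
    for c in range(cols):
        pivot = None
        for r in range(rank, rows):
            if A[r, c]:
                pivot = r
                break
        if pivot is None:
            continue
        A[[rank, pivot]] = A[[pivot, rank]]
        for r in range(rows):
            if r != rank and A[r, c]:
                A[r] ^= A[rank]
        rank += 1
    return rank


def betti_numbers_at(simplexes: dict, t: float) -> tuple[int, int, int]:
    """(b0, b1, b2) of the subcomplex {s : birth(s) <= t} by rank counting."""
    verts = sorted(s[0] for s, b in simplexes.items() if len(s) == 1 and b <= t)
    edges = sorted(s for s, b in simplexes.items() if len(s) == 2 and b <= t)
    tris = sorted(s for s, b in simplexes.items() if len(s) == 3 and b <= t)
    nv, ne, nf = len(verts), len(edges), len(tris)
    vi = {v: i for i, v in enumerate(verts)}
    ei = {e: i for i, e in enumerate(edges)}

    d1 = np.zeros((nv, ne), dtype=np.uint8)
    for j, (u, v) in enumerate(edges):
        d1[vi[u], j] = 1
        d1[vi[v], j] = 1
    d2 = np.zeros((ne, nf), dtype=np.uint8)
    for j, (a, b, c) in enumerate(tris):
        d2[ei[(a, b)], j] = 1
        d2[ei[(a, c)], j] = 1
        d2[ei[(b, c)], j] = 1

    r1 = gf2_rank(d1) if ne else 0
    r2 = gf2_rank(d2) if nf else 0
    b0 = nv - r1
    b1 = (ne - r1) - r2
    b2 = nf - r2
    return b0, b1, b2


# ------------------------------------------------------------- persistence

def barcode_bruteforce(simplexes: dict) -> list[tuple[int, float, float]]:
    """Full persistence by textbook column reduction of the whole boundary
    matrix (all dimensions at once), dropping zero-length pairs.

    Returns sorted (dim, birth, death) with death = inf for survivors;
    only dimensions 0 and 1 are reported (2-skeleton input).
    """
    order = sorted(simplexes.items(), key=lambda kv: (kv[1], len(kv[0]), kv[0]))
    index = {s: i for i, (s, _) in enumerate(order)}
    m = len(order)
    cols: list[set] = []
    for s, _ in order:
        if len(s) == 1:
            cols.append(set())
        else:
            cols.append({index[f] for f in itertools.combinations(s, len(s) - 1)})

    low_of: dict[int, int] = {}
    pairs: list[tuple[int, int]] = []
    for j in range(m):
        col = cols[j]
        while col:
            low = max(col)
            if low not in low_of:
                break
            col ^= cols[low_of[low]]
        if col:
            low_of[max(col)] = j
            pairs.append((max(col), j))

    paired = {i for p in pairs for i in p}
    out = []
    for i, j in pairs:
        dim = len(order[i][0]) - 1
        birth, death = order[i][1], order[j][1]
        if death > birth and dim <= 1:
            out.append((dim, birth, death))
    for i in range(m):
        if i not in paired:
            dim = len(order[i][0]) - 1
            if dim <= 1:
                out.append((dim, order[i][1], INF))
    out.sort()
    return out


# -------------------------------------------------------------- coactivity

def coactivity_bruteforce(trains, w: float, step: float, t_end: float):
    """All (start, active-cell-set) windows with >= 2 distinct active cells,
    checked spike by spike; consecutive duplicate sets collapsed."""
    starts = []
    k = 0
    while k * step <= t_end:
        starts.append(k * step)
        k += 1
    events = []
    prev = None
    for s in starts:
        active = set()
        for tr in trains:
            if any(s <= t < s + w for t in tr.times):
                active.add(tr.cell_id)
        if len(active) >= 2 and active != prev:
            events.append((s, frozenset(active)))
            prev = active
        elif len(active) >= 2:
            prev = active
    return events


def simplicial_complex_bruteforce(events, max_dim: int = 2) -> dict:
    """First-birth union of all faces of all events."""
    out: dict = {}
    for s, cells in events:
        verts = sorted(cells)
        for d in range(1, min(len(verts), max_dim + 1) + 1):
            for face in itertools.combinations(verts, d):
                birth = s  # caller passes window end as s if desired
                if face not in out or birth < out[face]:
                    out[face] = birth
    return out


def clique_birth_bruteforce(obs_a, obs_b, obs_c, horizon: float):
    """Earliest completion time by trying every observation as completion."""
    best = None
    for T in sorted(set(obs_a) | set(obs_b) | set(obs_c)):
        ok = all(
            any(T - horizon <= t <= T for t in obs) for obs in (obs_a, obs_b, obs_c)
        )
        if ok:
            best = T
            break
    return best
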