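"""Place-cell ensembles and spatial Poisson rates.

A place cell ``c`` fires around its field center ``r_c`` with the Gaussian
rate

    lambda_c(r) = f_c * exp(-|r - r_c|**2 / (2 s_c**2)),

where ``f_c`` is the peak rate and ``s_c`` the Gaussian width; the place
field extent is L_c = 3 s_c.  An ensemble is summarized by the triplet
(s, f, N): ensemble-mean width, ensemble-mean peak rate and cell count.
Individual ``s_c`` and ``f_c`` are lognormal with means (s, f) and standard
deviations (b*s, a*f), matching the heterogeneity of recorded populations;
field centers are uniform over the free space of the arena.

The headline ensemble of the study has mean field extent 24 cm (s = 0.08 m),
f = 20 Hz and N = 450 cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _field

import numpy as np
import pandas as pd

from .arena import Arena


@dataclass(frozen=True)
class PlaceCell:
    id: int
    r_c: tuple[float, float]
    s_c: float
    f_c: float

    @property
    def L_c(self) -> float:
        """Place-field extent (diameter), L_c = 3 s_c."""
        return 3.0 * self.s_c


@dataclass(frozen=True)
class PlaceMapParams:
    """Ensemble parameters (s, f, N) plus dispersion coefficients.

    ``s`` is the ensemble-mean Gaussian width in metres (mean field extent
    3*s), ``f`` the ensemble-mean peak rate in Hz, and ``a``/``b`` the
    coefficients of variation of the rate and width lognormals.
    """

    s: float = 0.08
    f: float = 20.0
    N: int = 450
    a: float = 0.25
    b: float = 0.25

    def __post_init__(self):
        if self.s <= 0 or self.f <= 0:
            raise ValueError("s and f must be positive")
        if self.N < 0 or self.a < 0 or self.b < 0:
            raise ValueError("N, a, b must be non-negative")


@dataclass(frozen=True)
class PlaceMap:
    params: PlaceMapParams
    cells: tuple[PlaceCell, ...] = _field(default_factory=tuple)

    @property
    def N(self) -> int:
        return len(self.cells)

    def centers(self) -> np.ndarray:
        return np.array([c.r_c for c in self.cells]).reshape(self.N, 2)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal matching the given natural-scale
    mean and SD: sigma^2 = ln(1 + sd^2/mean^2), mu = ln(mean) - sigma^2/2."""
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def generate_place_map(
    params: PlaceMapParams, arena: Arena, seed: int | None = None
) -> PlaceMap:
    """Draw an ensemble: lognormal (s_c, f_c), centers uniform over free space.

    With a = b = 0 the lognormals degenerate to the exact means.  Fields
    whose Gaussian tail crosses a wall are simply truncated by the boundary
    (no renormalization).  Deterministic given ``seed``.
    """
    if params.N > 0 and arena.free_area <= 0:
        raise ValueError("cannot place cells in an arena with no free space")
    rng = np.random.default_rng(seed)
    n = params.N
    if n == 0:
        return PlaceMap(params, ())

    if params.b > 0:
        mu, sg = _lognormal_params(params.s, params.b * params.s)
        s_c = rng.lognormal(mu, sg, n)
    else:
        s_c = np.full(n, params.s)
    if params.a > 0:
        mu, sg = _lognormal_params(params.f, params.a * params.f)
        f_c = rng.lognormal(mu, sg, n)
    else:
        f_c = np.full(n, params.f)

    centers = np.empty((n, 2))
    placed = 0
    while placed < n:
        m = n - placed
        xs = rng.uniform(0, arena.width, m)
        ys = rng.uniform(0, arena.height, m)
        ok = arena.contains(xs, ys)
        k = int(np.count_nonzero(ok))
        centers[placed : placed + k, 0] = xs[ok]
        centers[placed : placed + k, 1] = ys[ok]
        placed += k

    cells = tuple(
        PlaceCell(i, (float(centers[i, 0]), float(centers[i, 1])), float(s_c[i]), float(f_c[i]))
        for i in range(n)
    )
    return PlaceMap(params, cells)


def rate_at(cell: PlaceCell, r) -> np.ndarray | float:
    """Gaussian Poisson rate lambda_c(r), Hz.  ``r`` is (x, y) or (n, 2)."""
    r = np.asarray(r, dtype=float)
    d2 = np.sum((r - np.asarray(cell.r_c)) ** 2, axis=-1)
    return cell.f_c * np.exp(-d2 / (2.0 * cell.s_c**2))


# ---------------------------------------------------------------- CSV I/O

def place_map_to_csv(pm: PlaceMap, path) -> None:
    pd.DataFrame(
        {
            "id": [c.id for c in pm.cells],
            "x_c_m": [c.r_c[0] for c in pm.cells],
            "y_c_m": [c.r_c[1] for c in pm.cells],
            "s_c_m": [c.s_c for c in pm.cells],
            "f_c_hz": [c.f_c for c in pm.cells],
        }
    ).to_csv(path, index=False)


def place_map_from_csv(path, params: PlaceMapParams | None = None) -> PlaceMap:
    df = pd.read_csv(path)
    cells = tuple(
        PlaceCell(int(r.id), (float(r.x_c_m), float(r.y_c_m)), float(r.s_c_m), float(r.f_c_hz))
        for r in df.itertuples()
    )
    if params is None:
        s = float(np.mean(df["s_c_m"])) if len(df) else 0.08
        f = float(np.mean(df["f_c_hz"])) if len(df) else 20.0
        params = PlaceMapParams(s=s, f=f, N=len(df))
    return PlaceMap(params, cells)
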