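import numpy as np
import pytest

import placetopo as pt


@pytest.fixture(scope="session")
def arena():
    return pt.default_arena()


@pytest.fixture(scope="session")
def lfp60():
    """One minute of synthetic LFP at the defaults."""
    return pt.synthesize_lfp(60.0, seed=101)


@pytest.fixture(scope="session")
def traj60(arena):
    return pt.simulate_trajectory(arena, 60.0, seed=102)


@pytest.fixture(scope="session")
def troughs60(lfp60):
    return pt.detect_troughs(lfp60.gamma_scaled, lfp60.fs)


@pytest.fixture(scope="session")
def small_map(arena):
    """A reduced ensemble for fast whole-pipeline tests."""
    params = pt.PlaceMapParams(s=0.08, f=20.0, N=120)
    return pt.generate_place_map(params, arena, seed=103)


@pytest.fixture(scope="session")
def small_trains(small_map, traj60, lfp60):
    """Spike trains of the reduced ensemble at beta = 0 and beta = 2."""
    return {
        beta: pt.generate_ensemble_spikes(small_map, traj60, lfp60, beta, seed=104)
        for beta in (0.0, 2.0)
    }


def random_filtered_complex(rng, n_vertices=8, p_edge=0.5, p_tri=0.6):
    """A random face-closed filtration on <= n_vertices vertices."""
    fc = pt.FilteredComplex()
    verts = list(range(n_vertices))
    for v in verts:
        fc.add((v,), float(rng.integers(0, 5)))
    import itertools

    for e in itertools.combinations(verts, 2):
        if rng.random() < p_edge:
            lo = max(fc.simplexes[(e[0],)], fc.simplexes[(e[1],)])
            fc.add(e, float(lo + rng.integers(0, 5)))
    for t in itertools.combinations(verts, 3):
        faces = [(t[0], t[1]), (t[0], t[2]), (t[1], t[2])]
        if all(f in fc.simplexes for f in faces) and rng.random() < p_tri:
            lo = max(fc.simplexes[f] for f in faces)
            fc.add(t, float(lo + rng.integers(0, 5)))
    return fc


def random_trains(rng, n_cells=8, duration=10.0, rate=2.0):
    """Independent Poisson spike trains for oracle comparisons."""
    out = []
    for c in range(n_cells):
        n = rng.poisson(rate * duration)
        out.append(pt.SpikeTrain(c, np.sort(rng.uniform(0, duration, n))))
    return out
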