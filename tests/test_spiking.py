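import math

import numpy as np
import pytest

import placetopo as pt
from placetopo.arena import Trajectory
from placetopo.spiking import (
    circular_diff,
    gamma_phase_histogram,
    pooled_isi_hist,
    theta_gate_normalizer,
)

TWO_PI = 2 * math.pi
THETA_PERIOD = 0.125


def straight_crossing_trajectory(duration, dt=0.001, x0=0.05, x1=0.95, y=0.2):
    """Back-and-forth sweeps along a horizontal line (constant speed)."""
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    period = 8.0  # seconds per full back-and-forth
    phase = (t % period) / period
    x = np.where(phase < 0.5, x0 + (x1 - x0) * 2 * phase, x1 - (x1 - x0) * 2 * (phase - 0.5))
    y_arr = np.full(n, y)
    v = 2 * (x1 - x0) / period
    return Trajectory(t, x, y_arr, v)


class TestFieldTraversal:
    def test_never_entering_field_is_all_nan(self, traj60):
        far = pt.PlaceCell(0, (10.0, 10.0), 0.08, 20.0)
        assert np.isnan(pt.field_traversal(far, traj60)).all()

    def test_straight_chord_grows_linearly_to_extent(self):
        tr = straight_crossing_trajectory(4.0)
        cell = pt.PlaceCell(0, (0.5, 0.2), 0.08, 20.0)
        l_t = pt.field_traversal(cell, tr)
        inside = np.isfinite(l_t)
        first = np.nonzero(inside)[0]
        run = first[first < np.searchsorted(tr.t, 4.0)]
        seg = l_t[run[0] : run[0] + 100]
        d = np.diff(seg)
        assert seg[0] == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(d, d[0], rtol=1e-6)
        assert np.nanmax(l_t) == pytest.approx(cell.L_c, abs=1e-3)

    def test_arc_traversal_equals_polygonal_length(self):
        # quarter-circle of radius 0.1 inside a field centered at the origin
        dt = 0.001
        th = np.linspace(0, math.pi / 2, 2001)
        x = 0.5 + 0.1 * np.cos(th)
        y = 0.5 + 0.1 * np.sin(th)
        tr = Trajectory(np.arange(th.size) * dt, x, y, 0.1)
        cell = pt.PlaceCell(0, (0.5, 0.5), 0.08, 20.0)
        l_t = pt.field_traversal(cell, tr)
        poly = np.sum(np.hypot(np.diff(x), np.diff(y)))
        assert l_t[-1] == pytest.approx(poly, rel=1e-9)


class TestPhaseAndGates:
    @pytest.mark.parametrize(
        "l, expected", [(0.0, 0.0), (0.12, math.pi), (0.24, 0.0)]
    )
    def test_preferred_phase_endpoints(self, l, expected):
        assert pt.preferred_phase(l, 0.24) == pytest.approx(expected, abs=1e-12)

    def test_preferred_phase_clamps_and_warns(self):
        with pytest.warns(UserWarning):
            out = pt.preferred_phase(np.array([0.3]), 0.24)
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_theta_factor_peak_and_half_width(self):
        eps = 0.5
        assert pt.theta_factor(1.0, 1.0, eps) == pytest.approx(1.0)
        d = eps * math.sqrt(2 * math.log(2))
        assert pt.theta_factor(1.0 + d, 1.0, eps) == pytest.approx(0.5, rel=1e-9)

    def test_theta_factor_uses_circular_distance(self):
        eps = 0.3
        near_wrap = pt.theta_factor(0.05, TWO_PI - 0.05, eps)
        assert near_wrap == pytest.approx(math.exp(-(0.1**2) / (2 * eps**2)))

    def test_tuning_width_formula(self):
        # v = 0.2 m/s, L = 0.72 m, omega = 2*pi*8 -> 2*pi*v/(L*omega) ~ 0.0347
        eps = pt.tuning_width(0.2, 0.72, TWO_PI * 8.0)
        assert eps == pytest.approx(2 * math.pi * 0.2 / (0.72 * TWO_PI * 8.0))
        assert eps == pytest.approx(0.0347, abs=5e-4)

    def test_theta_gate_normalizer_matches_quadrature(self):
        from scipy.integrate import quad

        for eps in (0.1, 0.65, 2.0):
            z, _ = quad(lambda u: math.exp(-(u**2) / (2 * eps**2)), -math.pi, math.pi)
            assert theta_gate_normalizer(eps) == pytest.approx(z / TWO_PI, rel=1e-9)

    def test_gamma_factor_unit_mean_and_hot_limit(self, lfp60):
        A = lfp60.gamma_scaled
        assert np.array_equal(pt.gamma_factor(A, 0.0), np.ones_like(A))
        lam = pt.gamma_factor(A, 2.0)
        assert np.mean(lam) == pytest.approx(1.0, abs=1e-6)
        # trough beats peak for any positive coupling
        assert lam[np.argmin(A)] > lam[np.argmax(A)]


class TestGenerateSpikes:
    def test_far_cell_is_silent(self, traj60, lfp60):
        far = pt.PlaceCell(0, (10.0, 10.0), 0.08, 20.0)
        train = pt.generate_spikes(far, traj60, lfp60, beta=0.0, seed=0)
        assert train.n == 0

    def test_deterministic_given_seed(self, small_map, traj60, lfp60):
        a = pt.generate_spikes(small_map.cells[0], traj60, lfp60, 1.0, seed=9)
        b = pt.generate_spikes(small_map.cells[0], traj60, lfp60, 1.0, seed=9)
        assert np.array_equal(a.times, b.times)

    def test_times_strictly_increasing_in_session(self, small_trains):
        for trains in small_trains.values():
            for tr in trains:
                if tr.n > 1:
                    assert (np.diff(tr.times) > 0).all()

    def test_grid_mismatch_rejected(self, small_map, traj60):
        other = pt.synthesize_lfp(30.0, seed=0)
        with pytest.raises(ValueError):
            pt.generate_spikes(small_map.cells[0], traj60, other, 0.0, seed=0)

    def test_unmodulated_generator_is_poisson(self, arena):
        """With both gates off and the animal parked at the field center,
        counts over 200 seeds match Poisson(f_c * T) in mean and variance."""
        lfp = pt.synthesize_lfp(10.0, seed=0)
        n = lfp.n
        tr = Trajectory(lfp.t, np.full(n, 0.2), np.full(n, 0.2), 0.0)
        cell = pt.PlaceCell(0, (0.2, 0.2), 0.08, 20.0)
        counts = [
            pt.generate_spikes(
                cell, tr, lfp, 0.0, seed=s, theta_modulation=False
            ).n
            for s in range(200)
        ]
        counts = np.asarray(counts, dtype=float)
        expect = 20.0 * 10.0
        assert abs(counts.mean() - expect) < 3 * math.sqrt(expect / 200)
        assert 0.7 < counts.var() / counts.mean() < 1.3

    def test_gamma_phase_concentration_increases_with_beta(
        self, small_trains, lfp60
    ):
        """Cooling couples spikes to the gamma troughs: the circular variance
        of spike gamma-phases drops and mass accumulates near +-pi."""
        _, _, cv_hot = gamma_phase_histogram(small_trains[0.0], lfp60)
        hist, edges, cv_cold = gamma_phase_histogram(small_trains[2.0], lfp60)
        assert cv_cold < cv_hot
        centers = (edges[:-1] + edges[1:]) / 2
        trough_mass = hist[np.abs(centers) > 3 * math.pi / 4].sum()
        assert trough_mass > 0.5


class TestSpikeSpread:
    def test_spikes_exactly_at_deep_troughs_have_zero_spread(self, troughs60):
        deep = pt.deep_troughs(troughs60)
        times = np.array([g.t_i for g in deep[:40]])
        trains = [
            pt.SpikeTrain(0, times),
            pt.SpikeTrain(1, times + 1e-4),
        ]
        est = pt.spike_spread(trains, troughs60, THETA_PERIOD)
        assert est.delta == pytest.approx(0.0, abs=1e-3)
        assert est.n_events > 0

    def test_uniform_window_spread(self, troughs60):
        """Spikes uniform on +-W/2 around deep troughs: |offset| is uniform
        on [0, W/2], so the 68th-percentile full width is 2*0.68*W/2."""
        rng = np.random.default_rng(0)
        deep = [g.t_i for g in pt.deep_troughs(troughs60)]
        W = 0.02
        a = np.sort(np.array(deep) + rng.uniform(-W / 2, W / 2, len(deep)))
        b = np.sort(np.array(deep) + rng.uniform(-W / 2, W / 2, len(deep)))
        est = pt.spike_spread(
            [pt.SpikeTrain(0, a), pt.SpikeTrain(1, b)], troughs60, THETA_PERIOD
        )
        assert est.delta == pytest.approx(2 * 0.68 * W / 2, rel=0.15)

    def test_gaussian_offsets_recover_two_sigma(self, troughs60):
        """Gaussian jitter around deep troughs: Delta -> 2*sigma."""
        rng = np.random.default_rng(1)
        deep = np.array([g.t_i for g in pt.deep_troughs(troughs60)])
        sigma = 0.004
        a = np.sort(deep + rng.normal(0, sigma, deep.size))
        b = np.sort(deep + rng.normal(0, sigma, deep.size))
        est = pt.spike_spread(
            [pt.SpikeTrain(0, a), pt.SpikeTrain(1, b)], troughs60, THETA_PERIOD
        )
        assert est.delta == pytest.approx(2 * sigma, rel=0.15)

    def test_no_coactivity_flags_empty(self, troughs60):
        single = [pt.SpikeTrain(0, np.array([1.0, 2.0]))]
        est = pt.spike_spread(single, troughs60, THETA_PERIOD)
        assert est.n_events == 0 and not est.valid

    def test_monotone_nonincreasing_in_beta(
        self, small_map, traj60, lfp60, troughs60
    ):
        deltas = []
        for beta in (0.0, 1.0, 2.0):
            trains = pt.generate_ensemble_spikes(
                small_map, traj60, lfp60, beta, seed=104
            )
            deltas.append(
                pt.spike_spread(trains, troughs60, lfp60.theta_period, beta=beta).delta
            )
        assert deltas[0] >= deltas[1] >= deltas[2]


class TestISIStats:
    def test_two_spikes_single_interval(self):
        h, bins = pt.isi_stats(pt.SpikeTrain(0, np.array([0.0, 0.02])))
        assert h.sum() == pytest.approx(1.0)
        k = np.nonzero(h)[0]
        assert bins[k[0]] <= 0.02 < bins[k[0] + 1]

    def test_periodic_train_is_a_single_bin(self):
        times = np.arange(100) * (THETA_PERIOD / 7)
        h, _ = pt.isi_stats(pt.SpikeTrain(0, times))
        assert np.count_nonzero(h) == 1

    def test_insufficient_events_empty(self):
        h, _ = pt.isi_stats(pt.SpikeTrain(0, np.array([1.0])))
        assert h.sum() == 0
        h2, _ = pt.trough_interval_stats([])
        assert h2.sum() == 0

    def test_isi_approaches_trough_intervals_with_cooling(
        self, small_map, traj60, lfp60, troughs60
    ):
        """As beta grows the (burst-collapsed) ISI histogram moves toward the
        deep-trough interval histogram: spike timing becomes controlled by
        the deep troughs.  Spikes closer than half a gamma period are one
        burst event and collapse to its onset."""

        def collapse(times, refractory=0.009):
            if times.size == 0:
                return times
            keep = np.concatenate(([True], np.diff(times) > refractory))
            return times[keep]

        ref, _ = pt.trough_interval_stats(troughs60)
        tvs = []
        for beta in (0.0, 1.0, 2.0):
            trains = pt.generate_ensemble_spikes(
                small_map, traj60, lfp60, beta, seed=104
            )
            events = [pt.SpikeTrain(tr.cell_id, collapse(tr.times)) for tr in trains]
            h, _ = pooled_isi_hist(events)
            tvs.append(pt.tv_distance(h, ref))
        assert tvs[0] > tvs[2]
        assert tvs[0] > tvs[1]


@pytest.fixture(scope="module")
def crossing_setup():
    lfp = pt.synthesize_lfp(600.0, seed=31)
    tr = straight_crossing_trajectory(600.0)
    cell = pt.PlaceCell(0, (0.5, 0.2), 0.08, 20.0)
    return lfp, tr, cell


class TestInvariancesUnderCooling:
    """Place fields and precession are properties of the spatial and theta
    gates; the gamma factor must not reshape them."""

    def _rate_profile(self, cell, tr, train, nbins=16):
        idx = np.clip(np.round(train.times / tr.dt).astype(int), 0, tr.n - 1)
        spike_x = tr.x[idx]
        occ, edges = np.histogram(tr.x, bins=nbins, range=(0.3, 0.7))
        cnt, _ = np.histogram(spike_x, bins=edges)
        rate = cnt / np.maximum(occ, 1)
        return rate / max(rate.max(), 1e-12)

    def test_rate_map_shape_invariant(self, crossing_setup):
        lfp, tr, cell = crossing_setup
        profiles = {}
        for beta in (0.0, 2.0):
            train = pt.generate_spikes(cell, tr, lfp, beta, seed=41)
            profiles[beta] = self._rate_profile(cell, tr, train)
        r = np.corrcoef(profiles[0.0], profiles[2.0])[0, 1]
        assert r > 0.8

    def test_precession_slope_negative_at_all_betas(self, crossing_setup):
        lfp, tr, cell = crossing_setup
        l_t = pt.field_traversal(cell, tr)
        for beta in (0.0, 2.0):
            train = pt.generate_spikes(cell, tr, lfp, beta, seed=42)
            idx = np.clip(np.round(train.times / tr.dt).astype(int), 0, tr.n - 1)
            ok = np.isfinite(l_t[idx])
            l_rel = l_t[idx][ok] / cell.L_c
            phases = lfp.theta_phase[idx][ok]
            # unwrap around the preferred-phase line: phase - 2*pi*(1 - l)
            resid = circular_diff(phases, TWO_PI * (1 - l_rel))
            phi = TWO_PI * (1 - l_rel) + resid
            slope = np.polyfit(l_rel, phi, 1)[0]
            assert slope < 0
            assert abs(slope + TWO_PI) < 0.5 * TWO_PI
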