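"""Unit tests for the lattice geometry and the delay-SDE simulator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from her6osc.grid_model import (
    Lattice,
    ModelParams,
    deterministic_steady_state,
    hill_auto,
    hill_li,
    langevin_noise,
    neighbour_average,
    simulate,
)


def brute_force_neighbours(rows, cols, r, c):
    """Geometric adjacency oracle: cells within one hex step in the odd-r
    axial embedding (centres at x = c + 0.5*(r odd), y = r * sqrt(3)/2)."""
    def centre(rr, cc):
        return np.array([cc + 0.5 * (rr % 2), rr * np.sqrt(3) / 2])

    out = []
    for rr in range(rows):
        for cc in range(cols):
            if (rr, cc) == (r, c):
                continue
            if np.linalg.norm(centre(r, c) - centre(rr, cc)) < 1.01:
                out.append(rr * cols + cc)
    return sorted(out)


class TestLattice:
    def test_matches_geometric_oracle_everywhere(self):
        lat = Lattice(10, 6)
        for r in range(10):
            for c in range(6):
                assert lat.neighbour_sets[r * 6 + c] == \
                    brute_force_neighbours(10, 6, r, c)

    def test_interior_cells_have_six_neighbours(self):
        lat = Lattice(10, 6)
        for r in range(2, 8):
            for c in range(2, 4):
                assert lat.degree(r * 6 + c) == 6

    def test_corner_cells_keep_only_geometric_neighbours(self):
        lat = Lattice(10, 6)
        for corner in (0, 5, 54, 59):
            assert 2 <= lat.degree(corner) <= 3

    @given(rows=st.integers(2, 8), cols=st.integers(2, 8))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_adjacency_symmetric_no_self_loops(self, rows, cols):
        lat = Lattice(rows, cols)
        for i, nbrs in enumerate(lat.neighbour_sets):
            assert i not in nbrs
            assert len(nbrs) >= 2
            for j in nbrs:
                assert i in lat.neighbour_sets[j]
        assert sum(map(len, lat.neighbour_sets)) % 2 == 0


class TestHillFunctions:
    @pytest.mark.parametrize("p, P0, n, expected", [
        (0.0, 100.0, 4.0, 1.0),
        (100.0, 100.0, 4.0, 0.5),
        (100.0, 100.0, 1.0, 0.5),
        (200.0, 100.0, 4.0, 1.0 / 17.0),
    ])
    def test_autoinhibition_values(self, p, P0, n, expected):
        assert hill_auto(p, P0, n) == pytest.approx(expected, rel=1e-12)

    def test_lateral_inhibition_values(self):
        assert hill_li(0.0, 500.0, 2.0) == 1.0
        assert hill_li(500.0, 500.0, 3.0) == 0.5
        assert hill_li(1500.0, 500.0, 2.0) == pytest.approx(0.1)

    @given(st.floats(0.0, 1e5), st.floats(0.1, 1e4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_decreasing_in_p(self, p, P0):
        assert hill_auto(p + 1.0, P0, 3.0) < hill_auto(p, P0, 3.0)

    def test_rejects_corrupted_state(self):
        with pytest.raises(ValueError):
            hill_auto(-1.0, 100.0, 2.0)
        with pytest.raises(ValueError):
            hill_auto(np.nan, 100.0, 2.0)


class TestNeighbourAverage:
    def test_uniform_field_is_fixed_point(self):
        lat = Lattice(10, 6)
        p = np.full(60, 500.0)
        for i in range(60):
            assert neighbour_average(p, lat, i) == pytest.approx(500.0)

    def test_interior_cell_mean_of_six(self):
        lat = Lattice(5, 5)
        cell = 2 * 5 + 2
        nbrs = lat.neighbour_sets[cell]
        assert len(nbrs) == 6
        p = np.zeros(25)
        p[nbrs] = [100.0, 200.0, 300.0, 400.0, 500.0, 600.0]
        assert neighbour_average(p, lat, cell) == pytest.approx(350.0)

    def test_corner_uses_only_its_neighbours(self):
        lat = Lattice(10, 6)
        p = np.arange(60, dtype=float)
        expected = np.mean(p[brute_force_neighbours(10, 6, 0, 0)])
        assert neighbour_average(p, lat, 0) == pytest.approx(expected)


class TestLangevinNoise:
    def test_noise_off_gives_zero(self, rng):
        params = ModelParams(noise_on=False, rows=1, cols=1)
        em, ep = langevin_noise(10.0, 20.0, 5.0, 3.0, params, rng)
        assert em == 0.0 and ep == 0.0

    def test_zero_propensities_give_zero(self, rng):
        params = ModelParams(rows=1, cols=1)
        em, ep = langevin_noise(0.0, 0.0, 0.0, 0.0, params, rng)
        assert em == 0.0 and ep == 0.0

    def test_variance_matches_propensity_prediction(self, rng):
        # at the deterministic steady state production = degradation, so
        # var(eta_m) = 2 mu_m m* dt (and analogously for protein)
        params = ModelParams(rows=1, cols=1)
        m_star, p_star = deterministic_steady_state(params)
        n = 100_000
        em, ep = langevin_noise(
            np.full(n, m_star), np.full(n, p_star),
            np.full(n, params.mu_m * m_star),
            np.full(n, params.mu_p_effective * p_star), params, rng,
        )
        for eta, rate, level in ((em, params.mu_m, m_star),
                                 (ep, params.mu_p_effective, p_star)):
            expected = 2 * rate * level * params.dt
            se = expected * np.sqrt(2.0 / n)
            assert abs(np.var(eta) - expected) < 3 * se
            assert abs(np.mean(eta)) < 3 * np.sqrt(expected / n)

    def test_negative_propensity_rejected(self, rng):
        params = ModelParams(rows=1, cols=1)
        with pytest.raises(ValueError):
            langevin_noise(1.0, 1.0, -5.0, 0.0, params, rng)


class TestSteadyState:
    def test_repression_off_limit(self):
        p = ModelParams(alpha_m=1.0, alpha_p=1.0, mu_m=1.0, mu_p=1.0,
                        P0_auto=1e12, P0_LI=1e12, coupled=False,
                        rows=1, cols=1)
        m_star, p_star = deterministic_steady_state(p)
        assert m_star == pytest.approx(1.0, rel=1e-6)
        assert p_star == pytest.approx(1.0, rel=1e-6)

    def test_doubling_degradation_lowers_protein(self):
        base = ModelParams(rows=1, cols=1)
        _, p1 = deterministic_steady_state(base)
        _, p2 = deterministic_steady_state(base.with_multiplier(2.0))
        assert p2 < p1

    @pytest.mark.parametrize("coupled", [False, True])
    def test_plug_back_residual(self, coupled):
        params = ModelParams(alpha_m=750.0, alpha_p=12.0, mu_m=1.7,
                             mu_p=4.2, P0_auto=900.0, n_auto=3.0,
                             P0_LI=1200.0, n_LI=2.5, coupled=coupled)
        m_star, p_star = deterministic_steady_state(params)
        h = hill_auto(p_star, params.P0_auto, params.n_auto)
        if coupled:
            h *= hill_li(p_star, params.P0_LI, params.n_LI)
        res_m = params.alpha_m * h - params.mu_m * m_star
        res_p = params.alpha_p * m_star - params.mu_p_effective * p_star
        assert abs(res_m) < 1e-9 * max(params.alpha_m, 1.0)
        assert abs(res_p) < 1e-9 * max(params.alpha_p * m_star, 1.0)


STABLE = dict(alpha_m=100.0, alpha_p=5.0, mu_m=2.0, mu_p=2.0,
              P0_auto=500.0, n_auto=2.0, tau_auto=0.1, tau_LI=0.1,
              coupled=False, noise_on=False, rows=1, cols=1, t_end=30.0)


class TestSimulate:
    def test_stable_regime_converges_to_fixed_point(self):
        params = ModelParams(**STABLE)
        m_star, p_star = deterministic_steady_state(params)
        res = simulate(params)
        assert abs(res.m[0, -1] - m_star) / m_star < 1e-3
        assert abs(res.p[0, -1] - p_star) / p_star < 1e-3

    def test_strong_delayed_feedback_oscillates(self):
        # long delay relative to protein lifetime with steep repression:
        # sustained limit cycle whose period exceeds twice the delay
        params = ModelParams(alpha_m=500.0, alpha_p=10.0, mu_m=3.0,
                             mu_p=3.0, P0_auto=300.0, n_auto=6.0,
                             tau_auto=1.0, tau_LI=1.0, coupled=False,
                             noise_on=False, rows=1, cols=1, t_end=60.0)
        res = simulate(params)
        tail = res.p[0, res.p.shape[1] // 2:]
        t_tail = res.times[res.p.shape[1] // 2:]
        assert tail.std() / tail.mean() > 0.05, "no sustained oscillation"
        peaks = [
            t_tail[i] for i in range(1, tail.size - 1)
            if tail[i] > tail[i - 1] and tail[i] >= tail[i + 1]
        ]
        assert len(peaks) >= 3
        period = float(np.median(np.diff(peaks)))
        assert period > 2 * params.tau_auto

    def test_bitwise_determinism(self):
        params = ModelParams(rows=3, cols=3, t_end=5.0, seed=99)
        a, b = simulate(params), simulate(params)
        assert np.array_equal(a.m, b.m) and np.array_equal(a.p, b.p)
        assert a.seed == b.seed == 99

    def test_coupled_single_cell_reduces_to_model1(self):
        shared = dict(rows=1, cols=1, t_end=10.0, seed=3)
        a = simulate(ModelParams(coupled=True, **shared))
        b = simulate(ModelParams(coupled=False, **shared))
        assert np.array_equal(a.p, b.p)

    def test_states_never_negative(self):
        params = ModelParams(alpha_m=20.0, alpha_p=2.0, P0_auto=50.0,
                             P0_LI=50.0, rows=4, cols=4, t_end=20.0,
                             seed=17)
        res = simulate(params)
        assert res.m.min() >= 0 and res.p.min() >= 0

    def test_zero_noise_matches_fine_grid_reference(self):
        params = ModelParams(noise_on=False, rows=2, cols=2, t_end=20.0,
                             dt=0.01, tau_auto=0.3, tau_LI=0.3, seed=5)
        fine = ModelParams(noise_on=False, rows=2, cols=2, t_end=20.0,
                           dt=0.001, tau_auto=0.3, tau_LI=0.3, seed=5)
        h0 = (np.full(4, 50.0), np.full(4, 400.0))
        res_c = simulate(params, history=h0)
        res_f = simulate(fine, history=h0)
        rel = abs(res_c.p[:, -1] - res_f.p[:, -1]) / np.abs(res_f.p[:, -1])
        assert rel.max() < 1e-3

    def test_noise_variance_independent_of_dt(self):
        # chemical-Langevin consistency: the stationary variance of protein
        # in a stable noisy regime does not depend on the step size
        out = {}
        for dt in (1.0 / 60.0, 1.0 / 120.0):
            variances = []
            for seed in range(8):
                params = ModelParams(**{**STABLE, "noise_on": True,
                                        "t_end": 60.0, "dt": dt,
                                        "seed": seed})
                res = simulate(params)
                variances.append(res.p[0, res.p.shape[1] // 2:].var())
            out[dt] = np.mean(variances)
        ratio = out[1.0 / 60.0] / out[1.0 / 120.0]
        assert 0.7 < ratio < 1.4

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(dt=0.5, tau_auto=0.3)
        with pytest.raises(ValueError):
            ModelParams(t_end=-1.0)
        with pytest.raises(ValueError):
            simulate(ModelParams(rows=1, cols=1),
                     history=(np.array([-1.0]), np.array([1.0])))
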