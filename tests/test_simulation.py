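"""Lattice extrusion dynamics, contact reconstruction, and fit metrics.

The contact kernel is cross-checked against scipy's Dijkstra on the explicit
loop graph, and the stepping dynamics against closed-form trajectories and
conservation laws.
"""

import numpy as np
import pytest
from scipy.sparse import lil_matrix
from scipy.sparse.csgraph import dijkstra
from scipy import stats

from hicfountains import simulation as sim
from hicfountains.snipping import Pileup


def single_extruder_params(L=200, **kw):
    defaults = dict(
        L=L,
        platforms=(L // 2,),
        enrichment=1.0,
        p_load=0.0,
        p_unload=0.0,
        p_step=1.0,
        mechanism="barriers",  # platform-only loading; p_stall=0 -> no stalls
        p_stall=0.0,
    )
    defaults.update(kw)
    return sim.SimParams(**defaults)


class TestStep:
    def test_empty_stays_empty_without_loading(self):
        params = single_extruder_params()
        state = sim.ExtruderState(params.L)
        rng = np.random.default_rng(0)
        for _ in range(100):
            sim.step(state, params, rng)
        assert state.n == 0

    def test_deterministic_leg_separation(self):
        # single unobstructed extruder: span after k steps is 1 + 2k
        params = single_extruder_params()
        state = sim.ExtruderState(params.L)
        state.add(99, 100, "platform")
        rng = np.random.default_rng(1)
        for k in range(1, 31):
            sim.step(state, params, rng, check=True)
            assert state.right[0] - state.left[0] == 1 + 2 * k

    def test_converging_extruders_stall_and_never_cross(self):
        params = single_extruder_params(L=60)
        state = sim.ExtruderState(params.L)
        state.add(10, 11, "background")
        state.add(20, 21, "background")
        rng = np.random.default_rng(2)
        for _ in range(10_000):
            sim.step(state, params, rng, check=True)
            l0, r0 = state.left[0], state.right[0]
            l1, r1 = state.left[1], state.right[1]
            # leg ordering preserved: ends never interleave on the ring
            assert l0 < r0 and l1 < r1
            assert (r0 % 60) != (l1 % 60)

    def test_loading_respects_occupancy(self):
        params = single_extruder_params(p_load=1.0, enrichment=1.0)
        state = sim.ExtruderState(params.L)
        rng = np.random.default_rng(3)
        sim.step(state, params, rng, check=True)
        assert state.n == 1  # platform pair occupied after the first load


class TestRun:
    def test_uniform_loading_flat_occupancy(self):
        params = sim.SimParams(
            L=500, platforms=(250,), enrichment=1.0, seed=4,
            p_load=4e-4, p_unload=1 / 75,
        )
        _, occ = sim.run(params, burn_in=500, n_samples=2000, interval=25)
        # occupancy pooled into 25 Kb bins; blocked-leg dwell times make the
        # site-level profile slow to mix, but coarse bins must be uniform
        coarse = occ.reshape(20, -1).mean(axis=1)
        assert coarse.max() / coarse.min() < 1.5

    def test_platform_peak_centered(self):
        params = sim.SimParams(
            L=500, platforms=(250,), enrichment=1.0, seed=5, p_load=0.02,
            p_unload=1 / 40, mechanism="barriers", p_stall=0.0,
        )
        _, occ = sim.run(params, burn_in=500, n_samples=6000, interval=10)
        aligned = sim.align_occupancy(occ, params.platforms, halfwidth=200)
        sm = np.convolve(aligned, np.ones(21) / 21, mode="same")
        center = len(aligned) // 2
        assert abs(int(np.argmax(sm)) - center) <= 2

    def test_fwhm_shrinks_with_unloading_rate(self):
        fwhms = []
        for p_unload in (1 / 120, 1 / 60, 1 / 30):
            params = sim.SimParams(
                L=500, platforms=(250,), enrichment=1.0, seed=6, p_load=0.02,
                p_unload=p_unload, mechanism="barriers", p_stall=0.0,
            )
            _, occ = sim.run(params, burn_in=600, n_samples=5000, interval=10)
            aligned = sim.align_occupancy(occ, params.platforms, halfwidth=240)
            fwhms.append(sim.occupancy_fwhm(aligned, background_offsets=(180, 230)))
        assert fwhms[0] > fwhms[1] > fwhms[2]

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sim.run(single_extruder_params(), n_samples=0)
        with pytest.raises(ValueError):
            sim.run(single_extruder_params(), burn_in=-1)


class TestSteadyStats:
    def test_empty_states_zero(self):
        empty = (np.array([], dtype=int), np.array([], dtype=int), np.array([], dtype=bool))
        st = sim.steady_stats([empty] * 10, (0, 100), 500)
        assert st["all_per_region"] == 0.0

    def test_no_samples_errors(self):
        with pytest.raises(ValueError, match="empty"):
            sim.steady_stats([], (0, 100), 500)

    def test_birth_death_balance(self):
        params = sim.SimParams(seed=7)
        samples, _ = sim.run(params, burn_in=2000, n_samples=1500, interval=20)
        st = sim.steady_stats(samples, (50, 450), params.L)
        n_platform_pairs = 2 * len(params.platforms)
        rate = params.p_load * (
            params.L - n_platform_pairs + params.enrichment * n_platform_pairs
        )
        predicted = rate / params.p_unload / params.L
        assert st["density_per_kb"] == pytest.approx(predicted, rel=0.1)


def dijkstra_oracle(left, right, L):
    g = lil_matrix((L, L))
    for i in range(L):
        j = (i + 1) % L
        g[i, j] = 1.0
        g[j, i] = 1.0
    eps = 1e-9  # scipy treats 0 as "no edge"; use a negligible weight
    for l, r in zip(left, right):
        g[l % L, r % L] = eps
        g[r % L, l % L] = eps
    return dijkstra(g.tocsr(), directed=False)


class TestContactsFromLoops:
    def test_no_loops_closed_form(self):
        L = 30
        p = sim.contacts_from_loops(
            (np.array([], dtype=int), np.array([], dtype=int)), L
        )
        sep = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
        ring = np.minimum(sep, L - sep)
        np.testing.assert_allclose(p, (ring + 1.0) ** -1.5)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_dijkstra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(20, 51))
        k = int(rng.integers(1, 4))
        sites = rng.choice(L, size=2 * k, replace=False)
        left, right = sites[:k], sites[k:]
        p = sim.contacts_from_loops((left, right), L, exponent=-1.5, offset=1)
        d = dijkstra_oracle(left, right, L)
        d = np.round(d)  # strip the epsilon bridge weights
        np.testing.assert_allclose(p, (d + 1.0) ** -1.5, rtol=1e-9)

    def test_symmetry_and_bridge_enrichment(self):
        L = 40
        left, right = np.array([10]), np.array([30])
        p = sim.contacts_from_loops((left, right), L)
        np.testing.assert_allclose(p, p.T)
        p0 = sim.contacts_from_loops((np.array([], int), np.array([], int)), L)
        # contacts across the loop are enriched relative to the bare ring
        assert p[8, 32] > p0[8, 32]
        # d_eff(l - a, r + b) = a + b through the bridge
        assert p[8, 32] == pytest.approx((2 + 2 + 1.0) ** -1.5)

    def test_invalid_exponent(self):
        with pytest.raises(ValueError, match="exponent"):
            sim.contacts_from_loops(
                (np.array([], int), np.array([], int)), 10, exponent=0.5
            )


class TestSimulatedFountain:
    def test_pileup_shape_200kb_factor_10(self):
        params = single_extruder_params(L=400, p_load=2e-3, p_unload=1 / 60)
        samples, _ = sim.run(params, burn_in=300, n_samples=40, interval=10)
        pile = sim.simulated_average_fountain(samples, params)
        assert pile.values.shape == (20, 20)
        assert pile.resolution == 10_000

    def test_facilitated_beats_uniform_wedge_score(self):
        scores = {}
        for e in (1.0, 30.0):
            vals = []
            for seed in range(3):
                params = sim.SimParams(
                    L=400, platforms=(200,), enrichment=e, seed=seed,
                )
                samples, _ = sim.run(
                    params, burn_in=600, n_samples=700, interval=15,
                    collect_occupancy=False,
                )
                vals.append(sim.window_wedge_score(samples, params))
            scores[e] = np.mean(vals)
        assert scores[30.0] > scores[1.0] + 0.1


class TestFitMetrics:
    def _pileup(self, values):
        return Pileup(values=values, n_obs=np.ones_like(values))

    def test_identical(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(1, 2, (20, 20))
        m = sim.fit_metrics(self._pileup(v), self._pileup(v))
        assert m["protractor_mse"] == 0.0
        assert m["shape_spearman"] == pytest.approx(1.0)

    def test_constant_shift(self):
        rng = np.random.default_rng(9)
        v = rng.uniform(1, 2, (20, 20))
        m = sim.fit_metrics(self._pileup(v + 0.7), self._pileup(v))
        assert m["shape_spearman"] == pytest.approx(1.0)
        assert m["protractor_mse"] == pytest.approx(0.49, rel=1e-6)

    def test_permutation_null_spearman(self):
        rng = np.random.default_rng(10)
        v = rng.uniform(1, 2, (20, 20))
        rhos = []
        for _ in range(100):
            perm = v.copy().ravel()
            rng.shuffle(perm)
            m = sim.fit_metrics(self._pileup(perm.reshape(20, 20)), self._pileup(v))
            rhos.append(m["shape_spearman"])
        assert np.abs(rhos).max() < 0.2

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            sim.fit_metrics(
                self._pileup(np.ones((10, 10))), self._pileup(np.ones((20, 20)))
            )


class TestParameterSweep:
    def test_single_point_and_sorting(self):
        ref_params = sim.SimParams(L=400, platforms=(200,), enrichment=10.0, seed=11)
        samples, _ = sim.run(
            ref_params, burn_in=400, n_samples=150, interval=10,
            collect_occupancy=False,
        )
        ref = sim.simulated_average_fountain(samples, ref_params)
        grid = [
            sim.SimParams(L=400, platforms=(200,), enrichment=e, seed=12)
            for e in (1.0, 10.0)
        ]
        table = sim.parameter_sweep(grid, ref, burn_in=400, n_samples=150)
        assert len(table) == 2
        assert (table["protractor_mse"].diff().dropna() >= 0).all()
        with pytest.raises(ValueError, match="empty"):
            sim.parameter_sweep([], ref)
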