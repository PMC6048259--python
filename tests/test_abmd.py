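import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltabind import (
    BiasState,
    CollectiveVariable,
    binding_dg,
    binding_result,
    build_toy_dimer,
    delta_delta_g,
    deposit_bias,
    eval_cv,
    flood_1d,
    kd_ratio,
    pmf_from_bias,
    run_abmd,
    run_cmd,
    separation_cv,
    significance_ddg,
)
from deltabind.abmd import DegenerateGeometryError, _cv_gradient
from deltabind.constants import KB
from deltabind.dynamics import IntegratorConfig
from deltabind.gamd import FreeEnergyLandscape


def singleton_cv(kind, points):
    """CV over four single-bead groups placed at the given points."""
    coords = np.asarray(points, dtype=float)
    cv = CollectiveVariable(kind=kind, groups=([0], [1], [2], [3]))
    return cv, coords


class TestEvalCv:
    def test_distance_between_group_centres(self):
        cv, coords = singleton_cv(
            "distance", [[0, 0, 0], [1, 0, 0], [4, 0, 0], [5, 0, 0]]
        )
        assert eval_cv(coords, cv) == pytest.approx(4.0)

    def test_collinear_angle_is_180(self):
        cv, coords = singleton_cv(
            "angle", [[0, 0, 0], [1, 0, 0], [3, 0, 0], [3, 0, 0.0]]
        )
        coords[3] = [5, 0, 0]
        assert eval_cv(coords, cv) == pytest.approx(180.0)

    def test_planar_cis_torsion_is_zero(self):
        cv, coords = singleton_cv(
            "torsion", [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]]
        )
        assert eval_cv(coords, cv) == pytest.approx(0.0, abs=1e-10)

    def test_right_handed_quarter_turn_torsion(self):
        cv, coords = singleton_cv(
            "torsion", [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 0, 1]]
        )
        assert abs(eval_cv(coords, cv)) == pytest.approx(90.0)

    def test_degenerate_geometry_rejected(self):
        cv, coords = singleton_cv(
            "distance", [[0, 0, 0], [1, 0, 0], [0.5, 0, 0], [0.5, 0, 0]]
        )
        with pytest.raises(DegenerateGeometryError):
            eval_cv(coords, cv)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_distance_cv_matches_direct_formula_on_random_coords(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(0, 5, (8, 3))
        masses = rng.uniform(1, 20, 8)
        cv = CollectiveVariable(
            kind="distance", groups=([0, 1], [2], [3, 4], [5, 6, 7]), masses=masses
        )
        tu = np.array([0, 1, 2])
        wx = np.array([3, 4, 5, 6, 7])
        v = np.average(coords[tu], axis=0, weights=masses[tu])
        y = np.average(coords[wx], axis=0, weights=masses[wx])
        assert eval_cv(coords, cv) == pytest.approx(np.linalg.norm(v - y))

    def test_cv_gradient_matches_finite_difference(self, rng):
        coords = rng.normal(0, 3, (8, 3))
        masses = rng.uniform(1, 10, 8)
        for kind in ("distance", "angle", "torsion"):
            cv = CollectiveVariable(
                kind=kind, groups=([0, 1], [2, 3], [4, 5], [6, 7]), masses=masses
            )
            g = _cv_gradient(coords, cv)
            h = 1e-6
            for _ in range(6):
                i, d = rng.integers(8), rng.integers(3)
                cp, cm = coords.copy(), coords.copy()
                cp[i, d] += h
                cm[i, d] -= h
                num = (eval_cv(cp, cv) - eval_cv(cm, cv)) / (2 * h)
                assert g[i, d] == pytest.approx(num, rel=1e-3, abs=1e-7)


class TestDepositBias:
    def grid_state(self, **kw):
        return BiasState(edges=(np.linspace(0.0, 10.0, 51),), tau=2.0, **kw)

    def test_single_deposit_peaks_at_the_deposit_point(self):
        state = self.grid_state()
        deposit_bias(state, [5.0], dt=2.0)
        nodes = state.edges[0]
        assert nodes[np.argmax(state.bias)] == pytest.approx(5.0)
        amp = KB * state.temperature * (2.0 * 1e-3) / state.tau
        assert state.bias.max() == pytest.approx(amp)
        # compact support: kernel dies beyond its half-width
        hw = state.kernel_halfwidth_cells * (nodes[1] - nodes[0])
        assert np.all(state.bias[np.abs(nodes - 5.0) >= hw] == 0.0)

    def test_two_deposits_double_the_bump(self):
        a, b = self.grid_state(), self.grid_state()
        deposit_bias(a, [5.0], dt=2.0)
        deposit_bias(b, [5.0], dt=2.0)
        deposit_bias(b, [5.0], dt=2.0)
        np.testing.assert_allclose(b.bias, 2 * a.bias, rtol=1e-12)

    def test_out_of_grid_deposits_follow_the_boundary_rule(self):
        rej = self.grid_state()
        deposit_bias(rej, [11.0], dt=2.0)
        assert rej.n_deposits == 0 and np.all(rej.bias == 0.0)
        clip = self.grid_state(boundary="clip")
        deposit_bias(clip, [11.0], dt=2.0)
        assert clip.n_deposits == 1
        assert np.argmax(clip.bias) == len(clip.edges[0]) - 1

    def test_flat_potential_floods_flat(self):
        """On a flat landscape the converged bias is flat (flat-histogram)."""

        class Flat:
            def energy(self, x):
                return np.zeros_like(np.asarray(x, dtype=float))

            def force(self, x):
                return np.zeros_like(np.asarray(x, dtype=float))

        state = flood_1d(
            Flat(), np.linspace(-2, 2, 41), n_steps=200_000, tau=2.0, seed=2
        )
        interior = slice(4, -4)  # kernel tails make the very edges lag
        bias = np.mean(state.snapshots[-len(state.snapshots) // 2 :], axis=0)
        b = bias[interior]
        assert (b.max() - b.min()) / b.mean() < 0.10


class TestRunAbmd:
    def test_zero_deposition_reduces_to_cmd(self, wt_system):
        config = IntegratorConfig(n_steps=200, save_stride=20, seed=3)
        state, traj = run_abmd(
            wt_system,
            separation_cv(wt_system),
            config,
            np.linspace(3.0, 18.0, 31),
            tau=np.inf,
        )
        assert np.all(state.bias == 0.0)
        ref = run_cmd(wt_system, config)
        np.testing.assert_allclose(traj.coords, ref.coords, atol=1e-12)

    def test_deterministic_under_fixed_seed(self, wt_system):
        config = IntegratorConfig(n_steps=300, save_stride=30, seed=5)
        grid = np.linspace(3.0, 18.0, 31)
        s1, t1 = run_abmd(wt_system, separation_cv(wt_system), config, grid, tau=1.0)
        s2, t2 = run_abmd(wt_system, separation_cv(wt_system), config, grid, tau=1.0)
        np.testing.assert_array_equal(t1.coords, t2.coords)
        np.testing.assert_array_equal(s1.bias, s2.bias)


class TestPmfFromBias:
    def test_flat_bias_gives_flat_pmf(self):
        state = BiasState(edges=(np.linspace(0, 1, 11),))
        state.bias[:] = 4.2
        pmf = pmf_from_bias(state)
        np.testing.assert_allclose(pmf.F, 0.0, atol=1e-12)

    def test_single_well_deposit_history_gives_single_basin(self):
        state = BiasState(edges=(np.linspace(0, 10, 51),), tau=1.0)
        for _ in range(50):
            deposit_bias(state, [5.0], dt=2.0)
        pmf = pmf_from_bias(state)
        assert pmf.F[np.argmin(np.abs(state.edges[0] - 5.0))] == 0.0
        assert np.all(np.diff(pmf.F[: 25]) <= 1e-12)  # monotone into the basin


def _pmf_from_profile(centers, F, T=310.0):
    cell = centers[1] - centers[0]
    edges = np.concatenate([[centers[0] - cell / 2], centers + cell / 2])
    p = np.exp(-F / (KB * T))
    p = p / p.sum()
    return FreeEnergyLandscape(
        edges=(edges,), p_prime=p, p=p, F=np.asarray(F, dtype=float),
        counts=np.full(len(F), np.nan), temperature=T,
    )


class TestBindingDg:
    def test_flat_profile_with_equal_windows_gives_zero(self):
        centers = np.linspace(0.5, 19.5, 20)
        pmf = _pmf_from_profile(centers, np.zeros(20))
        assert binding_dg(pmf, (0, 5), (15, 20)) == pytest.approx(0.0, abs=1e-12)

    def test_square_well_closed_form(self):
        centers = np.linspace(0.5, 19.5, 20)
        F = np.zeros(20)
        F[centers <= 5.0] = -5.0
        pmf = _pmf_from_profile(centers, F)
        assert binding_dg(pmf, (0, 5), (15, 20)) == pytest.approx(-5.0)

    def test_overlapping_or_empty_windows_rejected(self):
        centers = np.linspace(0.5, 19.5, 20)
        pmf = _pmf_from_profile(centers, np.zeros(20))
        with pytest.raises(ValueError):
            binding_dg(pmf, (0, 10), (5, 20))
        with pytest.raises(ValueError):
            binding_dg(pmf, (0, 5), (25, 30))


class TestDdgAndKdRatio:
    @pytest.mark.parametrize(
        "dg_mut, dg_wt, expected",
        [(-9.45, -14.12, 4.67), (-30.87, -36.10, 5.23), (-7.0, -7.0, 0.0)],
    )
    def test_ddg_difference(self, dg_mut, dg_wt, expected):
        ddg, unc = delta_delta_g(dg_mut, dg_wt)
        assert ddg == pytest.approx(expected, abs=1e-12)
        assert unc == 0.0

    def test_uncertainty_propagates_in_quadrature(self):
        _, unc = delta_delta_g(-9.45, -14.12, 0.57, 1.82)
        assert unc == pytest.approx(np.hypot(0.57, 1.82))

    @pytest.mark.parametrize(
        "ddg, expected", [(4.67, 1961.64), (5.23, 4869.14)]
    )
    def test_kd_ratio_reproduces_reference_values(self, ddg, expected):
        assert kd_ratio(ddg, 310.0) == pytest.approx(expected, rel=0.005)

    def test_kd_ratio_of_zero_ddg_is_one(self):
        assert kd_ratio(0.0, 200.0) == 1.0

    @given(
        st.floats(-20, 20), st.floats(-20, 20), st.floats(-30, 30)
    )
    @settings(max_examples=50, deadline=None)
    def test_kd_ratio_invariant_to_common_offsets(self, a, b, c):
        d1, _ = delta_delta_g(a, b)
        d2, _ = delta_delta_g(a + c, b + c)
        assert kd_ratio(d1, 310.0) == pytest.approx(kd_ratio(d2, 310.0), rel=1e-9)

    def test_binding_result_consistency_enforced(self):
        res = binding_result([-14.0, -14.4], [-9.2, -9.8], T=310.0)
        assert res.ddg == pytest.approx(4.7)
        assert res.kd_ratio == pytest.approx(kd_ratio(res.ddg, 310.0))


class TestSignificance:
    def test_all_zero_replicates_not_significant(self):
        assert significance_ddg([0.0, 0.0, 0.0]) == 1.0

    def test_clear_positive_shift_detected(self):
        # one-sample t on {4,5,6} vs 0: t = 5 / (1/sqrt(3)), df = 2
        p = significance_ddg([4.0, 5.0, 6.0])
        from scipy import stats

        t = 5.0 / (1.0 / np.sqrt(3.0))
        assert p == pytest.approx(stats.t.sf(t, df=2), rel=1e-9)
        assert p < 0.05

    def test_permutation_agrees_with_t_in_direction(self):
        p = significance_ddg([4.0, 5.0, 6.0, 5.5], method="permutation", seed=1)
        assert p < 0.2

    def test_null_calibration_of_the_t_route(self):
        rng = np.random.default_rng(0)
        ps = [
            significance_ddg(rng.normal(0, 1, 6)) for _ in range(400)
        ]
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.01 < frac < 0.12


class TestToyFreeEnergyRecovery:
    def test_harmonic_cv_pmf_recovered_by_flooding(self):
        """Negated converged bias reproduces the analytic PMF of a harmonic CV."""
        from deltabind import Harmonic1D

        h = Harmonic1D(k=2.0)
        state = flood_1d(
            h, np.linspace(-3.0, 3.0, 61), n_steps=250_000, tau=3.0, seed=5
        )
        pmf = pmf_from_bias(state)
        nodes = state.edges[0]
        Fa = h.energy(nodes)
        region = Fa <= 3.0
        Fc = pmf.F[region] - pmf.F[region].min()
        Fr = Fa[region] - Fa[region].min()
        assert np.abs(Fc - Fr).max() < 0.45
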