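"""Deviation vectors, line-search step sizes, the stopping statistic, and
the full iterative reconstruction against direct least-squares references."""

import numpy as np
import pytest

import pct
from pct.solver import (
    StoppingConfig, compute_dp, compute_dv, compute_r, estimate_sigma_p,
    estimate_sigma_v, optimal_lambda, reconstruct, solve_direct,
)


class TestDeviationVectors:
    def test_micro_dp(self, micro):
        _, protons, system = micro
        dp = compute_dp(system, np.array([1.0, 1.0]), protons.wepl)
        np.testing.assert_allclose(dp, [0.0, -0.2, 0.0], atol=1e-14)

    def test_dp_trivial_cases(self, micro):
        _, protons, system = micro
        b = protons.wepl
        x_exact = np.array([16 / 15, 16 / 15])
        assert np.allclose(compute_dp(system, np.zeros(2), b), -b)
        dv_at_solution = compute_dv(system, compute_dp(system, x_exact, b))
        np.testing.assert_allclose(dv_at_solution, 0.0, atol=1e-12)

    def test_dp_dimension_mismatch(self, micro):
        _, protons, system = micro
        with pytest.raises(ValueError, match="mismatch"):
            compute_dp(system, np.zeros(5), protons.wepl)

    def test_micro_dv_weighted_average(self, micro):
        _, _, system = micro
        dv = compute_dv(system, np.array([0.0, -0.2, 0.0]))
        np.testing.assert_allclose(dv, [-0.1, -0.1], atol=1e-14)

    def test_dv_zero_for_zero_dp(self, micro):
        _, _, system = micro
        assert np.all(compute_dv(system, np.zeros(3)) == 0.0)

    def test_single_proton_single_voxel_average_is_identity(self):
        """A weighted average over one proton returns that proton's dp."""
        grid = pct.VoxelGrid((1, 1, 1), 2.0)
        p_in = np.array([[1.0, 1.0, -5.0]])
        d = np.array([[0.0, 0.0, 1.0]])
        protons = pct.ProtonList(p_in=p_in, d_in=d, p_out=p_in + 10 * d, d_out=d,
                                 wepl=np.array([4.0]), angle_deg=np.zeros(1))
        system = pct.build_system_matrix(protons, grid)
        np.testing.assert_allclose(compute_dv(system, np.array([4.0])), [4.0])


class TestOptimalLambda:
    def test_micro_dp_objective(self, micro):
        _, protons, system = micro
        dp = compute_dp(system, np.array([1.0, 1.0]), protons.wepl)
        dv = compute_dv(system, dp)
        assert optimal_lambda(system, dp, dv, "dp") == pytest.approx(2 / 3)

    def test_orthogonal_gives_zero(self, micro):
        _, _, system = micro
        dv = np.array([1.0, -1.0])
        Adv = system.A @ dv             # [1, 0, -1]
        dp = np.array([0.0, 5.0, 0.0])  # orthogonal to A dv
        assert optimal_lambda(system, dp, dv, "dp") == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("objective", ["dp", "dv"])
    def test_matches_grid_search_on_random_systems(self, objective):
        """The closed form agrees with a fine 1-D search of the objective."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            n_p, n_v = 12, 5
            A = np.abs(rng.normal(size=(n_p, n_v)))
            import scipy.sparse as sp
            from pct.geometry import SystemMatrix
            grid = pct.VoxelGrid((n_v, 1, 1), 1.0)
            s = A.sum(axis=0)
            system = SystemMatrix(A=sp.csr_matrix(A), grid=grid, chord_sums=s,
                                  proton_counts=(A > 0).sum(axis=0),
                                  mask=np.ones(n_v, bool),
                                  empty_rows=np.zeros(n_p, bool),
                                  npv_mean=float((A > 0).sum(axis=0).mean()))
            b = rng.normal(size=n_p)
            x = rng.normal(size=n_v)
            dp = compute_dp(system, x, b)
            dv = compute_dv(system, dp)
            lam = optimal_lambda(system, dp, dv, objective)
            grid_lams = np.linspace(lam - 2.0, lam + 2.0, 4001)

            def objective_value(l):
                dp_new = compute_dp(system, x - l * dv, b)
                if objective == "dp":
                    return dp_new @ dp_new
                dv_new = compute_dv(system, dp_new)
                return dv_new @ dv_new

            values = [objective_value(l) for l in grid_lams]
            best = grid_lams[int(np.argmin(values))]
            assert lam == pytest.approx(best, abs=2 * (grid_lams[1] - grid_lams[0]))

    def test_stagnation_signalled(self, micro):
        _, _, system = micro
        with pytest.raises(ArithmeticError, match="stagnation"):
            optimal_lambda(system, np.zeros(3), np.zeros(2), "dp")


class TestNoiseEstimates:
    def test_sigma_p_constant_vector_is_zero(self):
        assert estimate_sigma_p(np.full(10, 3.3)) == pytest.approx(0.0)

    def test_sigma_p_micro_value(self):
        assert estimate_sigma_p(np.array([0.0, -0.2, 0.0])) == pytest.approx(0.11547, abs=1e-5)

    def test_sigma_p_recovers_population_sigma(self):
        rng = np.random.default_rng(2)
        dp = rng.normal(0.0, 2.5, 100_000)
        assert estimate_sigma_p(dp) == pytest.approx(2.5, rel=0.01)

    def test_sigma_v_substitution_and_sqrt_law(self):
        grid = pct.VoxelGrid((4, 4, 4), 1.0)
        assert estimate_sigma_v(2.0, 400.0, grid) == pytest.approx(0.1)
        assert estimate_sigma_v(2.0, 1600.0, grid) == pytest.approx(0.05)
        assert estimate_sigma_v(0.0, 400.0, grid) == 0.0
        with pytest.raises(ValueError):
            estimate_sigma_v(2.0, 0.0, grid)

    def test_r_values(self):
        assert compute_r(np.zeros(5), 0.2) == 0.0
        dv = np.array([0.1, -0.1, 0.1, -0.1])
        assert compute_r(dv, 0.1) == pytest.approx(1.0)
        # micro-case at x=[1,1]: rms dv = 0.1, sigma_v set to 0.2
        assert compute_r(np.array([-0.1, -0.1]), 0.2) == pytest.approx(0.5)
        with pytest.raises(ZeroDivisionError):
            compute_r(dv, 0.0)


class TestReconstruct:
    def test_micro_one_dp_step_reaches_least_squares(self, micro):
        grid, protons, system = micro
        stop = StoppingConfig(r_stop=1e-6, max_iterations=5, x0_mode="volume",
                              x0_volume=pct.RSPVolume(grid, np.ones((2, 1, 1))))
        with pytest.warns(UserWarning):  # 3 protons < 10x voxels
            result = reconstruct(protons, grid, stop, system=system)
        x = result.volume.data.ravel()
        np.testing.assert_allclose(x, [16 / 15, 16 / 15], atol=1e-12)
        dv = compute_dv(system, compute_dp(system, x, protons.wepl))
        assert np.sqrt(np.mean(dv**2)) <= 1e-12

    def test_noiseless_data_converges_to_truth(self):
        """A consistent system (no noise, exact trajectories) reaches the
        true RSP map as the stopping threshold goes to zero."""
        grid = pct.VoxelGrid.centered((12, 2, 12), 2.0)
        truth = pct.make_phantom(pct.water_cylinder(20.0, 4.0, 1.0), grid)
        cfg = pct.SimulationConfig(protons_per_angle=400, n_angles=24,
                                   angle_spacing_deg=15.0, wepl_noise_sigma=0.0,
                                   tracker_pitch=0.0, divergence_mrad=0.0,
                                   beam_extent=(26.0, 3.5), seed=3)
        protons = pct.simulate_protons(truth, cfg)
        result = reconstruct(protons, grid, StoppingConfig(r_stop=1e-9, max_iterations=3000))
        assert result.converged
        inside = truth.data > 0
        assert np.max(np.abs(result.volume.data[inside] - 1.0)) < 1e-5

    def test_deeper_stopping_needs_more_iterations(self, small_sim):
        """Iterations to reach r grow monotonically as r decreases."""
        result = reconstruct(small_sim["protons"], small_sim["grid"],
                             StoppingConfig(r_stop=0.2, max_iterations=3000),
                             system=small_sim["system"],
                             snapshot_r=(2.0, 1.0, 0.75, 0.5))
        history = result.history

        def iterations_to(r_value):
            return next(rec["iteration"] for rec in history if rec["r"] <= r_value)

        counts = [iterations_to(r) for r in (2.0, 1.0, 0.75, 0.5, 0.2)]
        assert counts == sorted(counts)
        assert counts[-1] > counts[0]

    def test_each_step_does_not_increase_its_objective(self, small_sim):
        system = small_sim["system"]
        b = small_sim["protons"].wepl
        x = pct.initial_guess(system, b, StoppingConfig())
        for it in range(12):
            dp = compute_dp(system, x, b)
            dv = compute_dv(system, dp)
            objective = "dp" if it % 2 == 0 else "dv"
            lam = optimal_lambda(system, dp, dv, objective)
            x_new = x - lam * dv
            dp_new = compute_dp(system, x_new, b)
            if objective == "dp":
                assert dp_new @ dp_new <= dp @ dp + 1e-9
            else:
                dv_new = compute_dv(system, dp_new)
                assert dv_new @ dv_new <= dv @ dv + 1e-9
            x = x_new

    def test_iterative_matches_direct_least_squares(self, small_sim):
        """Iterating deep below the stopping band lands on the
        normal-equations solution (max-norm within 1e-2 sigma_v)."""
        system = small_sim["system"]
        protons = small_sim["protons"]
        result = reconstruct(protons, small_sim["grid"],
                             StoppingConfig(r_stop=1e-4, max_iterations=20000),
                             system=system)
        assert result.converged
        x_direct = solve_direct(system, protons.wepl)
        dv_direct = compute_dv(system, compute_dp(system, x_direct, protons.wepl))
        assert np.sqrt(np.mean(dv_direct[system.mask] ** 2)) <= 1e-10
        sigma_v = result.state.sigma_v
        max_dev = np.max(np.abs(result.volume.data.ravel() - x_direct))
        assert max_dev <= 1e-2 * sigma_v

    def test_mean_wepl_property_at_solution(self, small_sim):
        """At the least-squares solution, the chord-weighted mean calculated
        WEPL of the protons touching each voxel equals the mean measured
        WEPL (equivalently dv = 0)."""
        system = small_sim["system"]
        b = small_sim["protons"].wepl
        x = solve_direct(system, b)
        calc = system.A @ x
        mean_calc = compute_dv(system, calc)
        mean_meas = compute_dv(system, b)
        np.testing.assert_allclose(mean_calc[system.mask], mean_meas[system.mask],
                                   atol=1e-8)


class TestStoppingConfig:
    @pytest.mark.parametrize("kwargs", [
        {"r_stop": 0.0}, {"max_iterations": 0}, {"x0_mode": "bogus"},
        {"x0_mode": "volume"},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StoppingConfig(**kwargs)
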