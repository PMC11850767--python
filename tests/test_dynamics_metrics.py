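"""PCA change of basis, flow fields, velocities, rotation geometry,
transition statistics, attractor scores and sequentiality."""

import numpy as np
import pytest

from compete_dynamics import dynamics_metrics as dm
from compete_dynamics import rslds, synthetic_data
from compete_dynamics.synthetic_data import SimConfig


class TestPcaTransform:
    def test_whitened_covariance_identity(self, fitted_session):
        pca = dm.pca_transform(fitted_session)
        xw = (pca.W_white @ fitted_session.x.T).T
        cov = np.cov(xw.T)
        np.testing.assert_allclose(cov, np.eye(2), atol=1e-6)

    def test_variance_fractions_descending(self, fitted_session):
        pca = dm.pca_transform(fitted_session)
        assert np.all(np.diff(pca.var_frac) <= 1e-12)

    def test_transform_preserves_dynamics(self):
        """Simulate-then-transform equals transform-then-simulate in the
        noise-free model."""
        cfg = SimConfig(n_latent=2, n_units=12, n_timesteps=150, seed=6,
                        process_noise_sd=0.0, emission_noise_sd=0.0)
        p = synthetic_data.make_rotational_params(cfg)
        lat, rates, _ = synthetic_data.simulate_session(p, cfg, noise_free=True)
        fr = rslds.FitResult(params=p, z=lat.z, x=lat.x,
                             elbo_trace=np.array([0.0]),
                             variance_explained=1.0, converged=True)
        pca = dm.pca_transform(fr)
        x2 = pca.x2
        for k in range(3):
            A2, b2 = pca.transform_dynamics(p.A[k], p.b[k])
            steps = np.where(lat.z[1:] == k)[0]
            np.testing.assert_allclose(
                x2[steps + 1], x2[steps] @ A2.T + b2, atol=1e-8)

    def test_isotropic_orthonormal_case(self):
        """With identity emission and white latents the transformed latents
        keep their variance ordering trivially equal."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal((500, 2))
        p_toy = synthetic_data.make_rotational_params(
            SimConfig(n_latent=2, n_units=2, seed=0))
        p_toy.C = [np.eye(2)] * 3
        fr = rslds.FitResult(params=p_toy, z=np.zeros(500, dtype=int), x=x,
                             elbo_trace=np.array([0.0]),
                             variance_explained=1.0, converged=True)
        pca = dm.pca_transform(fr)
        assert np.all(pca.var_frac > 0.3)


class TestFlowField:
    def _fit_result(self, A, b):
        p = synthetic_data.make_rotational_params(
            SimConfig(n_latent=2, n_units=5, seed=0))
        p.A[0], p.b[0] = A, b
        x = np.random.default_rng(0).standard_normal((100, 2))
        return rslds.FitResult(params=p, z=np.zeros(100, dtype=int), x=x,
                               elbo_trace=np.array([0.0]),
                               variance_explained=1.0, converged=True), p

    def test_identity_dynamics_zero_field(self):
        fr, p = self._fit_result(np.eye(2), np.zeros(2))
        pca = dm.pca_transform(fr)
        grid = np.array([[0.0, 0.0], [1.0, 2.0], [-3.0, 1.0]])
        field = dm.flow_field(p, pca, grid, state=0)
        np.testing.assert_allclose(field, 0.0, atol=1e-9)

    def test_rotation_field_circulates(self):
        om = np.radians(15.0)
        A = np.array([[np.cos(om), -np.sin(om)], [np.sin(om), np.cos(om)]])
        fr, p = self._fit_result(A, np.zeros(2))
        pca = dm.pca_transform(fr)
        gg = np.linspace(-2, 2, 5)
        grid = np.array([[a, c] for a in gg for c in gg if (a, c) != (0, 0)])
        field = dm.flow_field(p, pca, grid, state=0)
        pts = np.zeros((len(grid), 2))
        pts[:, :2] = grid
        # curl sign: cross(position, displacement) has constant sign
        cross = grid[:, 0] * field[:, 1] - grid[:, 1] * field[:, 0]
        assert np.all(cross > 0) or np.all(cross < 0)

    def test_contraction_points_to_fixed_point(self):
        fr, p = self._fit_result(0.5 * np.eye(2), np.zeros(2))
        pca = dm.pca_transform(fr)
        grid = np.array([[2.0, 0.0], [0.0, 3.0], [-1.0, -1.0]])
        field = dm.flow_field(p, pca, grid, state=0)
        # every displacement reduces the distance to the (transformed) origin
        before = np.linalg.norm(grid, axis=1)
        after = np.linalg.norm(grid + field, axis=1)
        assert np.all(after < before)


class TestDynamicVelocity:
    def test_scalar_worked_example(self):
        p = synthetic_data.make_rotational_params(
            SimConfig(n_latent=2, n_units=5, seed=0))
        p.A = [0.9 * np.eye(2), 0.9 * np.eye(2), np.zeros((2, 2))]
        x = np.tile([2.0, 0.0], (9, 1))
        z = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        raw = dm.dynamic_velocity_raw(p, x, z)
        np.testing.assert_allclose(raw, [1.8, 1.8, 0.0], atol=1e-12)
        norm = dm.dynamic_velocity(p, x, z)
        np.testing.assert_allclose(norm, [1.0, 1.0, 0.0], atol=1e-12)

    def test_matches_bruteforce(self, rotational_session):
        p = rotational_session["params"]
        lat = rotational_session["latents"]
        v = dm.dynamic_velocity_raw(p, lat.x, lat.z)
        for k in range(3):
            expect = np.mean([np.linalg.norm(p.A[k] @ xi)
                              for xi, zi in zip(lat.x, lat.z) if zi == k])
            assert abs(v[k] - expect) < 1e-10

    def test_state1_normalization(self, rotational_session):
        p = rotational_session["params"]
        lat = rotational_session["latents"]
        assert dm.dynamic_velocity(p, lat.x, lat.z)[0] == 1.0

    def test_unvisited_state_flagged_nan(self):
        p = synthetic_data.make_rotational_params(
            SimConfig(n_latent=2, n_units=5, seed=0))
        v = dm.dynamic_velocity(p, np.ones((4, 2)), np.zeros(4, dtype=int))
        assert np.isnan(v[1]) and np.isnan(v[2])


class TestPointAttractor:
    def test_direct_comparison(self):
        x = np.array([[1.0, 0.0], [0.1, 0.0]])
        z = np.zeros(2, dtype=int)
        out = dm.point_attractor(x, z, np.eye(2))
        np.testing.assert_allclose(out, [0.1, 0.0])

    def test_zero_matrix_tie_breaks_earliest(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0]])
        out = dm.point_attractor(x, np.zeros(2, dtype=int), np.zeros((2, 2)))
        np.testing.assert_allclose(out, [1.0, 1.0])

    def test_matches_exhaustive_scan(self, rng):
        x = rng.standard_normal((50, 2))
        z = np.zeros(50, dtype=int)
        A = rng.standard_normal((2, 2))
        out = dm.point_attractor(x, z, A)
        norms = np.linalg.norm(x @ A.T, axis=1)
        np.testing.assert_allclose(out, x[np.argmin(norms)])

    def test_empty_state_rejected(self):
        with pytest.raises(ValueError):
            dm.point_attractor(np.ones((3, 2)), np.ones(3, dtype=int), np.eye(2))


class TestGeometricMedian:
    def test_symmetric_cross(self):
        pts = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)
        np.testing.assert_allclose(dm.geometric_median(pts), [0, 0], atol=1e-7)

    def test_single_point(self):
        np.testing.assert_allclose(dm.geometric_median(np.array([[2.0, 3.0]])),
                                   [2.0, 3.0])

    def test_matches_grid_search(self, rng):
        pts = rng.standard_normal((20, 2))
        m = dm.geometric_median(pts)
        obj = np.sum(np.linalg.norm(pts - m, axis=1))
        gx = np.linspace(pts[:, 0].min(), pts[:, 0].max(), 400)
        gy = np.linspace(pts[:, 1].min(), pts[:, 1].max(), 400)
        GX, GY = np.meshgrid(gx, gy)
        grid_pts = np.column_stack([GX.ravel(), GY.ravel()])
        d = np.zeros(len(grid_pts))
        for p in pts:
            d += np.linalg.norm(grid_pts - p, axis=1)
        assert obj <= d.min() + 1e-4

    def test_coincident_iterate_guard(self):
        # the mean of these points IS a data point and the true minimizer
        pts = np.array([[0, 0], [1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)
        np.testing.assert_allclose(dm.geometric_median(pts), [0, 0], atol=1e-7)


class TestRotationAngle:
    def test_worked_90_degrees(self):
        theta = dm.rotation_angle(np.array([[0.0, 1.0]]), attractor=[1.0, 0.0],
                                  median=[0.0, 0.0], rotation_direction=+1.0)
        np.testing.assert_allclose(theta, [90.0])

    def test_worked_270_degrees(self):
        theta = dm.rotation_angle(np.array([[0.0, -1.0]]), attractor=[1.0, 0.0],
                                  median=[0.0, 0.0], rotation_direction=+1.0)
        np.testing.assert_allclose(theta, [270.0])

    def test_collinear_zero(self):
        theta = dm.rotation_angle(np.array([[2.0, 0.0]]), attractor=[1.0, 0.0],
                                  median=[0.0, 0.0], rotation_direction=+1.0)
        np.testing.assert_allclose(theta, [0.0], atol=1e-9)

    def test_clockwise_direction_flips(self):
        theta = dm.rotation_angle(np.array([[0.0, 1.0]]), attractor=[1.0, 0.0],
                                  median=[0.0, 0.0], rotation_direction=-1.0)
        np.testing.assert_allclose(theta, [270.0])

    def test_point_at_median_masked(self):
        theta = dm.rotation_angle(np.array([[0.0, 0.0], [1.0, 0.0]]),
                                  attractor=[1.0, 0.0], median=[0.0, 0.0],
                                  rotation_direction=+1.0)
        assert np.isnan(theta[0]) and np.isfinite(theta[1])

    def test_coincident_attractor_median_rejected(self):
        with pytest.raises(ValueError):
            dm.rotation_angle(np.ones((3, 2)), [1.0, 1.0], [1.0, 1.0])

    def test_pure_rotation_advances_by_step(self):
        """On a noise-free circular trajectory the angle advances by exactly
        the generating step each bin (mod 360)."""
        step_deg = 10.0
        t = np.arange(200)
        traj = np.column_stack([np.cos(np.radians(step_deg * t)),
                                np.sin(np.radians(step_deg * t))]) * 3.0
        theta = dm.rotation_angle(traj, attractor=[3.0, 0.0], median=[0.0, 0.0])
        inc = np.diff(theta) % 360.0
        np.testing.assert_allclose(inc, step_deg, atol=1e-6)


class TestAngleEcdf:
    def test_degenerate_class(self):
        out = dm.angle_behavior_ecdf(np.full(10, 120.0),
                                     np.array(["snatch"] * 10))
        assert out["snatch"]["p50"] == 120.0

    def test_uniform_angles_median_near_180(self, rng):
        theta = rng.uniform(0, 360, 20000)
        out = dm.angle_behavior_ecdf(theta, np.array(["other"] * 20000))
        assert abs(out["other"]["p50"] - 180.0) < 10.0

    def test_phase_coupled_ordering(self):
        cfg = SimConfig(n_latent=2, n_units=8, n_timesteps=1500, seed=21,
                        behavior_rule={(0.0, 180.0): "snatch",
                                       (180.0, 360.0): "retreat"})
        p = synthetic_data.make_rotational_params(cfg)
        lat, _, gt = synthetic_data.simulate_session(p, cfg)
        theta = synthetic_data.rotation_phase(lat)
        out = dm.angle_behavior_ecdf(theta, gt.behavior_labels)
        assert out["snatch"]["p50"] < out["retreat"]["p50"]


class TestTransitionStats:
    def test_counting_oracle(self):
        z = np.array([0, 0, 1, 1, 1, 2])
        trans, self_p, dwell = dm.transition_stats(z)
        np.testing.assert_allclose(trans[0], [0.5, 0.5, 0.0])
        np.testing.assert_allclose(trans[1], [0.0, 2 / 3, 1 / 3])
        assert np.all(np.isnan(trans[2]))  # state 2 has no outgoing bins
        np.testing.assert_array_equal(dwell[0], [2])
        np.testing.assert_array_equal(dwell[1], [3])
        np.testing.assert_array_equal(dwell[2], [1])

    def test_constant_series(self):
        trans, self_p, dwell = dm.transition_stats(np.zeros(10, dtype=int))
        assert trans[0, 0] == 1.0
        np.testing.assert_array_equal(dwell[0], [10])

    def test_rows_sum_to_one(self, rotational_session):
        trans, _, _ = dm.transition_stats(rotational_session["latents"].z)
        np.testing.assert_allclose(np.nansum(trans, axis=1), 1.0)

    def test_trial_edges_excluded(self):
        z = np.array([0, 0, 1, 1])
        trans_all, _, _ = dm.transition_stats(z)
        trans_cut, _, _ = dm.transition_stats(z, trial_edges=[2])
        assert trans_all[0, 1] > 0
        assert trans_cut[0, 1] == 0.0

    def test_markov_chain_recovery(self):
        """Empirical matrix converges to the generating chain within
        sampling error."""
        rng = np.random.default_rng(0)
        P = np.array([[0.9, 0.08, 0.02], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
        T = 50000
        z = np.zeros(T, dtype=int)
        for t in range(1, T):
            z[t] = rng.choice(3, p=P[z[t - 1]])
        trans, _, _ = dm.transition_stats(z)
        counts = np.bincount(z[:-1], minlength=3)
        for i in range(3):
            se = np.sqrt(P[i] * (1 - P[i]) / counts[i])
            assert np.all(np.abs(trans[i] - P[i]) < 3.5 * se + 1e-12)


class TestQuartiles:
    def test_ladder(self):
        labels = dm.quartile_levels(np.arange(1.0, 9.0))
        np.testing.assert_array_equal(labels, [1, 1, 2, 2, 3, 3, 4, 4])

    def test_all_equal_ties_low(self):
        np.testing.assert_array_equal(dm.quartile_levels(np.ones(8)),
                                      np.ones(8, dtype=int))

    def test_descending_reverses(self, rng):
        v = rng.standard_normal(40)
        asc = dm.quartile_levels(v)
        desc = dm.quartile_levels(v, descending=True)
        np.testing.assert_array_equal(desc, 5 - asc)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            dm.quartile_levels(np.array([1.0, 2.0]))


class TestAttractorScores:
    def test_half_eigenvalue_time_constant(self):
        s = dm.attractor_scores(np.diag([0.5, 0.1]))
        assert np.isclose(s["time_constants"][0], 1.0 / abs(np.log(0.5)))
        assert np.isclose(s["time_constants"][0], 1.4427, atol=1e-4)

    def test_line_attractor_worked_example(self):
        s = dm.attractor_scores(np.diag([0.99, 0.9]))
        np.testing.assert_allclose(s["time_constants"], [99.499, 9.4912],
                                   atol=0.01)
        assert np.isclose(s["line_attractor_score"], np.log2(99.499 / 9.4912),
                          atol=1e-3)
        assert np.isclose(s["line_attractor_score"], 3.39, atol=0.01)

    def test_conjugate_pair_scores_zero(self):
        om = np.radians(25.0)
        A = 0.97 * np.array([[np.cos(om), -np.sin(om)],
                             [np.sin(om), np.cos(om)]])
        assert dm.attractor_scores(A)["line_attractor_score"] == 0.0

    def test_unit_eigenvalue_flagged_infinite(self):
        s = dm.attractor_scores(np.diag([1.0, 0.5]))
        assert np.isinf(s["stability"])
        assert s["has_unit_eigenvalue"]

    def test_zero_eigenvalue_zero_tau(self):
        s = dm.attractor_scores(np.zeros((2, 2)))
        np.testing.assert_array_equal(s["time_constants"], [0.0, 0.0])


class TestSequentiality:
    def _sequence_matrix(self, n_units=12, T=120, noise=0.0, rng=None):
        rng = rng or np.random.default_rng(0)
        mat = np.zeros((n_units, T))
        for i in range(n_units):
            center = int((i + 0.5) * T / n_units)
            mat[i] = np.exp(-0.5 * ((np.arange(T) - center) / 3.0) ** 2)
        if noise:
            mat += rng.normal(0, noise, mat.shape)
        return mat

    def test_perfect_sequence_beats_null(self):
        mat = self._sequence_matrix()
        out = dm.sequentiality_index(mat, n_shuffles=200, seed=0)
        assert out["index"] > np.percentile(out["null"], 99)

    def test_iid_noise_within_null(self, rng):
        mat = rng.standard_normal((12, 120))
        out = dm.sequentiality_index(mat, n_shuffles=200, seed=0)
        lo, hi = np.percentile(out["null"], [2.5, 97.5])
        assert lo <= out["index"] <= hi

    def test_row_permutation_invariant(self, rng):
        mat = self._sequence_matrix(noise=0.1, rng=rng)
        a = dm.sequentiality_index(mat, n_shuffles=10, seed=1)["index"]
        b = dm.sequentiality_index(mat[rng.permutation(12)], n_shuffles=10,
                                   seed=1)["index"]
        assert np.isclose(a, b)

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            dm.sequentiality_index(np.ones((3, 50)))
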