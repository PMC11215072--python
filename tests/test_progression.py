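"""GP velocity field, finite differences, Euler integration and rendering."""

import numpy as np
import pandas as pd
import pytest

from amyloid_latent_dyn import (
    GPFieldConfig,
    finite_difference_velocities,
    fit_velocity_field,
    generate_image_trajectory,
    integrate_trajectory,
    predict_velocity,
)
from amyloid_latent_dyn.progression import VelocityFieldModel


def _table(rows):
    return pd.DataFrame(rows, columns=["subject_id", "scan_time_years", "age",
                                       "apoe4_count", "b_1", "b_2"])


class TestFiniteDifferences:
    def test_hand_arithmetic(self):
        tab = _table([("s", 0.0, 70.0, 1, 1.0, 0.0), ("s", 0.5, 70.5, 1, 2.0, 2.0)])
        obs = finite_difference_velocities(tab)
        assert len(obs) == 1
        np.testing.assert_allclose(obs[["v_b_1", "v_b_2"]].iloc[0], [2.0, 4.0])
        np.testing.assert_allclose(obs[["b_1", "b_2"]].iloc[0], [1.5, 1.0])
        assert obs["age"].iloc[0] == pytest.approx(70.25)

    def test_identical_latents_give_zero_velocity(self):
        tab = _table([("s", 0.0, 70, 0, 0.7, -0.2), ("s", 1.0, 71, 0, 0.7, -0.2)])
        obs = finite_difference_velocities(tab)
        np.testing.assert_allclose(obs[["v_b_1", "v_b_2"]].iloc[0], [0.0, 0.0])

    def test_count_matches_pairing_oracle(self):
        rng = np.random.default_rng(0)
        counts = [1, 2, 2, 3, 3, 3, 4, 4, 4, 4]
        rows = []
        for i, n in enumerate(counts):
            for j in range(n):
                rows.append((f"s{i}", float(j), 70.0 + j, 0,
                             rng.normal(), rng.normal()))
        obs = finite_difference_velocities(_table(rows))
        # brute-force pairing oracle: one observation per consecutive pair
        expected = sum(n - 1 for n in counts)
        assert len(obs) == expected == 20

    def test_start_point_evaluation_option(self):
        tab = _table([("s", 0.0, 70.0, 1, 1.0, 0.0), ("s", 0.5, 70.5, 1, 2.0, 2.0)])
        obs = finite_difference_velocities(tab, eval_point="start")
        np.testing.assert_allclose(obs[["b_1", "b_2"]].iloc[0], [1.0, 0.0])
        assert obs["age"].iloc[0] == 70.0

    def test_short_intervals_skipped_and_counted(self):
        tab = _table([("s", 0.0, 70, 0, 0.0, 0.0), ("s", 0.1, 70.1, 0, 1.0, 1.0),
                      ("s", 1.1, 71.1, 0, 2.0, 2.0)])
        obs = finite_difference_velocities(tab, min_dt=0.25)
        assert len(obs) == 1
        assert obs.attrs["n_skipped"] == 1

    def test_duplicate_timestamps_raise(self):
        tab = _table([("s", 1.0, 70, 0, 0.0, 0.0), ("s", 1.0, 70, 0, 1.0, 1.0)])
        with pytest.raises(ValueError, match="s"):
            finite_difference_velocities(tab)

    def test_single_scan_subjects_contribute_nothing(self):
        tab = _table([("a", 0.0, 70, 0, 0.0, 0.0)])
        assert len(finite_difference_velocities(tab)) == 0


def _linear_field_observations(A, n=200, noise=0.01, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        b = rng.uniform(-1, 1, 2)
        v = A @ b + rng.normal(0, noise, 2)
        rows.append({"subject_id": f"s{i}", "pair_index": 0, "dt": 0.1,
                     "age": 70.0, "apoe4_count": 0,
                     "b_1": b[0], "b_2": b[1], "v_b_1": v[0], "v_b_2": v[1]})
    obs = pd.DataFrame(rows)
    obs.attrs["score_cols"] = ["b_1", "b_2"]
    return obs


STATE_ONLY = GPFieldConfig(covariates=())


class TestVelocityField:
    def test_null_field_predicts_zero(self):
        obs = _linear_field_observations(np.zeros((2, 2)), n=60, noise=0.0, seed=1)
        model = fit_velocity_field(obs, STATE_ONLY, seed=0)
        for b in np.random.default_rng(2).uniform(-1, 1, (10, 2)):
            v, _ = predict_velocity(b, np.empty(0), model)
            assert np.all(np.abs(v) < 1e-3)

    def test_interpolates_training_targets_in_low_noise_limit(self):
        obs = _linear_field_observations(np.array([[0.3, 0.1], [0.0, -0.4]]),
                                         n=30, noise=0.0, seed=3)
        # fixed hyperparameters: the interpolation property is exact only
        # when the kernel is not driven to a degenerate optimum
        cfg = GPFieldConfig(covariates=(), noise_variance=1e-10,
                            noise_bounds=(1e-12, 1e-6), optimize=False)
        model = fit_velocity_field(obs, cfg, seed=0)
        b = obs[["b_1", "b_2"]].to_numpy()[:5]
        target = obs[["v_b_1", "v_b_2"]].to_numpy()[:5]
        pred, _ = predict_velocity(b, np.empty((5, 0)), model)
        np.testing.assert_allclose(pred, target, atol=1e-6)

    def test_linear_field_recovery(self):
        A = np.array([[-0.5, 0.2], [0.1, -0.3]])
        obs = _linear_field_observations(A, n=200, noise=0.01, seed=4)
        model = fit_velocity_field(obs, STATE_ONLY, seed=0)
        grid = np.random.default_rng(5).uniform(-0.9, 0.9, (100, 2))
        pred, _ = predict_velocity(grid, np.empty((100, 0)), model)
        rmse = np.sqrt(np.mean((pred - grid @ A.T) ** 2))
        assert rmse < 5 * 0.01
        p, _ = predict_velocity(np.array([1.0, 1.0]), np.empty(0), model)
        np.testing.assert_allclose(p, A @ np.ones(2), atol=0.05)

    def test_prior_reversion_far_from_data(self):
        obs = _linear_field_observations(np.array([[-0.5, 0.0], [0.0, -0.5]]),
                                         n=60, noise=0.01, seed=6)
        model = fit_velocity_field(obs, STATE_ONLY, seed=0)
        _, var_in = predict_velocity(np.zeros(2), np.empty(0), model)
        v_far, var_far = predict_velocity(np.full(2, 50.0), np.empty(0), model)
        # posterior mean reverts toward the de-meaned prior; variance grows
        assert np.all(var_far > var_in)
        np.testing.assert_allclose(v_far, model.target_mean, atol=0.05)

    def test_seeded_determinism(self):
        obs = _linear_field_observations(np.eye(2) * -0.2, n=40, seed=7)
        m1 = fit_velocity_field(obs, STATE_ONLY, seed=3)
        m2 = fit_velocity_field(obs, STATE_ONLY, seed=3)
        for g1, g2 in zip(m1.gps, m2.gps):
            np.testing.assert_array_equal(g1.kernel_.theta, g2.kernel_.theta)

    def test_too_few_observations_rejected(self):
        obs = _linear_field_observations(np.eye(2), n=3)
        with pytest.raises(ValueError, match="at least 5"):
            fit_velocity_field(obs, STATE_ONLY)

    def test_degenerate_states_rejected(self):
        obs = _linear_field_observations(np.eye(2), n=10)
        obs[["b_1", "b_2"]] = 0.5
        with pytest.raises(ValueError, match="degenerate"):
            fit_velocity_field(obs, STATE_ONLY)

    def test_serialization_roundtrip(self, tmp_path):
        obs = _linear_field_observations(np.eye(2) * -0.3, n=30, seed=8)
        model = fit_velocity_field(obs, STATE_ONLY, seed=0)
        model.save(tmp_path / "field.joblib")
        loaded = VelocityFieldModel.load(tmp_path / "field.joblib")
        b = np.array([0.2, -0.1])
        np.testing.assert_array_equal(
            predict_velocity(b, np.empty(0), model)[0],
            predict_velocity(b, np.empty(0), loaded)[0],
        )


class TestEuler:
    def test_zero_duration(self):
        traj = integrate_trajectory(np.array([1.0]), np.empty(0), 0.0, 0.1,
                                    field=lambda b, c: -b)
        assert traj.times.tolist() == [0.0]
        np.testing.assert_array_equal(traj.states, [[1.0]])

    def test_exponential_decay_closed_form(self):
        traj = integrate_trajectory(np.array([1.0]), np.empty(0), 1.0, 1e-4,
                                    field=lambda b, c: -b)
        assert abs(traj.states[-1, 0] - np.exp(-1.0)) < 1e-3

    def test_first_order_convergence(self):
        def endpoint_error(h):
            traj = integrate_trajectory(np.array([1.0]), np.empty(0), 1.0, h,
                                        field=lambda b, c: -b)
            return abs(traj.states[-1, 0] - np.exp(-1.0))

        ratio = endpoint_error(2e-3) / endpoint_error(1e-3)
        assert 1.7 <= ratio <= 2.3

    def test_initial_state_exact_and_grid_increasing(self):
        b0 = np.array([0.3, -0.2])
        traj = integrate_trajectory(b0, np.array([70.0]), 2.0, 0.3,
                                    field=lambda b, c: np.zeros_like(b))
        assert np.array_equal(traj.states[0], b0)
        assert traj.times[0] == 0.0
        assert np.all(np.diff(traj.times) > 0)
        assert traj.times[-1] == pytest.approx(2.0)

    def test_age_advances_with_time(self):
        seen = []

        def field(b, c):
            seen.append(c[0])
            return np.zeros_like(b)

        integrate_trajectory(np.zeros(1), np.array([70.0]), 1.0, 0.5, field=field)
        np.testing.assert_allclose(seen, [70.0, 70.5])

    def test_nonfinite_state_aborts_with_step_index(self):
        with pytest.raises(RuntimeError, match="step"):
            integrate_trajectory(np.array([1.0]), np.empty(0), 5.0, 0.5,
                                 field=lambda b, c: b * 1e300)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            integrate_trajectory(np.zeros(1), np.empty(0), 1.0, 0.0,
                                 field=lambda b, c: b)
        with pytest.raises(ValueError):
            integrate_trajectory(np.zeros(1), np.empty(0), -1.0, 0.1,
                                 field=lambda b, c: b)


class TestImageTrajectory:
    def test_t0_bit_matches_reconstruction_chain(self, tiny_gan):
        from amyloid_latent_dyn import EncoderConfig, EncoderModel, fit_pca, project, back_project

        enc = EncoderModel(EncoderConfig(volume_shape=(16, 16, 16), w_dim=8, seed=5))
        rng = np.random.default_rng(6)
        W = rng.normal(size=(20, 8))
        pca = fit_pca(W, 3)
        vol = rng.normal(size=(16, 16, 16)).astype(np.float32)
        res = generate_image_trajectory(
            vol, np.empty(0), [0.0], enc, tiny_gan, pca,
            field=lambda b, c: np.zeros_like(b),
        )
        expected = tiny_gan.synthesize(back_project(project(enc.encode(vol), pca), pca))
        assert np.array_equal(res["volumes"][0], expected)
        np.testing.assert_array_equal(res["differences"][0], 0.0)

    def test_requested_times_validated(self, tiny_gan):
        from amyloid_latent_dyn import EncoderConfig, EncoderModel, fit_pca

        enc = EncoderModel(EncoderConfig(volume_shape=(16, 16, 16), w_dim=8, seed=5))
        pca = fit_pca(np.random.default_rng(7).normal(size=(10, 8)), 2)
        vol = np.zeros((16, 16, 16), np.float32)
        with pytest.raises(ValueError, match="times"):
            generate_image_trajectory(vol, np.empty(0), [1.0, 2.0], enc, tiny_gan,
                                      pca, field=lambda b, c: b)


class TestPlot:
    def test_phase_plot_written_and_colors(self, tmp_path):
        from amyloid_latent_dyn.progression import _positivity_color, plot_dynamics

        assert _positivity_color(1.05) == "tab:blue"
        assert _positivity_color(1.15) == "tab:green"
        assert _positivity_color(1.25) == "tab:red"

        obs = _linear_field_observations(np.eye(2) * -0.2, n=30, seed=9)
        model = fit_velocity_field(obs, STATE_ONLY, seed=0)
        rng = np.random.default_rng(10)
        rows = []
        for i in range(6):
            rows.append({"subject_id": f"s{i}", "scan_time_years": 0.0,
                         "age": 70.0, "apoe4_count": 0, "suvr": 1.0 + 0.05 * i,
                         "b_1": rng.normal(), "b_2": rng.normal()})
        table = pd.DataFrame(rows)
        out = plot_dynamics(table, model, tmp_path / "phase.png",
                            long_subjects=["s1"])
        assert out.exists() and out.stat().st_size > 0

    def test_unknown_long_subject_raises(self, tmp_path):
        obs = _linear_field_observations(np.eye(2) * -0.2, n=30, seed=11)
        model = fit_velocity_field(obs, STATE_ONLY, seed=0)
        table = pd.DataFrame([{"subject_id": "s0", "scan_time_years": 0.0,
                               "age": 70.0, "apoe4_count": 0, "suvr": 1.0,
                               "b_1": 0.0, "b_2": 0.0}])
        from amyloid_latent_dyn.progression import plot_dynamics
        with pytest.raises(ValueError, match="unknown"):
            plot_dynamics(table, model, tmp_path / "x.png", long_subjects=["nope"])
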