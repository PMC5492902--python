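"""Chain-constrained EKF/UKF: process model, measurement models, tracking."""

import numpy as np
import pytest

from armfuse.arm_model import build_dh_from_chain, segment_angular_velocity
from armfuse.chain_filters import (
    ChainFilterParams,
    ChainFilterState,
    Method5Filter,
    UtConfig,
    method4_measurement,
    method4_track,
    method5_measurement,
    method5_track,
    process_matrix,
    process_predict,
)
from armfuse.synthetic import (
    CameraModel,
    DEFAULT_M0,
    GRAVITY,
    MotionScript,
    NoiseModel,
    SensorMounting,
    default_mounting,
    generate_trajectory,
    synthesize_camera,
    synthesize_imu,
)


def _state(ndof, X=None):
    X = np.zeros(3 * ndof) if X is None else np.asarray(X, float)
    return ChainFilterState(X, np.eye(3 * ndof))


class TestProcessModel:
    def test_rest_state_unchanged(self):
        st = _state(5)
        out = process_predict(st, 0.01)
        np.testing.assert_array_equal(out.X, st.X)

    def test_single_step_arithmetic(self):
        st = _state(1, [0.0, 1.0, 0.0])
        out = process_predict(st, 0.01)
        assert out.X[0] == pytest.approx(0.01, abs=1e-15)

    def test_quadratic_trajectory_exact_over_1000_steps(self):
        # closed form: q(t) = a + b t + c t²/... is reproduced exactly
        a, b, c = 0.2, -0.4, 1.3
        T = 0.01
        st = _state(1, [a, b, c])
        for j in range(1, 1001):
            st = process_predict(st, T)
            t = j * T
            expected = a + b * t + 0.5 * c * t * t
            assert abs(st.X[0] - expected) < 1e-12

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            process_matrix(5, 0.0)

    def test_state_shape_validation(self):
        with pytest.raises(ValueError):
            ChainFilterState(np.zeros(4), np.eye(4))


class TestMethod4Measurement:
    def test_n_pose_at_rest_predicts_gravity_and_zero_rate(self, chain):
        mounting = default_mounting()
        z = method4_measurement(np.zeros(15), chain, mounting)
        for i, _name in enumerate(mounting.segments):
            block = z[7 * i : 7 * i + 7]
            np.testing.assert_allclose(block[:3], -GRAVITY, atol=1e-12)  # accel
            np.testing.assert_allclose(block[3:6], 0.0, atol=1e-15)  # gyro
            assert abs(block[6]) < 1e-12  # heading innovation reference

    def test_camera_row_matches_simulator(self, chain):
        # cross-check against the camera synthesis on the true state
        truth = generate_trajectory(MotionScript("EFE", slow_cycles=1, fast_cycles=0), chain)
        cam = CameraModel()
        _, xy = synthesize_camera(truth, cam, NoiseModel.zero())
        k = 4
        idx = k * cam.rate_divisor
        X = np.zeros(15)
        X[0::3] = truth.Q[idx]
        X[1::3] = truth.Qd[idx]
        X[2::3] = truth.Qdd[idx]
        z = method4_measurement(X, chain, default_mounting(), camera=cam)
        np.testing.assert_allclose(z[-2:], xy[k], atol=1e-12)

    def test_heading_first_order_invariant_to_arm_pitch(self, chain):
        # flexing the arm (pitch) must not masquerade as a heading change
        mounting = default_mounting()
        m_meas = {name: DEFAULT_M0.copy() for name in mounting.segments}
        d = 1e-4
        for joint_idx in (0, 3):  # shoulder and elbow flexion
            Xp = np.zeros(15)
            Xm = np.zeros(15)
            Xp[3 * joint_idx] = d
            Xm[3 * joint_idx] = -d
            zp = method4_measurement(Xp, chain, mounting, m_meas=m_meas)
            zm = method4_measurement(Xm, chain, mounting, m_meas=m_meas)
            for i in range(len(mounting.segments)):
                dh = (zp[7 * i + 6] - zm[7 * i + 6]) / (2 * d)
                assert abs(dh) < 1e-6


class TestMethod5Measurement:
    def test_zero_lever_arm_reduces_to_joint_origin_model(self, chain):
        mounting = default_mounting()
        zero_lever = SensorMounting(
            rotation=dict(mounting.rotation),
            lever_arm={k: np.zeros(3) for k in mounting.lever_arm},
        )
        rng = np.random.default_rng(0)
        X = rng.uniform(-0.5, 0.5, 15)
        z5 = method5_measurement(X, chain, zero_lever)
        z4 = method4_measurement(X, chain, zero_lever)
        for i in range(2):
            np.testing.assert_allclose(z5[9 * i : 9 * i + 3], z4[7 * i : 7 * i + 3], atol=1e-12)

    def test_static_pose_reads_exact_gravity(self, chain):
        rng = np.random.default_rng(1)
        q = rng.uniform(-1, 1, 5)
        X = np.zeros(15)
        X[0::3] = q
        z = method5_measurement(X, chain, default_mounting())
        sig = chain.signals(q[None])
        for i, name in enumerate(("upper_arm", "forearm")):
            expected = sig[name].R[0].T @ (-GRAVITY)
            np.testing.assert_allclose(z[9 * i : 9 * i + 3], expected, atol=1e-12)

    def test_gyro_prediction_matches_angular_velocity_oracle(self, chain):
        rng = np.random.default_rng(2)
        q = rng.uniform(-0.8, 0.8, 5)
        qd = rng.uniform(-1, 1, 5)
        X = np.zeros(15)
        X[0::3] = q
        X[1::3] = qd
        z = method5_measurement(X, chain, default_mounting())
        omega = segment_angular_velocity(chain, q, qd)
        for i, name in enumerate(("upper_arm", "forearm")):
            np.testing.assert_allclose(z[9 * i + 3 : 9 * i + 6], omega[name], atol=1e-12)


class TestUnscentedTransform:
    def test_weights_sum_to_one(self):
        ut = UtConfig()
        _, wm, wc = ut.weights(15)
        # alpha = 1e-3 gives O(1e6) weights; cancellation leaves ~1e-10
        assert np.sum(wm) == pytest.approx(1.0, abs=1e-8)
        assert np.sum(UtConfig(alpha=1.0).weights(15)[1]) == pytest.approx(1.0, abs=1e-12)

    def test_sigma_points_reproduce_linear_map_exactly(self, chain, rng):
        # UT exactness on linear functions: mean and covariance closed form
        mounting = default_mounting()
        n = 15
        A = rng.standard_normal((4, n))
        b = rng.standard_normal(4)
        f = Method5Filter(chain, mounting, measurement_fn=lambda S: S @ A.T + b)
        X = rng.standard_normal(n)
        P = np.eye(n) * 0.1
        lam, wm, wc = f.ut.weights(n)
        sp = f._sigma_points(X, P, lam)
        Z = sp @ A.T + b
        zm = wm @ Z
        dZ = Z - zm
        Pzz = np.einsum("k,ki,kj->ij", wc, dZ, dZ)
        np.testing.assert_allclose(zm, A @ X + b, atol=1e-9)
        np.testing.assert_allclose(Pzz, A @ P @ A.T, atol=1e-8)

    def test_ukf_update_equals_kf_on_linear_measurement(self, chain, rng):
        # linear-Gaussian equivalence oracle: closed-form Kalman update
        mounting = default_mounting()
        n = 15
        H = rng.standard_normal((6, n))
        Rm = np.diag(rng.uniform(0.1, 0.5, 6))
        z = rng.standard_normal(6)
        params = ChainFilterParams(jerk_sigma=1.0)
        # unit spread keeps the UT weights benign so the linear-Gaussian
        # equivalence is exact to numerical precision
        f = Method5Filter(
            chain, mounting, params=params, ut=UtConfig(alpha=1.0, beta=0.0),
            measurement_fn=lambda S: S @ H.T,
        )
        X0 = f.state.X.copy()
        P0 = f.state.P.copy()
        T = 0.01
        out = f.step(z, Rm, None, T)
        # closed-form KF on the same linear system
        F = process_matrix(5, T)
        from armfuse.chain_filters import _process_noise

        Xp = F @ X0
        Pp = F @ P0 @ F.T + _process_noise(5, T, params.jerk_sigma)
        S = H @ Pp @ H.T + Rm
        K = Pp @ H.T @ np.linalg.inv(S)
        X_kf = Xp + K @ (z - H @ Xp)
        P_kf = Pp - K @ S @ K.T
        np.testing.assert_allclose(out.X, X_kf, atol=1e-9)
        np.testing.assert_allclose(out.P, P_kf, atol=1e-8)


class TestTrackingRoundTrips:
    def test_method4_holds_true_trajectory_on_clean_streams(self, chain, short_efe_truth, short_efe_clean):
        res = method4_track(short_efe_clean, chain)
        assert np.abs(res.joint_angles - short_efe_truth.Q).max() < 2e-5

    def test_method5_holds_true_trajectory_on_clean_streams(self, chain, short_efe_truth, short_efe_clean):
        res = method5_track(short_efe_clean, chain)
        assert np.abs(res.joint_angles - short_efe_truth.Q).max() < 0.02
        err = np.linalg.norm(res.wrist - short_efe_truth.wrist, axis=1)
        assert err.mean() < 2e-3

    def test_method4_converges_from_wrong_elbow_angle(self, chain):
        # static noiseless input, biased elbow initialization
        truth = generate_trajectory(
            MotionScript("EFE", amplitude=0.0, slow_cycles=1, fast_cycles=0, lead_in=3.0), chain
        )
        stream = synthesize_imu(truth, noise=NoiseModel.zero(), camera=CameraModel())
        from armfuse.chain_filters import Method4Filter

        filt = Method4Filter(chain, default_mounting(), camera=CameraModel())
        filt.state.X[9] = 0.5  # elbow flexion error of ~29 degrees
        cam_lookup = {int(round(tk / stream.dt)): row for tk, row in zip(stream.camera_t, stream.camera)}
        errs = []
        for j in range(truth.n_samples):
            st = filt.step(
                {k: v[j] for k, v in stream.accel.items()},
                {k: v[j] for k, v in stream.gyro.items()},
                {k: v[j] for k, v in stream.mag.items()},
                stream.dt,
                cam_row=cam_lookup.get(j),
            )
            errs.append(abs(st.q[3]))
        # monotone decrease after burn-in; large reduction of the initial error
        burn = np.array(errs[20:])
        assert np.all(np.diff(burn[:: len(burn) // 10]) < 0)
        assert errs[-1] < 0.1 * errs[0]

    def test_camera_aiding_beats_magnetic_disturbance(self, chain):
        """Paired seeded runs under a scripted field disturbance: the camera
        channel must strictly reduce the wrist RMSE."""
        dist = lambda t: 0.4 * np.array([np.cos(0.3 * t + 1.0), np.sin(0.3 * t + 1.0), 0.1 * np.sin(0.2 * t)])
        truth = generate_trajectory(MotionScript("EFE", slow_cycles=3, fast_cycles=1), chain)
        noise = NoiseModel(seed=5, mag_disturbance=dist)
        stream = synthesize_imu(truth, noise=noise, camera=CameraModel())
        rmse = {}
        for use_cam in (True, False):
            res = method4_track(stream, chain, use_camera=use_cam)
            rmse[use_cam] = np.sqrt(np.mean(np.sum((res.wrist - truth.wrist) ** 2, axis=1)))
        assert rmse[True] < rmse[False]

    def test_method4_innovation_whiteness_sanity(self, chain):
        # well-specified noise: normalized innovation squared stays moderate
        truth = generate_trajectory(MotionScript("EFE", slow_cycles=1, fast_cycles=0), chain)
        stream = synthesize_imu(truth, noise=NoiseModel(seed=11), camera=CameraModel())
        from armfuse.chain_filters import Method4Filter

        filt = Method4Filter(chain, default_mounting(), camera=CameraModel())
        for j in range(truth.n_samples):
            filt.step(
                {k: v[j] for k, v in stream.accel.items()},
                {k: v[j] for k, v in stream.gyro.items()},
                {k: v[j] for k, v in stream.mag.items()},
                stream.dt,
            )
        nis = np.array(filt.nis_history[50:])
        # soft sanity: median NIS within an order of magnitude of its dimension
        assert np.median(nis) < 10 * 16

    def test_method5_runs_on_explicit_dh_chain(self, chain, short_efe_truth, short_efe_clean):
        dh = build_dh_from_chain(chain)
        res = method5_track(short_efe_clean, dh)
        err = np.linalg.norm(res.wrist - short_efe_truth.wrist, axis=1)
        assert err.mean() < 2e-3

    def test_covariances_remain_psd(self, chain, short_efe_clean):
        res = method4_track(short_efe_clean, chain)
        assert res.joint_angles is not None  # _check_psd raised nowhere
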