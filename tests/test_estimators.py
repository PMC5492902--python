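"""Wahba solver and the free-segment trackers (methods 1-3, strapdown)."""

import numpy as np
import pytest

from armfuse.arm_model import Joint, KinematicChain, LimbSegment
from armfuse.estimators import (
    Cf3Config,
    Cf3Filter,
    Method1Filter,
    Method1Params,
    Method2Filter,
    Method2Params,
    WahbaProblem,
    attitude_from_vectors,
    reconstruct_positions,
    solve_wahba,
    solve_wahba_svd,
    track_free_segments,
)
from armfuse.kinematics import (
    geodesic_angle,
    quat_angle,
    quat_to_rotmat,
    random_rotation,
    rotation_about_axis,
    skew,
)
from armfuse.synthetic import (
    DEFAULT_M0,
    GRAVITY,
    MotionScript,
    NoiseModel,
    generate_trajectory,
    synthesize_imu,
)

G_REF = -GRAVITY  # static accelerometer reading in the root frame


class TestWahba:
    def test_identity_when_observations_equal_references(self):
        refs = np.array([[0, 0, 1.0], [1.0, 0, 0]])
        q = solve_wahba(WahbaProblem(refs, refs))
        np.testing.assert_allclose(q, [1, 0, 0, 0], atol=1e-12)

    def test_construct_then_recover(self, rng):
        for _ in range(50):
            A = random_rotation(rng)
            refs = rng.standard_normal((2, 3))
            refs /= np.linalg.norm(refs, axis=1, keepdims=True)
            obs = refs @ A.T
            q = solve_wahba(WahbaProblem(obs, refs))
            # small-angle-accurate metric: ‖R−A‖_F = 2√2·sin(θ/2)
            theta = 2 * np.arcsin(min(np.linalg.norm(quat_to_rotmat(q) - A) / (2 * np.sqrt(2)), 1.0))
            assert theta < 1e-9

    def test_qmethod_agrees_with_svd_oracle(self, rng):
        for _ in range(300):
            A = random_rotation(rng)
            refs = rng.standard_normal((2, 3))
            refs /= np.linalg.norm(refs, axis=1, keepdims=True)
            q1 = solve_wahba(WahbaProblem(refs @ A.T, refs))
            q2 = solve_wahba_svd(WahbaProblem(refs @ A.T, refs))
            assert quat_angle(q1, q2) < 1e-6

    def test_collinear_observations_rejected(self):
        refs = np.array([[0, 0, 1.0], [0, 0, -1.0]])
        with pytest.raises(ValueError, match="degenerate"):
            solve_wahba(WahbaProblem(refs, refs))

    def test_negative_weights_rejected(self):
        refs = np.array([[0, 0, 1.0], [1, 0, 0.0]])
        with pytest.raises(ValueError):
            WahbaProblem(refs, refs, weights=[1.0, -1.0])

    def test_attitude_from_vectors_inverts_simulated_readings(self, rng):
        for _ in range(20):
            R = random_rotation(rng)
            q = attitude_from_vectors(R.T @ G_REF, R.T @ DEFAULT_M0)
            assert np.linalg.norm(quat_to_rotmat(q) - R) < 3e-9


class TestMethod1:
    def test_static_filter_keeps_constant_measurements(self):
        f = Method1Filter(G_REF, DEFAULT_M0)
        for _ in range(200):
            q = f.step(np.zeros(3), G_REF, DEFAULT_M0, 0.01)
        np.testing.assert_allclose(f.X[:3], G_REF, atol=1e-9)
        np.testing.assert_allclose(f.X[3:], DEFAULT_M0, atol=1e-9)
        np.testing.assert_allclose(q, [1, 0, 0, 0], atol=1e-9)

    def test_prediction_tracks_rotated_gravity_second_order(self):
        # closed-form rotated-vector oracle: one predict step vs Rodrigues
        w = np.array([0.0, 0.0, 2.0])
        T = 0.01
        g_body = G_REF.copy()
        F = np.eye(3) - T * skew(w)
        predicted = F @ g_body
        exact = rotation_about_axis(w, np.linalg.norm(w) * T).T @ g_body
        assert np.linalg.norm(predicted - exact) < (np.linalg.norm(w) * T) ** 2 * np.linalg.norm(g_body)

    def test_filtering_reduces_measurement_variance(self):
        # Monte-Carlo: steady-state filtered variance below raw variance
        rng = np.random.default_rng(0)
        sigma = 0.5
        raw_var, filt_var = [], []
        for _ in range(100):
            f = Method1Filter(G_REF, DEFAULT_M0, Method1Params(accel_meas_sigma=sigma))
            xs = []
            zs = []
            for _ in range(300):
                a = G_REF + sigma * rng.standard_normal(3)
                m = DEFAULT_M0 + 0.01 * rng.standard_normal(3)
                f.step(np.zeros(3), a, m, 0.01)
                xs.append(f.X[:3].copy())
                zs.append(a)
            xs, zs = np.array(xs[100:]), np.array(zs[100:])
            filt_var.append(xs.var(axis=0).mean())
            raw_var.append(zs.var(axis=0).mean())
        assert np.mean(filt_var) < 0.5 * np.mean(raw_var)

    def test_covariance_stays_symmetric_psd(self):
        f = Method1Filter(G_REF, DEFAULT_M0)
        rng = np.random.default_rng(1)
        for _ in range(100):
            f.step(rng.standard_normal(3), G_REF, DEFAULT_M0, 0.01)
        np.testing.assert_allclose(f.P, f.P.T, atol=1e-12)
        assert np.min(np.linalg.eigvalsh(f.P)) > -1e-12


class TestMethod2:
    def test_static_converges_to_quest_fix_with_decaying_rate(self):
        f = Method2Filter(G_REF, DEFAULT_M0)
        for _ in range(500):
            q = f.step(np.zeros(3), G_REF, DEFAULT_M0, 0.01)
        np.testing.assert_allclose(q, [1, 0, 0, 0], atol=1e-6)
        assert np.linalg.norm(f.X[:3]) < 1e-6

    def test_free_decay_matches_scalar_ode(self):
        # closed form: omega(t) = omega0 exp(-t/t_k), no measurement updates
        t_k = 0.5
        f = Method2Filter(G_REF, DEFAULT_M0, Method2Params(t_k=(t_k, t_k, t_k)))
        w0 = np.array([1.2, 0.0, 0.0])
        f.initialize(w0, G_REF, DEFAULT_M0)
        T, n = 0.01, 100
        for _ in range(n):
            f.step(np.zeros(3), G_REF, DEFAULT_M0, T, update=False)
        expected = w0[0] * np.exp(-n * T / t_k)
        # first-order discretization error bound
        assert abs(f.X[0] - expected) < 0.02 * w0[0]

    def test_constant_rate_attitude_bounded_over_one_minute(self):
        # simulator round trip: noiseless constant-rate rotation, no drift
        f = Method2Filter(G_REF, DEFAULT_M0)
        w = np.array([0, 0, 0.5])
        T = 0.01
        errs = []
        for j in range(6000):
            R = rotation_about_axis([0, 0, 1], 0.5 * j * T)
            q = f.step(w, R.T @ G_REF, R.T @ DEFAULT_M0, T)
            if j % 100 == 0:
                errs.append(geodesic_angle(quat_to_rotmat(q), R))
        errs = np.array(errs)
        assert errs[-10:].max() < 5e-3  # bounded, no drift accumulation
        assert errs[-10:].max() < max(errs[:10].max(), 1e-3) * 5

    def test_invalid_decay_constant_rejected(self):
        with pytest.raises(ValueError):
            Method2Params(t_k=(0.5, -1.0, 0.5))


class TestMethod3:
    def test_fixed_point_at_true_attitude(self):
        for k in (2.0, 10.0, 200.0):
            f = Cf3Filter(G_REF, DEFAULT_M0, Cf3Config(k=k))
            for _ in range(50):
                q = f.step(np.zeros(3), G_REF, DEFAULT_M0, 0.01)
            np.testing.assert_allclose(q, [1, 0, 0, 0], atol=1e-9)

    def test_pure_and_perfect_identical_without_linear_acceleration(self):
        fp = Cf3Filter(G_REF, DEFAULT_M0, Cf3Config(mode="pure"))
        fx = Cf3Filter(G_REF, DEFAULT_M0, Cf3Config(mode="perfect"))
        rngs = np.random.default_rng(4)
        for _ in range(100):
            w = 0.3 * rngs.standard_normal(3)
            qp = fp.step(w, G_REF, DEFAULT_M0, 0.01)
            qq = fx.step(w, G_REF, DEFAULT_M0, 0.01, la=np.zeros(3))
            np.testing.assert_allclose(qp, qq, atol=1e-12)

    def test_perfect_mode_requires_acceleration(self):
        f = Cf3Filter(G_REF, DEFAULT_M0, Cf3Config(mode="perfect"))
        with pytest.raises(ValueError, match="linear acceleration"):
            f.step(np.zeros(3), G_REF, DEFAULT_M0, 0.01)

    def test_gain_must_exceed_one(self):
        with pytest.raises(ValueError):
            Cf3Config(k=0.5)


class TestTrackingHarness:
    def test_missing_segment_stream_rejected(self, chain, efe_clean_stream):
        import dataclasses

        broken = dataclasses.replace(
            efe_clean_stream,
            accel={"upper_arm": efe_clean_stream.accel["upper_arm"]},
            gyro={"upper_arm": efe_clean_stream.gyro["upper_arm"]},
            mag={"upper_arm": efe_clean_stream.mag["upper_arm"]},
        )
        res = track_free_segments(broken, chain, "method1")
        # only the available segment is tracked; full-chain reconstruction
        # with identity for the missing forearm is intentionally not a wrist fix
        assert "forearm" not in res.quaternions

    def test_unknown_method_rejected(self, chain, efe_clean_stream):
        with pytest.raises(ValueError, match="unknown"):
            track_free_segments(efe_clean_stream, chain, "method7")

    def test_zero_offset_chain_pins_wrist_to_root(self, rng):
        collapsed = KinematicChain(
            [
                LimbSegment("chest", None),
                LimbSegment("upper_arm", "chest", joints=(Joint("sfe", (0, -1, 0)),)),
                LimbSegment("forearm", "upper_arm", joints=(Joint("efe", (0, -1, 0)),)),
                LimbSegment("wrist", "forearm"),
            ]
        )
        rots = {
            name: np.stack([random_rotation(rng) for _ in range(5)])
            for name in ("upper_arm", "forearm")
        }
        wrist = reconstruct_positions(collapsed, rots)
        np.testing.assert_allclose(wrist, np.zeros((5, 3)), atol=1e-15)

    def test_identity_attitudes_reconstruct_n_pose(self, chain):
        rots = {
            name: np.broadcast_to(np.eye(3), (4, 3, 3))
            for name in ("upper_arm", "forearm")
        }
        wrist = reconstruct_positions(chain, rots)
        np.testing.assert_allclose(wrist, np.tile([0.0, 0.20, -0.345], (4, 1)), atol=1e-12)


class TestDriftBehaviour:
    def test_fused_methods_contain_drift_across_cycles(self, chain):
        """On noiseless periodic motion the per-cycle attitude error of the
        fused trackers must not grow cycle over cycle."""
        truth = generate_trajectory(MotionScript("EFE", slow_cycles=5, fast_cycles=0), chain)
        stream = synthesize_imu(truth, noise=NoiseModel.zero())
        Rtrue = truth.signals["forearm"].R
        b = truth.cycle_bounds
        for method in ("method1", "method3_pure"):
            res = track_free_segments(stream, chain, method)
            cycle_err = []
            for c in range(len(b) - 1):
                errs = [
                    geodesic_angle(quat_to_rotmat(res.quaternions["forearm"][j]), Rtrue[j])
                    for j in range(b[c], b[c + 1], 20)
                ]
                cycle_err.append(np.mean(errs))
            slope = np.polyfit(np.arange(len(cycle_err)), cycle_err, 1)[0]
            assert slope < 1e-3, f"{method} drifts: per-cycle errors {cycle_err}"

    def test_biased_strapdown_drifts_linearly(self, chain):
        """Negative control: gyro bias integrates into linearly growing
        attitude error that every fused method must beat."""
        truth = generate_trajectory(MotionScript("EFE", slow_cycles=3, fast_cycles=0), chain)
        noise = NoiseModel(gyro_sigma=0, gyro_bias=0.02, accel_sigma=0, mag_sigma=0, seed=2)
        stream = synthesize_imu(truth, noise=noise)
        res = track_free_segments(stream, chain, "strapdown")
        Rtrue = truth.signals["forearm"].R
        errs = np.array(
            [
                geodesic_angle(quat_to_rotmat(res.quaternions["forearm"][j]), Rtrue[j])
                for j in range(0, truth.n_samples, 100)
            ]
        )
        # monotone growth, roughly linear in time
        assert np.all(np.diff(errs) > 0)
        assert errs[-1] > 0.5 * 0.02 * truth.t[-1]  # bias direction partly along the spin axis
        res1 = track_free_segments(stream, chain, "method1")
        err1 = geodesic_angle(quat_to_rotmat(res1.quaternions["forearm"][-1]), Rtrue[-1])
        assert err1 < errs[-1]
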