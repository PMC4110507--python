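"""Angular-velocity extraction, Euler decomposition and derived series."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tremorkit.errors import UnsupportedOperation, ValidationError
from tremorkit.kinematics import (
    AngularVelocityTrace,
    Frame,
    GimbalLockWarning,
    OrientationTrace,
    angular_acceleration,
    angular_displacement,
    euler_decompose,
    integrate_angular_velocity,
    joint_angular_velocity,
    poisson_angular_velocity,
    resample,
)

RATE = 100.0


def _constant_rate_trace(axis, rate_rad_s=1.0, duration=2.0, fs=RATE):
    t = np.arange(0.0, duration, 1.0 / fs)
    rotvecs = np.outer(rate_rad_s * t, axis)
    return OrientationTrace(t, Rotation.from_rotvec(rotvecs).as_matrix())


def _smooth_omega(rng, t, amp=2.0, freqs=(0.3, 0.7, 1.3)):
    """Band-limited random angular velocity (reach-band content)."""
    w = np.zeros((t.size, 3))
    for ax in range(3):
        for f, a, p in zip(freqs, rng.uniform(0.3, 1.0, 3), rng.uniform(0, 7, 3)):
            w[:, ax] += a * np.sin(2 * np.pi * f * t + p)
    return amp * w / np.max(np.linalg.norm(w, axis=1))


class TestPoissonAngularVelocity:
    def test_static_orientation_gives_zero(self):
        t = np.arange(0.0, 1.0, 0.01)
        trace = OrientationTrace(t, np.tile(np.eye(3), (t.size, 1, 1)))
        av = poisson_angular_velocity(trace)
        assert np.allclose(av.omega, 0.0)

    @pytest.mark.parametrize("axis", [np.eye(3)[i] for i in range(3)], ids="xyz")
    def test_constant_rate_rotation_recovered(self, axis):
        av = poisson_angular_velocity(_constant_rate_trace(axis))
        interior = av.omega[1:-1]
        assert np.max(np.abs(interior - axis)) < 1e-3

    def test_agrees_with_quaternion_derivative_oracle(self):
        """omega = 2 qdot x q* is an independent route to the same velocity."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = np.arange(0.0, 5.0, 1.0 / RATE)
            trace = integrate_angular_velocity(t, _smooth_omega(rng, t))
            omega = poisson_angular_velocity(trace).omega

            q = trace.as_quaternions()  # (n, 4) wxyz
            qdot = np.gradient(q, 1.0 / RATE, axis=0)
            # quaternion product 2 * qdot * conj(q), vector part
            w0, x0, y0, z0 = qdot.T
            w1, x1, y1, z1 = (q * np.array([1.0, -1.0, -1.0, -1.0])).T
            oracle = 2.0 * np.stack(
                [
                    w0 * x1 + x0 * w1 + y0 * z1 - z0 * y1,
                    w0 * y1 - x0 * z1 + y0 * w1 + z0 * x1,
                    w0 * z1 + x0 * y1 - y0 * x1 + z0 * w1,
                ],
                axis=1,
            )
            rms = np.sqrt(np.mean((omega - oracle) ** 2))
            assert rms < 1e-3, f"seed {seed}: RMS {rms}"

    def test_round_trip_recovers_omega(self):
        """Integration followed by extraction returns the input velocity."""
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            t = np.arange(0.0, 5.0, 1.0 / RATE)
            # fast reaching: up to 10 rad/s with sub-hertz content
            w = _smooth_omega(rng, t, amp=10.0, freqs=(0.2, 0.4, 0.8))
            back = poisson_angular_velocity(integrate_angular_velocity(t, w)).omega
            assert np.sqrt(np.mean((back - w) ** 2)) < 1e-2

    def test_global_frame_equivariance(self):
        """Rotating the global frame by fixed Q maps omega to Q omega."""
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 3.0, 1.0 / RATE)
        trace = integrate_angular_velocity(t, _smooth_omega(rng, t))
        Q = Rotation.from_rotvec([0.4, -0.2, 0.9]).as_matrix()
        rotated = OrientationTrace(t, Q @ trace.rotations)
        w = poisson_angular_velocity(trace).omega
        w_rot = poisson_angular_velocity(rotated).omega
        assert np.allclose(w_rot, w @ Q.T, atol=1e-9)

    def test_body_frame_variant(self):
        """For rotation about a fixed axis body and global velocities agree."""
        av_g = poisson_angular_velocity(_constant_rate_trace(np.array([0, 0, 1.0])))
        av_b = poisson_angular_velocity(
            _constant_rate_trace(np.array([0, 0, 1.0])), frame=Frame.BODY
        )
        assert np.allclose(av_g.omega[1:-1], av_b.omega[1:-1], atol=1e-6)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValidationError):
            OrientationTrace(np.array([0.0, 0.01]), np.tile(np.eye(3), (2, 1, 1)))


class TestEulerDecompose:
    def test_single_axis_rotation(self):
        t = np.arange(3) * 0.01
        R = np.tile(Rotation.from_euler("z", 0.3).as_matrix(), (3, 1, 1))
        angles = euler_decompose(OrientationTrace(t, R))
        assert np.allclose(angles, [0.3, 0.0, 0.0], atol=1e-12)

    def test_identity_trace_gives_zero(self):
        t = np.arange(5) * 0.01
        angles = euler_decompose(OrientationTrace(t, np.tile(np.eye(3), (5, 1, 1))))
        assert np.allclose(angles, 0.0)

    def test_round_trip_on_random_triples(self):
        rng = np.random.default_rng(0)
        n = 1000
        triples = np.stack(
            [
                rng.uniform(-np.pi + 0.1, np.pi - 0.1, n),
                rng.uniform(-1.4, 1.4, n),  # clear of gimbal lock
                rng.uniform(-np.pi + 0.1, np.pi - 0.1, n),
            ],
            axis=1,
        )
        R = Rotation.from_euler("ZYX", triples).as_matrix()
        t = np.arange(n) * 0.01
        back = euler_decompose(OrientationTrace(t, R), unwrap=False)
        assert np.max(np.abs(back - triples)) < 1e-9

    def test_near_gimbal_lock_warns_but_returns(self):
        t = np.arange(3) * 0.01
        R = np.tile(Rotation.from_euler("y", np.pi / 2 - 1e-4).as_matrix(), (3, 1, 1))
        with pytest.warns(GimbalLockWarning):
            angles = euler_decompose(OrientationTrace(t, R))
        assert angles.shape == (3, 3)

    def test_unwrap_removes_two_pi_jumps(self):
        t = np.arange(0.0, 10.0, 1.0 / RATE)
        trace = _constant_rate_trace(np.array([0, 0, 1.0]), rate_rad_s=1.0, duration=10.0)
        yaw = euler_decompose(trace)[:, 0]
        assert np.max(np.abs(np.diff(yaw))) < 0.5  # no 2*pi steps
        assert yaw[-1] > 6.0  # accumulated past pi


class TestJointAngularVelocity:
    def test_identical_inputs_give_zero(self, clean_sim):
        av = poisson_angular_velocity(clean_sim.recording.sensors["hand"])
        assert np.allclose(joint_angular_velocity(av, av).omega, 0.0)

    def test_zero_proximal_is_identity(self):
        t = np.arange(5) * 0.01
        d = AngularVelocityTrace(t, np.arange(15.0).reshape(5, 3))
        p = AngularVelocityTrace(t, np.zeros((5, 3)))
        assert np.array_equal(joint_angular_velocity(d, p).omega, d.omega)

    def test_recovers_configured_wrist_contribution(self, clean_sim):
        """hand - distal forearm equals the documented wrist waveform (noise off)."""
        truth = clean_sim.truth
        t = truth.timestamps
        cfg_amp = 0.4 * 1.8**2  # voluntary_amp * distal_gain^2
        mix = np.array([1.0, 0.5, 0.1])
        mix = mix / np.linalg.norm(mix)
        base = np.sin(2 * np.pi * 0.1 * t + 1.05) + 0.3 * np.sin(
            2 * np.pi * 0.2 * t + 1.7 * 1.05
        )
        expected = cfg_amp * np.outer(base, mix)
        got = truth.voluntary["hand"] - truth.voluntary["forearm_distal"]
        assert np.max(np.abs(got - expected)) < 1e-6

    def test_mismatched_timestamps_rejected(self):
        t = np.arange(5) * 0.01
        a = AngularVelocityTrace(t, np.zeros((5, 3)))
        b = AngularVelocityTrace(t + 0.5, np.zeros((5, 3)))
        with pytest.raises(ValidationError):
            joint_angular_velocity(a, b)


class TestDisplacementAndAcceleration:
    def test_constant_rate_integral(self):
        t = np.arange(0.0, 2.0 + 1e-9, 0.01)
        av = AngularVelocityTrace(t, np.tile([0.0, 0.0, 1.0], (t.size, 1)))
        disp = angular_displacement(av)
        assert abs(disp[-1, 2] - 2.0) < 1e-12
        assert np.allclose(disp[:, 2], t, atol=1e-12)

    def test_zero_input_zero_output(self):
        t = np.arange(5) * 0.01
        av = AngularVelocityTrace(t, np.zeros((5, 3)))
        assert np.allclose(angular_displacement(av), 0.0)
        assert np.allclose(angular_acceleration(av), 0.0)

    def test_cosine_integrates_to_sine(self):
        t = np.arange(0.0, 3.0, 1.0 / RATE)
        w = np.zeros((t.size, 3))
        w[:, 0] = np.cos(2 * np.pi * t)
        disp = angular_displacement(AngularVelocityTrace(t, w))
        assert np.max(np.abs(disp[:, 0] - np.sin(2 * np.pi * t) / (2 * np.pi))) < 1e-4

    def test_displacement_additive_over_segments(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 4.0, 1.0 / RATE)
        w = rng.normal(size=(t.size, 3))
        full = angular_displacement(AngularVelocityTrace(t, w))
        k = t.size // 2
        first = angular_displacement(AngularVelocityTrace(t[: k + 1], w[: k + 1]))
        second = angular_displacement(AngularVelocityTrace(t[k:], w[k:]))
        glued = np.vstack([first, first[-1] + second[1:]])
        assert np.allclose(glued, full, atol=1e-12)

    def test_linear_ramp_acceleration(self):
        t = np.arange(0.0, 2.0, 0.01)
        w = np.zeros((t.size, 3))
        w[:, 2] = t
        acc = angular_acceleration(AngularVelocityTrace(t, w))
        assert np.max(np.abs(acc[1:-1, 2] - 1.0)) < 1e-10

    def test_sine_derivative(self):
        t = np.arange(0.0, 3.0, 1.0 / RATE)
        w = np.zeros((t.size, 3))
        w[:, 0] = np.sin(2 * np.pi * t)
        acc = angular_acceleration(AngularVelocityTrace(t, w))
        expected = 2 * np.pi * np.cos(2 * np.pi * t)
        rel_rms = np.sqrt(np.mean((acc[1:-1, 0] - expected[1:-1]) ** 2)) / np.sqrt(
            np.mean(expected**2)
        )
        assert rel_rms < 0.005


class TestResample:
    def test_constant_series(self):
        t = np.arange(0.0, 1.0, 0.01)
        t2, v2 = resample(t, np.full(t.size, 3.3), 1000.0)
        assert np.allclose(v2, 3.3)
        assert t2.size == 991  # spans the same 0.99 s interval

    def test_linear_ramp_exact(self):
        t = np.arange(0.0, 1.0, 0.01)
        t2, v2 = resample(t, 5.0 * t, 1000.0)
        assert np.allclose(v2, 5.0 * t2, atol=1e-12)

    def test_sine_interpolation_error_bound(self):
        f = 5.0
        t = np.arange(0.0, 2.0, 1.0 / RATE)
        t2, v2 = resample(t, np.sin(2 * np.pi * f * t), 1000.0)
        bound = (2 * np.pi * f / RATE) ** 2 / 8.0
        assert np.max(np.abs(v2 - np.sin(2 * np.pi * f * t2))) < bound

    def test_downsampling_refused(self):
        t = np.arange(0.0, 1.0, 0.01)
        with pytest.raises(UnsupportedOperation):
            resample(t, t, 50.0)
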