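"""Synthetic finger-to-nose trials with ground-truth decomposition.

No recordings were published with the method this package implements, so the
generator stands in for them.  It emulates the statistical structure the
algorithms rely on, not musculoskeletal detail:

* an additive kinematic chain — each sensor's angular velocity is the sum of
  the contributions of all joints proximal to it, so proximal movement is
  carried along by distal segments;
* distal amplification — each successive joint contribution is scaled by
  ``distal_gain_voluntary`` (> 1), and kinetic tremor amplitude grows by
  ``distal_gain_tremor`` per segment toward the hand;
* a non-rigid forearm — pronosupination (rotation about the forearm's long
  axis) reaches the proximal forearm sensor only at a fraction
  ``forearm_gradient`` of its distal value, which is what makes the two
  forearm sensors of the 4-sensor layout distinguishable at all;
* kinetic tremor — an amplitude-modulated sinusoid in the 3-12 Hz band whose
  slow envelope follows the movement cycle (tremor waxes during motion);
* measurement imperfections — white noise on the angular velocity, and an
  optional causal first-order low-pass of the orientation stream emulating
  the lag of the sensors' onboard orientation fusion (off by default).

Orientations are produced by exact per-step axis-angle integration of the
total angular velocity, so Poisson extraction of the generated stream is a
genuine round trip.  The ground truth carries the constructed voluntary,
tremor and total series per sensor, plus a ``gyro`` channel defined as the
Poisson angular velocity of the lag-free orientation stream — what an ideal
co-located gyroscope would deliver to the comparison pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy import signal as sps
from scipy.spatial.transform import Rotation

from .errors import ValidationError
from .io_formats import SensorConfiguration, TrialRecording
from .kinematics import (
    Frame,
    OrientationTrace,
    integrate_angular_velocity,
    poisson_angular_velocity,
)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SimulatedTrial",
    "simulate_trial",
    "make_fixture_suite",
    "write_ground_truth",
    "read_gyro_sidecar",
]

#: chain sites distal -> proximal for each configuration
_SITES = {
    SensorConfiguration.FOUR_MIMU: ["hand", "forearm_distal", "forearm_proximal", "humerus"],
    SensorConfiguration.THREE_MIMU_DISTAL: ["hand", "forearm_distal", "humerus"],
    SensorConfiguration.THREE_MIMU_PROXIMAL: ["hand", "forearm_proximal", "humerus"],
}
#: segment depth below the shoulder (humerus 0, forearm 1, hand 2)
_DEPTH = {"humerus": 0, "forearm_proximal": 1, "forearm_distal": 1, "hand": 2}


@dataclass
class SynthConfig:
    """Study conditions of a simulated finger-to-nose trial.

    Defaults mirror the recorded protocol: 30 s trials of 3 nose-knee cycles
    sampled at 100 Hz, voluntary content at the 0.1 Hz cycle fundamental and
    its low harmonics (well below 2 Hz), tremor at 5 Hz within the 3-12 Hz
    band.  Amplitude ratios along the chain are order-of-magnitude choices
    (amplification 1.8 per joint for voluntary motion, 2.5 per segment for
    tremor) exposed here because the true patient ratios are unknown.
    """

    configuration: SensorConfiguration = SensorConfiguration.THREE_MIMU_DISTAL
    trial_duration: float = 30.0
    n_cycles: int = 3
    sample_rate: float = 100.0
    tremor_freq: float = 5.0
    voluntary_amp: float = 0.4  # humerus angular-velocity scale, rad/s
    tremor_amp_distal: float = 1.0  # hand tremor amplitude, rad/s
    distal_gain_voluntary: float = 1.8
    distal_gain_tremor: float = 2.5
    forearm_gradient: float = 0.6
    noise_sd: float = 0.01  # rad/s
    ekf_lag_cutoff: float | None = None  # Hz; None disables the lag emulation
    seed: int = 0

    def __post_init__(self) -> None:
        self.configuration = SensorConfiguration(self.configuration)
        if not 3.0 <= self.tremor_freq <= 12.0:
            raise ValidationError("tremor_freq must lie in the 3-12 Hz tremor band")
        if self.cycle_freq >= 2.0:
            raise ValidationError(
                "voluntary cycle fundamental must stay below 2 Hz "
                f"(got {self.cycle_freq:.3g} Hz)"
            )
        if self.trial_duration <= 0 or self.sample_rate <= 0 or self.n_cycles < 1:
            raise ValidationError("duration, sample_rate and n_cycles must be positive")
        if self.distal_gain_voluntary <= 1.0 or self.distal_gain_tremor <= 1.0:
            raise ValidationError("distal gains must exceed 1")
        if not 0.0 <= self.forearm_gradient <= 1.0:
            raise ValidationError("forearm_gradient must lie in [0, 1]")
        if self.ekf_lag_cutoff is not None and not (
            0.0 < self.ekf_lag_cutoff < self.sample_rate / 2
        ):
            raise ValidationError("ekf_lag_cutoff must lie below the Nyquist frequency")

    @property
    def cycle_freq(self) -> float:
        """Fundamental of the finger-to-nose cycle, Hz."""
        return self.n_cycles / self.trial_duration


@dataclass
class GroundTruth:
    """Per-sensor constructed series and true chain positions.

    ``total = voluntary + tremor`` per sample by construction; ``gyro`` is
    the ideal co-located gyroscope channel (Poisson velocity of the lag-free
    orientation stream, i.e. including measurement noise and discretization).
    """

    timestamps: np.ndarray
    voluntary: dict[str, np.ndarray]
    tremor: dict[str, np.ndarray]
    total: dict[str, np.ndarray]
    gyro: dict[str, np.ndarray]
    orientation: dict[str, OrientationTrace]
    true_locations: dict[str, int]


class SimulatedTrial(NamedTuple):
    recording: TrialRecording
    truth: GroundTruth


def _joint_contributions(cfg: SynthConfig, t: np.ndarray) -> dict[str, np.ndarray]:
    """Smooth periodic angular-velocity contribution of each joint, (n, 3).

    Each joint moves about a distinct dominant axis with a distinct phase and
    a second harmonic, all below 2 Hz.  Amplitude grows along the chain:
    shoulder A0, elbow/pronosupination A0*gain, wrist A0*gain**2.
    """
    f0 = cfg.cycle_freq
    A0 = cfg.voluntary_amp
    gv = cfg.distal_gain_voluntary

    def wave(amp, axis_mix, phase, harmonic=0.3):
        base = np.sin(2 * np.pi * f0 * t + phase) + harmonic * np.sin(
            2 * np.pi * 2 * f0 * t + 1.7 * phase
        )
        return amp * np.outer(base, axis_mix / np.linalg.norm(axis_mix))

    # small phase offsets: joints lead/lag slightly but stay positively
    # correlated, as in a coordinated reach — large offsets would let a distal
    # joint cancel a proximal one and destroy the distal amplification
    return {
        # shoulder elevation: mostly about the global y axis
        "shoulder": wave(A0, np.array([0.2, 1.0, 0.15]), 0.0),
        # elbow flexion: mostly x
        "elbow": wave(A0 * gv, np.array([1.0, 0.25, 0.1]), 0.35),
        # forearm pronosupination: about the forearm long axis (z)
        "pronosupination": wave(A0 * gv, np.array([0.1, 0.15, 1.0]), 0.7),
        # wrist flexion/deviation: x/y mix
        "wrist": wave(A0 * gv**2, np.array([1.0, 0.5, 0.1]), 1.05),
    }


def _voluntary_chain(cfg: SynthConfig, t: np.ndarray, sites: list[str]) -> dict[str, np.ndarray]:
    c = _joint_contributions(cfg, t)
    chain = {
        "humerus": c["shoulder"],
        "forearm_proximal": c["shoulder"] + c["elbow"] + cfg.forearm_gradient * c["pronosupination"],
        "forearm_distal": c["shoulder"] + c["elbow"] + c["pronosupination"],
    }
    # the hand rides on the full forearm motion regardless of sensor subset
    chain["hand"] = chain["forearm_distal"] + c["wrist"]
    return {s: chain[s] for s in sites}


def _tremor_series(cfg: SynthConfig, t: np.ndarray, sites: list[str], rng) -> dict[str, np.ndarray]:
    """Amplitude-modulated kinetic tremor, synchronous across the chain."""
    if cfg.tremor_amp_distal == 0.0:
        return {s: np.zeros((t.size, 3)) for s in sites}
    envelope = 0.3 + 0.7 * 0.5 * (1.0 - np.cos(2 * np.pi * cfg.cycle_freq * t))
    phase = rng.uniform(0.0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * cfg.tremor_freq * t + phase)
    axis_mix = np.array([0.8, 0.45, 0.2])
    axis_mix = axis_mix / np.linalg.norm(axis_mix)
    base = np.outer(envelope * carrier, axis_mix)
    out = {}
    for s in sites:
        depth_below_hand = _DEPTH["hand"] - _DEPTH[s]
        amp = cfg.tremor_amp_distal / cfg.distal_gain_tremor**depth_below_hand
        out[s] = amp * base
    return out


def _lag_orientation(trace: OrientationTrace, cutoff_hz: float) -> OrientationTrace:
    """Causal first-order low-pass of the quaternion stream (fusion-lag emulation)."""
    q = trace.as_quaternions()
    b, a = sps.butter(1, cutoff_hz, btype="low", fs=trace.sample_rate)
    zi = sps.lfilter_zi(b, a)
    filtered = np.stack(
        [sps.lfilter(b, a, q[:, j], zi=zi * q[0, j])[0] for j in range(4)], axis=1
    )
    filtered /= np.linalg.norm(filtered, axis=1, keepdims=True)
    R = Rotation.from_quat(np.roll(filtered, -1, axis=1)).as_matrix()
    return OrientationTrace(trace.timestamps, R)


def simulate_trial(cfg: SynthConfig, trial_id: str | None = None) -> SimulatedTrial:
    """Generate one labelled trial with its ground-truth decomposition."""
    sites = _SITES[cfg.configuration]
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.trial_duration * cfg.sample_rate)) + 1
    t = np.arange(n) / cfg.sample_rate

    voluntary = _voluntary_chain(cfg, t, sites)
    tremor = _tremor_series(cfg, t, sites, rng)
    total = {s: voluntary[s] + tremor[s] for s in sites}

    sensors: dict[str, OrientationTrace] = {}
    gyro: dict[str, np.ndarray] = {}
    orientation_truth: dict[str, OrientationTrace] = {}
    for s in sites:
        measured = total[s] + rng.normal(0.0, cfg.noise_sd, size=(n, 3))
        # uniform random initial attitude per sensor
        q0 = rng.normal(size=4)
        R0 = Rotation.from_quat(q0 / np.linalg.norm(q0)).as_matrix()
        trace = integrate_angular_velocity(t, measured, R0=R0, frame=Frame.GLOBAL)
        orientation_truth[s] = trace
        gyro[s] = poisson_angular_velocity(trace).omega
        sensors[s] = _lag_orientation(trace, cfg.ekf_lag_cutoff) if cfg.ekf_lag_cutoff else trace

    true_locations = {s: i + 1 for i, s in enumerate(sites)}
    recording = TrialRecording(
        trial_id=trial_id or f"synth_{cfg.configuration.value}_seed{cfg.seed}",
        configuration=cfg.configuration,
        sensors=sensors,
        reference_order=list(sites),
        sample_rate=cfg.sample_rate,
        true_locations=true_locations,
    )
    truth = GroundTruth(
        timestamps=t,
        voluntary=voluntary,
        tremor=tremor,
        total=total,
        gyro=gyro,
        orientation=orientation_truth,
        true_locations=true_locations,
    )
    return SimulatedTrial(recording=recording, truth=truth)


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Write a ground-truth sidecar CSV (one block per sensor).

    Columns per block: t, voluntary/tremor/total/gyro x-y-z (rad/s).
    """
    from pathlib import Path

    lines = []
    order = sorted(truth.true_locations, key=truth.true_locations.get)
    lines.append("# true_locations=" + ",".join(f"{s}:{truth.true_locations[s]}" for s in order))
    cols = ["t"] + [f"{kind}_{ax}" for kind in ("vol", "tre", "tot", "gyro") for ax in "xyz"]
    for s in order:
        lines.append(f"# sensor={s}")
        lines.append(",".join(cols))
        data = np.column_stack(
            [truth.timestamps, truth.voluntary[s], truth.tremor[s], truth.total[s], truth.gyro[s]]
        )
        for row in data:
            lines.append(",".join(f"{x:.17g}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gyro_sidecar(path) -> dict[str, np.ndarray]:
    """Read only the gyroscope channels from a ground-truth sidecar file."""
    from pathlib import Path

    gyro: dict[str, list[list[float]]] = {}
    current = None
    skip_header = False
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("# sensor="):
            current = line.partition("=")[2].strip()
            gyro[current] = []
            skip_header = True
            continue
        if line.startswith("#"):
            continue
        if skip_header:
            skip_header = False
            continue
        if current is not None:
            gyro[current].append([float(x) for x in line.split(",")])
    return {s: np.asarray(rows)[:, 10:13] for s, rows in gyro.items()}


def make_fixture_suite(
    n_trials: int,
    template: SynthConfig | None = None,
    seed: int = 0,
    configurations: list[SensorConfiguration] | None = None,
    severity_range: tuple[float, float] = (0.02, 2.0),
) -> list[SimulatedTrial]:
    """A reproducible suite of trials spanning tremor severities.

    Tremor severity multipliers are spaced geometrically over
    ``severity_range`` (default 100x spread: nearly absent to severe) and
    shuffled; voluntary and tremor amplitudes additionally receive a +-30%
    per-trial jitter.  Configurations cycle through ``configurations``
    (default: all three layouts).  The same ``seed`` always yields the
    bitwise-identical suite.
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    template = template or SynthConfig()
    if configurations is None:
        configurations = list(_SITES)
    rng = np.random.default_rng(seed)
    severities = np.geomspace(severity_range[0], severity_range[1], n_trials)
    rng.shuffle(severities)
    suite: list[SimulatedTrial] = []
    for i in range(n_trials):
        jitter_v, jitter_t = rng.uniform(0.7, 1.3, size=2)
        cfg = replace(
            template,
            configuration=configurations[i % len(configurations)],
            voluntary_amp=template.voluntary_amp * jitter_v,
            tremor_amp_distal=template.tremor_amp_distal * severities[i] * jitter_t,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        suite.append(simulate_trial(cfg, trial_id=f"suite{seed}_trial{i:03d}"))
    return suite
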