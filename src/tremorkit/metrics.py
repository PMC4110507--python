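"""Kinematic tracking error and spectral summaries for tremor estimators.

The kinematic tracking error (KTE) compares a real-time tremor estimate with
the offline reference through the absolute per-sample error
``b_k = |estimate_k - reference_k|``:

    KTE = mean(b) + var(b)

The mean term gauges how quickly the tracker reacts to velocity changes; the
variance term (population variance, divide by N) gauges the smoothness of the
estimate.  Both are reported separately because the two real-time pipelines
differ almost entirely in the mean term: smoothing inside the sensor's
onboard orientation fusion delays the tremor content, which shows up as a
systematic tracking lag, not as roughness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import TrialRecording
from .kinematics import resample
from .tremor import GHFilterParams, gh_filter, joint_velocity_from_orientation, offline_reference

__all__ = ["KTEResult", "kte", "amplitude_spectrum", "compare_methods"]


@dataclass
class KTEResult:
    """Total KTE plus its mean (kte1) and variance (kte2) components."""

    kte: float
    kte1: float
    kte2: float
    n_samples: int


def kte(estimate: np.ndarray, reference: np.ndarray) -> KTEResult:
    """Kinematic tracking error of an estimate against a reference series."""
    est = np.asarray(estimate, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValidationError("estimate and reference must be equal-length 1-D series")
    if est.size < 2:
        raise ValidationError("KTE needs at least 2 samples")
    b = np.abs(est - ref)
    kte1 = float(np.mean(b))
    kte2 = float(np.var(b))  # population variance
    return KTEResult(kte=kte1 + kte2, kte1=kte1, kte2=kte2, n_samples=est.size)


def amplitude_spectrum(series: np.ndarray, rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Single-sided amplitude spectrum of a mean-removed series.

    A pure sinusoid of amplitude A shows a peak of height A at its frequency.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("series must be 1-D with at least 2 samples")
    x = x - np.mean(x)
    n = x.size
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    amp = np.abs(spectrum) / n
    amp[1:] *= 2.0
    if n % 2 == 0:
        amp[-1] /= 2.0  # Nyquist bin is not doubled
    return freqs, amp


def compare_methods(
    trial: TrialRecording,
    gyro: dict[str, np.ndarray],
    theta: float,
    joint: tuple[str, str] | None = None,
    upsample_rate_hz: float = 1000.0,
    offline_cutoff_hz: float = 2.0,
) -> pd.DataFrame:
    """Per-axis KTE of the orientation- and gyroscope-based tremor estimates.

    ``gyro`` maps sensor id to an (n, 3) angular-velocity series sampled on
    the trial's grid — the co-located gyroscope channel (available for
    synthetic trials, where it is the ground-truth measurement).  Both
    real-time estimates are scored against the offline reference computed
    from the gyroscope joint velocity; an ``offline`` row (the reference
    against itself, identically zero) anchors the table.

    Returns a tidy frame with columns method, axis, kte, kte1, kte2.
    """
    if joint is None:
        joint = (trial.reference_order[0], trial.reference_order[1])
    distal_id, proximal_id = joint
    for sid in joint:
        if sid not in gyro:
            raise ValidationError(f"gyro channel missing for sensor {sid!r}")
    t_src = trial.sensors[distal_id].timestamps
    joint_gyro = np.asarray(gyro[distal_id], float) - np.asarray(gyro[proximal_id], float)
    _, gyro_w = resample(t_src, joint_gyro, upsample_rate_hz)
    _, _, orient_w = joint_velocity_from_orientation(trial, joint, upsample_rate_hz)

    params = GHFilterParams(theta=theta, dt=1.0 / upsample_rate_hz)
    rows = []
    for i, axis in enumerate(("x", "y", "z")):
        ref = offline_reference(gyro_w[:, i], upsample_rate_hz, fc=offline_cutoff_hz).tremor
        for method, w in (("orientation", orient_w), ("gyroscope", gyro_w)):
            est = gh_filter(w[:, i], params).tremor
            res = kte(est, ref)
            rows.append(
                {"method": method, "axis": axis, "kte": res.kte, "kte1": res.kte1, "kte2": res.kte2}
            )
        res = kte(ref, ref)
        rows.append(
            {"method": "offline", "axis": axis, "kte": res.kte, "kte1": res.kte1, "kte2": res.kte2}
        )
    return pd.DataFrame(rows, columns=["method", "axis", "kte", "kte1", "kte2"])
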