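"""The 18 per-sensor motion features and the cross-sensor rank transform.

Each sensor's orientation stream is reduced to angular velocity (Poisson
extraction), angular displacement (trapezoidal integration) and angular
acceleration (central differences).  Every axis of every signal is rectified
(|x|, |y|, |z|) before statistics are taken, which makes the features
insensitive to how the sensor happens to be oriented on the segment; they
combine the axes symmetrically, so they are also invariant to axis
permutations.

Feature table (ids 1-18)
------------------------
================  ============  ========  ============
quantity          displacement  velocity  acceleration
================  ============  ========  ============
sum path length        1           --          --
sum max(|.|)           --           5           9
sum RMS per axis       2            6          10
RMS of 3-D norm        3            7          11
sum var per axis       4            8          12
sum cov eigenvalues   13           15          17
sum |PC1 loadings|    14           16          18
================  ============  ========  ============

Because the chain is additive — motion of proximal segments is carried along
by distal ones, and kinetic tremor is likewise amplified distally — the
magnitude-monotone features order sensors from hand to humerus.  Features are
therefore consumed as within-trial *ranks* (1 = largest), which makes the
downstream classifiers robust across tremor severities.

Variance here is always the population variance (divide by N); the same
convention is used by the tracking-error metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import TrialRecording
from .kinematics import (
    angular_acceleration,
    angular_displacement,
    poisson_angular_velocity,
)

__all__ = [
    "FEATURE_IDS",
    "HIGHLIGHTED_FEATURES",
    "FeatureVector",
    "RankMatrix",
    "features_from_signals",
    "compute_features",
    "rank_transform",
    "feature_table",
]

FEATURE_IDS: tuple[int, ...] = tuple(range(1, 19))

#: features that are individually sufficient to order the chain on the
#: finger-to-nose task (the magnitude-monotone subset)
HIGHLIGHTED_FEATURES: frozenset[int] = frozenset({1, 2, 3, 4, 5, 6, 7, 8, 13, 15})

logger = logging.getLogger(__name__)


@dataclass
class FeatureVector:
    """All 18 features for one sensor in one trial."""

    values: dict[int, float]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if sorted(self.values) != list(FEATURE_IDS):
            raise ValidationError("a FeatureVector must contain features 1..18")
        bad = {k: v for k, v in self.values.items() if not np.isfinite(v)}
        if bad:
            raise ValidationError(f"non-finite feature values: {bad}")

    def __getitem__(self, feature_id: int) -> float:
        return self.values[feature_id]


@dataclass
class RankMatrix:
    """Within-trial ranks per feature: 1 = largest value across sensors."""

    sensor_ids: list[str]
    ranks: dict[tuple[int, str], int]
    tied_features: set[int] = field(default_factory=set)

    def rank_of(self, feature_id: int, sensor_id: str) -> int:
        return self.ranks[(feature_id, sensor_id)]

    def order(self, feature_id: int) -> list[str]:
        """Sensor ids sorted by ascending rank (descending feature value)."""
        return sorted(self.sensor_ids, key=lambda s: self.ranks[(feature_id, s)])

    def to_frame(self) -> pd.DataFrame:
        data = {
            f"f{fid}": [self.ranks[(fid, s)] for s in self.sensor_ids]
            for fid in FEATURE_IDS
        }
        return pd.DataFrame(data, index=self.sensor_ids)


def _domain_stats(signal: np.ndarray) -> dict[str, float]:
    """Statistics of one rectified (n, 3) signal: the per-domain building blocks."""
    rect = np.abs(signal)
    cov = np.cov(rect.T, bias=True)
    eigvals, eigvecs = np.linalg.eigh(cov)
    pc1 = eigvecs[:, -1]  # eigh sorts ascending; last column = first PC
    return {
        "path_length": float(np.sum(np.abs(np.diff(rect, axis=0)))),
        "sum_max": float(np.sum(np.max(rect, axis=0))),
        "sum_rms": float(np.sum(np.sqrt(np.mean(rect**2, axis=0)))),
        "rms_norm": float(np.sqrt(np.mean(np.sum(rect**2, axis=1)))),
        "sum_var": float(np.sum(np.var(rect, axis=0))),
        "eig_sum": float(np.sum(eigvals)),
        "pc1_abs_sum": float(np.sum(np.abs(pc1))),
        "_trace": float(np.trace(cov)),
    }


def features_from_signals(
    displacement: np.ndarray, velocity: np.ndarray, acceleration: np.ndarray
) -> FeatureVector:
    """Assemble the 18 features from (n, 3) displacement/velocity/acceleration."""
    for name, sig in (
        ("displacement", displacement),
        ("velocity", velocity),
        ("acceleration", acceleration),
    ):
        sig = np.asarray(sig)
        if sig.ndim != 2 or sig.shape[1] != 3 or sig.shape[0] < 2:
            raise ValidationError(f"{name} must have shape (n >= 2, 3)")
    d = _domain_stats(np.asarray(displacement, float))
    v = _domain_stats(np.asarray(velocity, float))
    a = _domain_stats(np.asarray(acceleration, float))
    degenerate = any(s["_trace"] == 0.0 for s in (d, v, a))
    if degenerate:
        logger.warning(
            "degenerate (constant) signal: covariance features are 0 and the "
            "first-PC loadings fall back to the eigensolver tie-break"
        )
    values = {
        1: d["path_length"],
        2: d["sum_rms"],
        3: d["rms_norm"],
        4: d["sum_var"],
        5: v["sum_max"],
        6: v["sum_rms"],
        7: v["rms_norm"],
        8: v["sum_var"],
        9: a["sum_max"],
        10: a["sum_rms"],
        11: a["rms_norm"],
        12: a["sum_var"],
        13: d["eig_sum"],
        14: d["pc1_abs_sum"],
        15: v["eig_sum"],
        16: v["pc1_abs_sum"],
        17: a["eig_sum"],
        18: a["pc1_abs_sum"],
    }
    return FeatureVector(values=values, degenerate=degenerate)


def compute_features(trial: TrialRecording) -> dict[str, FeatureVector]:
    """Compute the 18 features for every sensor of a trial.

    Velocity comes from Poisson extraction of the orientation stream;
    displacement and acceleration are derived from that same velocity series
    so all three domains share one kinematic chain.
    """
    out: dict[str, FeatureVector] = {}
    for sid, trace in trial.sensors.items():
        av = poisson_angular_velocity(trace)
        disp = angular_displacement(av)
        acc = angular_acceleration(av)
        out[sid] = features_from_signals(disp, av.omega, acc)
    return out


def rank_transform(features: dict[str, FeatureVector]) -> RankMatrix:
    """Rank sensors within each feature, 1 = largest value.

    Ties are broken by sensor input order and flagged per feature.
    """
    if len(features) < 2:
        raise ValidationError("ranking needs at least 2 sensors")
    sensor_ids = list(features)
    ranks: dict[tuple[int, str], int] = {}
    tied: set[int] = set()
    for fid in FEATURE_IDS:
        vals = np.array([features[s][fid] for s in sensor_ids])
        if np.unique(vals).size < vals.size:
            tied.add(fid)
        order = np.argsort(-vals, kind="stable")
        for rank, idx in enumerate(order, start=1):
            ranks[(fid, sensor_ids[idx])] = rank
    return RankMatrix(sensor_ids=sensor_ids, ranks=ranks, tied_features=tied)


def feature_table(
    features: dict[str, FeatureVector], ranks: RankMatrix | None = None
) -> pd.DataFrame:
    """Tabulate raw feature values (and ranks) with one row per sensor."""
    if ranks is None:
        ranks = rank_transform(features)
    rows = {}
    for sid in features:
        row = {f"f{fid}": features[sid][fid] for fid in FEATURE_IDS}
        row.update({f"rank_f{fid}": ranks.rank_of(fid, sid) for fid in FEATURE_IDS})
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")
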