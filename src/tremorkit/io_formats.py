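"""Plain-text I/O for trial recordings, run configuration and result tables.

Trial dialect
-------------
A trial file is a CSV with ``#``-prefixed header lines followed by one block
per sensor::

    # trial_id=patient03_trial1
    # configuration=three_mimu_distal
    # reference_order=hand,forearm_distal,humerus
    # sample_rate=100.0
    # true_locations=hand:1,forearm_distal:2,humerus:3   (optional)
    # sensor=hand
    t,qw,qx,qy,qz
    0.00,1,0,0,0
    ...

Orientations are stored as scalar-first unit quaternions; a 9-column rotation
matrix block (``t,r11,...,r33``, row-major) is accepted as an alternative.
Timestamps are seconds; sampling must be uniform because all downstream
differentiation assumes a fixed period.  Angles are radians internally;
degrees are only a boundary concern and are handled by the config flag
``angles_in_degrees`` where Euler-angle tables are exported.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import yaml

from .errors import FormatError, ValidationError
from .kinematics import (
    ORTHONORMALITY_TOL,
    OrientationTrace,
    orthonormalize_rotations,
)

__all__ = [
    "SensorConfiguration",
    "TrialRecording",
    "GASettings",
    "RunConfig",
    "read_trial",
    "write_trial",
    "load_config",
    "DEFAULT_THETA_GYRO",
    "DEFAULT_THETA_ORIENTATION",
]

logger = logging.getLogger(__name__)

#: g-h smoothing parameter tuned on patient data for the gyroscope pipeline
DEFAULT_THETA_GYRO = 0.9952
#: g-h smoothing parameter tuned on patient data for the orientation pipeline
DEFAULT_THETA_ORIENTATION = 0.9958


class SensorConfiguration(str, Enum):
    """Which subset of the four chain sites carries a sensor.

    ``FOUR_MIMU`` is the full neuroprosthesis layout (hand, distal forearm,
    proximal forearm, humerus); the two three-sensor layouts keep one forearm
    sensor, placed distally or proximally.
    """

    FOUR_MIMU = "four_mimu"
    THREE_MIMU_DISTAL = "three_mimu_distal"
    THREE_MIMU_PROXIMAL = "three_mimu_proximal"

    @property
    def n_sensors(self) -> int:
        return 4 if self is SensorConfiguration.FOUR_MIMU else 3


@dataclass
class TrialRecording:
    """One recorded (or simulated) trial: per-sensor orientation streams.

    ``reference_order`` lists sensor ids from most distal to most proximal —
    the fixed placement order used as ground truth by the locator.
    ``true_locations`` optionally maps sensor id to its ordinal chain position
    (1 = hand); when present it must agree with ``reference_order``.
    """

    trial_id: str
    configuration: SensorConfiguration
    sensors: dict[str, OrientationTrace]
    reference_order: list[str]
    sample_rate: float
    true_locations: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.configuration = SensorConfiguration(self.configuration)
        if not self.sensors:
            raise ValidationError("a trial needs at least one sensor")
        if len(self.sensors) != self.configuration.n_sensors:
            raise ValidationError(
                f"configuration {self.configuration.value} requires "
                f"{self.configuration.n_sensors} sensors, got {len(self.sensors)}"
            )
        if sorted(self.reference_order) != sorted(self.sensors):
            raise ValidationError("reference_order must be a permutation of sensor ids")
        first = next(iter(self.sensors.values()))
        for sid, trace in self.sensors.items():
            if len(trace) != len(first) or not np.allclose(
                trace.timestamps, first.timestamps, atol=1e-9, rtol=0.0
            ):
                raise ValidationError(
                    f"sensor {sid!r} does not share timestamps with the others"
                )
        if abs(first.sample_rate - self.sample_rate) > 0.01 * self.sample_rate:
            raise ValidationError(
                f"declared sample_rate {self.sample_rate} Hz does not match the "
                f"trace spacing ({first.sample_rate:.6g} Hz)"
            )
        if self.true_locations is not None:
            if sorted(self.true_locations) != sorted(self.sensors):
                raise ValidationError("true_locations must cover exactly the sensor ids")
            expected = {sid: i + 1 for i, sid in enumerate(self.reference_order)}
            if self.true_locations != expected:
                raise ValidationError(
                    "true_locations disagrees with reference_order"
                )

    @property
    def sensor_ids(self) -> list[str]:
        return list(self.sensors)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.sensors.values())))

    @property
    def duration(self) -> float:
        t = next(iter(self.sensors.values())).timestamps
        return float(t[-1] - t[0])


@dataclass
class GASettings:
    """Genetic-algorithm settings for the scalar filter-parameter search."""

    population: int = 100
    crossover_rate: float = 0.8
    elite_count: int = 2
    max_generations: int = 50
    mutation_sigma_frac: float = 0.05
    stall_tol: float = 1e-6
    stall_generations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.crossover_rate <= 1:
            raise ValidationError("crossover_rate must be in (0, 1]")
        if not 0 <= self.elite_count < self.population:
            raise ValidationError("elite_count must be smaller than the population")
        if self.population < 2 or self.max_generations < 1:
            raise ValidationError("population >= 2 and max_generations >= 1 required")


@dataclass
class RunConfig:
    """Pipeline parameters with their shipped defaults.

    ``gh_theta`` defaults to the orientation-pipeline value; the gyroscope
    value is available as :data:`DEFAULT_THETA_GYRO`.
    """

    gh_theta: float = DEFAULT_THETA_ORIENTATION
    theta_bounds: tuple[float, float] = (0.8, 1.0)
    offline_cutoff_hz: float = 2.0
    upsample_rate_hz: float = 1000.0
    input_rate_hz: float = 100.0
    ga: GASettings = field(default_factory=GASettings)
    rng_seed: int = 0
    feature_selection: int | str = "all"
    angles_in_degrees: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.gh_theta <= 1.0:
            raise ValidationError(f"gh_theta must lie in [0, 1], got {self.gh_theta}")
        lo, hi = self.theta_bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValidationError("theta_bounds must satisfy 0 <= lo < hi <= 1")
        self.theta_bounds = (float(lo), float(hi))
        if self.offline_cutoff_hz <= 0:
            raise ValidationError("offline_cutoff_hz must be positive")
        if self.offline_cutoff_hz >= self.input_rate_hz / 2:
            raise ValidationError(
                f"offline_cutoff_hz ({self.offline_cutoff_hz} Hz) must be below the "
                f"Nyquist frequency of the input rate ({self.input_rate_hz / 2} Hz)"
            )
        if self.upsample_rate_hz < self.input_rate_hz:
            raise ValidationError("upsample_rate_hz must be >= input_rate_hz")
        if self.feature_selection != "all":
            f = int(self.feature_selection)
            if not 1 <= f <= 18:
                raise ValidationError("feature_selection must be 'all' or 1..18")
            self.feature_selection = f


# ---------------------------------------------------------------------------
# trial files
# ---------------------------------------------------------------------------

_QUAT_HEADER = ["t", "qw", "qx", "qy", "qz"]
_MATRIX_HEADER = ["t"] + [f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
_QUAT_NORM_TOL = 1e-3


def _parse_header_line(line: str) -> tuple[str, str]:
    body = line.lstrip("#").strip()
    if "=" not in body:
        raise FormatError(f"malformed header line: {line!r}")
    key, _, value = body.partition("=")
    return key.strip(), value.strip()


def read_trial(path: str | Path) -> TrialRecording:
    """Read a trial file in the documented CSV dialect.

    Quaternion rows are renormalized to unit length (rejecting norm deviations
    beyond 1e-3); rotation-matrix rows drifted beyond the orthonormality
    tolerance are re-orthonormalized with a logged warning, and rejected when
    the drift exceeds 1e-3.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    blocks: dict[str, list[list[float]]] = {}
    block_cols: dict[str, list[str]] = {}
    current: str | None = None
    expect_columns = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, value = _parse_header_line(line)
                if key == "sensor":
                    if value in blocks:
                        raise FormatError(f"duplicate sensor block {value!r}")
                    current = value
                    blocks[current] = []
                    expect_columns = True
                else:
                    meta[key] = value
                continue
            if current is None:
                raise FormatError(f"data row before any '# sensor=' block (line {lineno})")
            if expect_columns:
                cols = [c.strip() for c in line.split(",")]
                if cols not in (_QUAT_HEADER, _MATRIX_HEADER):
                    raise FormatError(
                        f"unrecognized column header for sensor {current!r}: {cols}"
                    )
                block_cols[current] = cols
                expect_columns = False
                continue
            try:
                row = [float(x) for x in line.split(",")]
            except ValueError as exc:
                raise FormatError(f"non-numeric data at line {lineno}") from exc
            if len(row) != len(block_cols[current]):
                raise FormatError(
                    f"row width {len(row)} does not match header at line {lineno}"
                )
            blocks[current].append(row)

    for key in ("trial_id", "configuration", "reference_order", "sample_rate"):
        if key not in meta:
            raise FormatError(f"missing required header '# {key}='")
    try:
        configuration = SensorConfiguration(meta["configuration"])
    except ValueError as exc:
        raise FormatError(f"unknown configuration {meta['configuration']!r}") from exc
    reference_order = [s.strip() for s in meta["reference_order"].split(",")]
    sample_rate = float(meta["sample_rate"])
    true_locations = None
    if "true_locations" in meta:
        true_locations = {}
        for item in meta["true_locations"].split(","):
            sid, _, pos = item.partition(":")
            true_locations[sid.strip()] = int(pos)

    sensors: dict[str, OrientationTrace] = {}
    for sid, rows in blocks.items():
        if not rows:
            raise FormatError(f"sensor block {sid!r} contains no data rows")
        data = np.asarray(rows, dtype=float)
        t = data[:, 0]
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"sensor {sid!r}: timestamps are not strictly increasing")
        if block_cols[sid] == _QUAT_HEADER:
            sensors[sid] = OrientationTrace.from_quaternions(
                t, data[:, 1:5], norm_tol=_QUAT_NORM_TOL
            )
        else:
            R = data[:, 1:10].reshape(-1, 3, 3)
            drift = np.max(np.abs(R.transpose(0, 2, 1) @ R - np.eye(3)))
            if drift > 1e-3:
                raise ValidationError(
                    f"sensor {sid!r}: rotation matrices deviate from orthonormality "
                    f"by {drift:.3g}"
                )
            if drift > ORTHONORMALITY_TOL:
                logger.warning(
                    "sensor %r: re-orthonormalizing rotations (drift %.3g)", sid, drift
                )
                R = orthonormalize_rotations(R)
            sensors[sid] = OrientationTrace(t, R)

    return TrialRecording(
        trial_id=meta["trial_id"],
        configuration=configuration,
        sensors=sensors,
        reference_order=reference_order,
        sample_rate=sample_rate,
        true_locations=true_locations,
    )


def write_trial(trial: TrialRecording, path: str | Path) -> None:
    """Write a trial in the documented dialect (quaternion blocks, 17 digits)."""
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# trial_id={trial.trial_id}\n")
    buf.write(f"# configuration={trial.configuration.value}\n")
    buf.write(f"# reference_order={','.join(trial.reference_order)}\n")
    buf.write(f"# sample_rate={trial.sample_rate!r}\n")
    if trial.true_locations is not None:
        items = ",".join(f"{sid}:{pos}" for sid, pos in trial.true_locations.items())
        buf.write(f"# true_locations={items}\n")
    for sid, trace in trial.sensors.items():
        buf.write(f"# sensor={sid}\n")
        buf.write(",".join(_QUAT_HEADER) + "\n")
        q = trace.as_quaternions()
        for t, row in zip(trace.timestamps, q):
            buf.write(
                f"{t:.17g},{row[0]:.17g},{row[1]:.17g},{row[2]:.17g},{row[3]:.17g}\n"
            )
    path.write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------

_GA_KEYS = {f.name for f in GASettings.__dataclass_fields__.values()}  # type: ignore[attr-defined]


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; missing keys take the shipped defaults."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise FormatError("config file must be a flat key-value mapping")
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    unknown = set(raw) - known - {"ga"}
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "theta_bounds" in kwargs:
        kwargs["theta_bounds"] = tuple(float(x) for x in kwargs["theta_bounds"])
    ga_raw = kwargs.pop("ga", {})
    if not isinstance(ga_raw, dict) or set(ga_raw) - _GA_KEYS:
        raise FormatError("'ga' must be a mapping with GASettings keys")
    kwargs["ga"] = GASettings(**ga_raw)
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise FormatError(str(exc)) from exc
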