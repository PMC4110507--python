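"""Separation of voluntary and tremulous movement with a g-h filter.

Voluntary upper-limb movement during activities of daily living lives below
2 Hz, while kinetic tremor occupies 3-12 Hz.  A g-h (alpha-beta) tracker tuned
as a heavy smoother follows the slow voluntary component and lags the tremor;
its one-step prediction x_{k+1,k} is therefore taken as the voluntary
estimate, and the residual

    tremor_k = y_k - x_{k+1,k}

as the tremor estimate.  The gains come from the critically damped
single-parameter family

    g = 1 - theta**2,      h = (1 - theta)**2,      theta in [0, 1],

so one scalar sets the bandwidth; theta near 1 smooths hard.  The residual
transfer function is (z - 1)**2 / (z - theta)**2 — a double zero at DC and a
double real pole at theta — which passes the tremor band nearly unchanged at
theta ~ 0.995 while rejecting the voluntary band.

The filter recursion (predict / innovate / update) is linear and
time-invariant, so it is evaluated exactly through its difference equation
with initial conditions matching x_hat_0 = y_0, v_hat_0 = 0; this is the same
arithmetic as the explicit state-space loop but runs vectorized.

``optimize_theta`` tunes theta by a genetic algorithm (population 100,
roulette selection, 80% arithmetic crossover, 2 elites, Gaussian mutation)
minimizing the summed kinematic tracking error of the g-h tremor estimate
against the offline reference — a zero-phase second-order low-pass at 2 Hz
applied to the joint angular velocity, the offline gold standard the filter
tries to match in real time.  The search is bounded to [0.8, 1]: smaller
theta would let too much tremor into the voluntary estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .io_formats import GASettings, TrialRecording
from .kinematics import (
    AngularVelocityTrace,
    joint_angular_velocity,
    poisson_angular_velocity,
    resample,
)

__all__ = [
    "GHFilterParams",
    "TremorDecomposition",
    "JointTremorEstimate",
    "GAResult",
    "gh_filter",
    "gh_tremor_response",
    "offline_reference",
    "joint_velocity_from_orientation",
    "estimate_tremor_from_orientation",
    "optimize_theta",
]


@dataclass
class GHFilterParams:
    """Critically damped g-h gains derived from one smoothing parameter."""

    theta: float
    dt: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValidationError(f"theta must lie in [0, 1], got {self.theta}")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")

    @property
    def g(self) -> float:
        return 1.0 - self.theta**2

    @property
    def h(self) -> float:
        return (1.0 - self.theta) ** 2


@dataclass
class TremorDecomposition:
    """One channel's decomposition: raw = voluntary + tremor, sample by sample."""

    timestamps: np.ndarray
    raw: np.ndarray
    voluntary: np.ndarray
    tremor: np.ndarray

    def __post_init__(self) -> None:
        n = self.timestamps.size
        for name in ("raw", "voluntary", "tremor"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValidationError(f"{name} must be 1-D with {n} samples")
            setattr(self, name, arr)
        if not np.allclose(self.raw, self.voluntary + self.tremor, atol=1e-9, rtol=0.0):
            raise ValidationError("decomposition must satisfy raw = voluntary + tremor")


def gh_filter(
    y: np.ndarray,
    params: GHFilterParams,
    timestamps: np.ndarray | None = None,
    output: str = "prediction",
) -> TremorDecomposition:
    """Run the g-h recursion on one uniformly sampled channel.

    The recursion is

        x_pred_k = x_hat_{k-1} + dt * v_hat_{k-1}
        r_k      = y_k - x_pred_k
        x_hat_k  = x_pred_k + g * r_k
        v_hat_k  = v_hat_{k-1} + (h / dt) * r_k

    initialized with ``x_hat_0 = y_0`` and ``v_hat_0 = 0``.  With
    ``output="prediction"`` (default) the voluntary series is the one-step
    prediction ``x_pred`` (``voluntary[0] = y[0]``); ``output="update"``
    returns the filtered update ``x_hat`` instead.

    Eliminating the state gives the exact residual difference equation

        e_k - 2 theta e_{k-1} + theta**2 e_{k-2} = y_k - 2 y_{k-1} + y_{k-2}

    with e_0 = 0 and e_1 = y_1 - y_0, which is evaluated with a direct-form
    IIR filter and initial conditions chosen to reproduce those starting
    values exactly.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValidationError("input must be a 1-D series with at least 2 samples")
    if output not in ("prediction", "update"):
        raise ValidationError("output must be 'prediction' or 'update'")
    theta = params.theta
    b = np.array([1.0, -2.0, 1.0])
    a = np.array([1.0, -2.0 * theta, theta**2])
    zi = np.array([-y[0], y[0]])
    residual, _ = sps.lfilter(b, a, y, zi=zi)
    if output == "prediction":
        voluntary = y - residual
    else:
        voluntary = y - (1.0 - params.g) * residual
    tremor = y - voluntary
    if timestamps is None:
        timestamps = np.arange(y.size) * params.dt
    return TremorDecomposition(
        timestamps=np.asarray(timestamps, dtype=float),
        raw=y,
        voluntary=voluntary,
        tremor=tremor,
    )


def gh_tremor_response(theta: float, freq_hz: float, rate_hz: float) -> float:
    """Magnitude of the tremor (residual) channel at one frequency.

    Evaluates |(z - 1)^2 / (z - theta)^2| at z = exp(2j pi f / fs): the
    steady-state gain from measurement to tremor estimate.
    """
    z = np.exp(2j * np.pi * freq_hz / rate_hz)
    return float(np.abs((z - 1.0) ** 2 / (z - theta) ** 2))


def offline_reference(
    y: np.ndarray,
    rate_hz: float,
    fc: float = 2.0,
    timestamps: np.ndarray | None = None,
) -> TremorDecomposition:
    """Offline gold-standard decomposition by recursive low-pass filtering.

    The voluntary estimate is a zero-phase (forward-backward) second-order
    Butterworth low-pass at ``fc``; the tremor estimate is the remainder.
    Zero-phase filtering is only possible offline, which is exactly why this
    serves as the reference rather than the real-time method.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValidationError("input must be a 1-D series with at least 2 samples")
    if not 0 < fc < rate_hz / 2:
        raise ValidationError(
            f"cutoff {fc} Hz must lie below the Nyquist frequency {rate_hz / 2} Hz"
        )
    sos = sps.butter(2, fc, btype="low", fs=rate_hz, output="sos")
    voluntary = sps.sosfiltfilt(sos, y)
    if timestamps is None:
        timestamps = np.arange(y.size) / rate_hz
    return TremorDecomposition(
        timestamps=np.asarray(timestamps, dtype=float),
        raw=y,
        voluntary=voluntary,
        tremor=y - voluntary,
    )


@dataclass
class JointTremorEstimate:
    """Per-axis tremor decompositions of one joint plus the norm channel."""

    joint: tuple[str, str]
    rate_hz: float
    axes: dict[str, TremorDecomposition]

    def axis(self, name: str) -> TremorDecomposition:
        return self.axes[name]


def joint_velocity_from_orientation(
    trial: TrialRecording,
    joint: tuple[str, str] | None = None,
    upsample_rate_hz: float = 1000.0,
) -> tuple[tuple[str, str], np.ndarray, np.ndarray]:
    """Joint angular velocity of a sensor pair, upsampled to the filter rate.

    ``joint`` is (distal sensor id, proximal sensor id); by default the two
    most distal sensors of the reference order — the wrist, where tremor is
    most pronounced.  Returns (joint, timestamps, (n, 3) velocity).
    """
    if joint is None:
        joint = (trial.reference_order[0], trial.reference_order[1])
    distal_id, proximal_id = joint
    for sid in joint:
        if sid not in trial.sensors:
            raise ValidationError(f"sensor {sid!r} not present in trial {trial.trial_id!r}")
    distal = poisson_angular_velocity(trial.sensors[distal_id])
    proximal = poisson_angular_velocity(trial.sensors[proximal_id])
    jv = joint_angular_velocity(distal, proximal)
    t, w = resample(jv.timestamps, jv.omega, upsample_rate_hz)
    return joint, t, w


def _decompose_axes(
    t: np.ndarray, w: np.ndarray, theta: float, rate_hz: float
) -> dict[str, TremorDecomposition]:
    params = GHFilterParams(theta=theta, dt=1.0 / rate_hz)
    axes = {
        name: gh_filter(w[:, i], params, timestamps=t)
        for i, name in enumerate(("x", "y", "z"))
    }
    axes["norm"] = gh_filter(np.linalg.norm(w, axis=1), params, timestamps=t)
    return axes


def estimate_tremor_from_orientation(
    trial: TrialRecording,
    theta: float,
    joint: tuple[str, str] | None = None,
    upsample_rate_hz: float = 1000.0,
) -> JointTremorEstimate:
    """Full orientation-to-tremor pipeline for one joint.

    Per sensor: Poisson angular-velocity extraction; then proximal-from-distal
    subtraction, upsampling to the filter rate, and a g-h decomposition per
    axis.  The norm channel filters the Euclidean norm of the joint velocity
    with the same parameters.
    """
    joint, t, w = joint_velocity_from_orientation(trial, joint, upsample_rate_hz)
    return JointTremorEstimate(
        joint=joint, rate_hz=upsample_rate_hz, axes=_decompose_axes(t, w, theta, upsample_rate_hz)
    )


# ---------------------------------------------------------------------------
# genetic-algorithm tuning of theta
# ---------------------------------------------------------------------------


@dataclass
class GAResult:
    """Outcome of the scalar GA search."""

    theta: float
    fitness: float
    history: list[float] = field(default_factory=list)  # per-generation best cost
    n_generations: int = 0


def _default_fitness(
    trials: Sequence[TrialRecording],
    upsample_rate_hz: float,
    offline_cutoff_hz: float,
    joint: tuple[str, str] | None,
) -> Callable[[float], float]:
    """Summed KTE of the g-h tremor estimate against the offline reference.

    The joint velocity and the offline reference do not depend on theta, so
    they are precomputed once per trial.
    """
    from .metrics import kte  # local import: metrics depends on this module

    prepared: list[tuple[np.ndarray, np.ndarray]] = []
    for trial in trials:
        _, _, w = joint_velocity_from_orientation(trial, joint, upsample_rate_hz)
        ref = np.stack(
            [
                offline_reference(w[:, i], upsample_rate_hz, fc=offline_cutoff_hz).tremor
                for i in range(3)
            ],
            axis=1,
        )
        prepared.append((w, ref))
    dt = 1.0 / upsample_rate_hz

    def fitness(theta: float) -> float:
        params = GHFilterParams(theta=theta, dt=dt)
        total = 0.0
        for w, ref in prepared:
            for i in range(3):
                est = gh_filter(w[:, i], params).tremor
                total += kte(est, ref[:, i]).kte
        return total

    return fitness


def optimize_theta(
    trials: Sequence[TrialRecording] | None,
    settings: GASettings | None = None,
    bounds: tuple[float, float] = (0.8, 1.0),
    fitness: Callable[[float], float] | None = None,
    upsample_rate_hz: float = 1000.0,
    offline_cutoff_hz: float = 2.0,
    joint: tuple[str, str] | None = None,
) -> GAResult:
    """Tune the g-h smoothing parameter with a real-coded genetic algorithm.

    Population initialized uniformly within ``bounds``; each generation keeps
    the ``elite_count`` best individuals unchanged, fills the rest by roulette
    selection on inverted cost followed by arithmetic crossover at the
    configured rate, and perturbs non-elites with bound-clipped Gaussian
    mutation (sigma = ``mutation_sigma_frac`` of the bound width).  Stops at
    ``max_generations`` or when the best cost has improved by less than
    ``stall_tol`` for ``stall_generations`` consecutive generations.

    A custom scalar ``fitness`` (cost, minimized) may replace the default
    summed-KTE objective, in which case ``trials`` may be ``None``.
    """
    settings = settings or GASettings()
    lo, hi = bounds
    if not (0.0 <= lo < hi <= 1.0):
        raise ValidationError("bounds must satisfy 0 <= lo < hi <= 1")
    if fitness is None:
        if not trials:
            raise ValidationError("optimize_theta needs trials or an explicit fitness")
        fitness = _default_fitness(list(trials), upsample_rate_hz, offline_cutoff_hz, joint)

    rng = np.random.default_rng(settings.seed)
    width = hi - lo
    sigma = settings.mutation_sigma_frac * width
    pop = rng.uniform(lo, hi, size=settings.population)
    best_theta = pop[0]
    best_cost = np.inf
    history: list[float] = []
    stall = 0
    gen = 0
    for gen in range(1, settings.max_generations + 1):
        costs = np.array([fitness(th) for th in pop])
        order = np.argsort(costs, kind="stable")
        gen_best_cost = float(costs[order[0]])
        improvement = best_cost - gen_best_cost
        if gen_best_cost < best_cost:
            best_cost = gen_best_cost
            best_theta = float(pop[order[0]])
        history.append(best_cost)
        stall = stall + 1 if improvement < settings.stall_tol else 0
        if stall >= settings.stall_generations:
            break
        elites = pop[order[: settings.elite_count]].copy()
        # roulette on inverted cost: weight by distance below the worst
        inv = costs.max() - costs
        weights = inv / inv.sum() if inv.sum() > 0 else np.full(pop.size, 1.0 / pop.size)
        n_children = settings.population - settings.elite_count
        parents = rng.choice(pop, size=2 * n_children, p=weights)
        children = np.empty(n_children)
        for i in range(n_children):
            p1, p2 = parents[2 * i], parents[2 * i + 1]
            if rng.random() < settings.crossover_rate:
                u = rng.random()
                children[i] = u * p1 + (1.0 - u) * p2
            else:
                children[i] = p1
        children = np.clip(children + rng.normal(0.0, sigma, size=n_children), lo, hi)
        pop = np.concatenate([elites, children])
    return GAResult(
        theta=best_theta, fitness=best_cost, history=history, n_generations=gen
    )
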