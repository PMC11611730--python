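"""Trajectory-to-statistics pipeline for rolling-adhesion data.

The same procedure is applied to simulated, synthetic and experimental
displacement traces:

1. convert the imposed volumetric flow rate to a wall shear rate
   (gdot = 6 Q / (h^2 w), valid for a wide rectangular channel under
   Poiseuille flow);
2. linearly interpolate the (possibly unevenly sampled) displacement onto a
   uniform time grid (default step 0.01 s for event-driven simulation
   output);
3. differentiate and Savitzky--Golay-smooth to an instantaneous velocity;
4. split into stop and roll regimes with a velocity threshold
   (default 0.5 um/s);
5. aggregate per-particle and ensemble statistics: the fraction of rolling
   particles f_roll (net displacement > 1 um), the duration-weighted rolling
   velocity v_roll, the mean stop duration t_stop, and the overall velocity.

Filtering rules: trajectories shorter than 30 frames are dropped, and a
dataset retaining fewer than 30 particles is flagged invalid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "ChannelGeometry",
    "UniformTrajectory",
    "RegimeSegmentation",
    "RollingStats",
    "shear_rate_from_flow",
    "interpolate",
    "instantaneous_velocity",
    "segment",
    "rolling_stats",
    "analyze_trajectories",
]

#: analysis defaults (velocity threshold um/s; filtering rules)
VELOCITY_THRESHOLD = 0.5
MIN_FRAMES = 30
MIN_PARTICLES = 30
MIN_ROLL_DISPLACEMENT = 1.0
SG_WINDOW = 11
SG_POLYORDER = 2


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular microfluidic channel cross-section and imposed flow.

    ``height``/``width`` in um, ``flow_rate`` in ul/min.  The shear-rate
    formula assumes w >> h (wide-channel Poiseuille flow); the default
    geometry is a 1,500 um x 50 um channel.
    """

    height: float = 50.0
    width: float = 1500.0
    flow_rate: float = 21.0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("channel dimensions must be positive")


def shear_rate_from_flow(geom: ChannelGeometry) -> float:
    """Wall shear rate gdot = 6 Q / (h^2 w), in 1/s.

    Q is converted from ul/min to m^3/s and the dimensions from um to m.
    Linear in Q.
    """
    q = geom.flow_rate * 1e-9 / 60.0  # ul/min -> m^3/s
    h = geom.height * 1e-6
    w = geom.width * 1e-6
    return 6.0 * q / (h * h * w)


@dataclass
class UniformTrajectory:
    """Positions on a uniform time grid.

    ``source`` records provenance (simulated / experimental / synthetic);
    experimental and synthetic data carry the camera frame clock as ``dt``.
    """

    start_time: float
    dt: float
    positions: np.ndarray
    source: str = "simulated"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.positions.size < 2:
            raise ValueError("a trajectory needs at least 2 samples")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.dt * np.arange(self.positions.size)

    @property
    def n_frames(self) -> int:
        return int(self.positions.size)

    @property
    def duration(self) -> float:
        return self.dt * (self.positions.size - 1)

    @property
    def net_displacement(self) -> float:
        return abs(float(self.positions[-1] - self.positions[0]))


def interpolate(
    times: Sequence[float],
    positions: Sequence[float],
    dt: float = 0.01,
    source: str = "simulated",
) -> UniformTrajectory:
    """Piecewise-linear resampling of an event-timestamped trace.

    The uniform grid starts at the first timestamp and covers
    ``floor((t_end - t_0)/dt)`` whole steps; when the span is an integer
    multiple of ``dt`` both endpoints are reproduced exactly, otherwise the
    sub-step tail is dropped.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(positions, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two samples to interpolate")
    if np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be non-decreasing")
    if not dt > 0:
        raise ValueError("dt must be positive")
    span = t[-1] - t[0]
    n = int(math.floor(span / dt + 1e-9)) + 1
    if n < 2:
        raise ValueError("trajectory shorter than one interpolation step")
    grid = t[0] + dt * np.arange(n)
    pos = np.interp(grid, t, x)
    return UniformTrajectory(start_time=float(t[0]), dt=dt, positions=pos, source=source)


def instantaneous_velocity(
    traj: UniformTrajectory,
    window: int = SG_WINDOW,
    polyorder: int = SG_POLYORDER,
) -> np.ndarray:
    """Finite-difference velocity with Savitzky--Golay smoothing (um/s).

    Central differences (one-sided at the edges) followed by an SG filter of
    the given window and polynomial order; ``window=1`` disables smoothing.
    The returned series has the same length as the trajectory; the filter's
    edge samples are completed by polynomial extrapolation (SciPy ``interp``
    mode), which is exact for signals of degree <= ``polyorder``.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window >= traj.positions.size:
        raise ValueError("smoothing window must be shorter than the series")
    v = np.gradient(traj.positions, traj.dt)
    if window > 1:
        if window <= polyorder:
            raise ValueError("window must exceed polyorder")
        v = savgol_filter(v, window, polyorder, mode="interp")
    return v


@dataclass(frozen=True)
class Interval:
    t_start: float
    t_end: float
    kind: str  # "roll" | "stop"

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class RegimeSegmentation:
    """Contiguous, alternating stop/roll intervals covering a trajectory.

    Each velocity sample owns the interval [t, t + dt); intervals are maximal
    runs of same-regime samples, so the segmentation partitions
    [t0, t0 + n*dt) exactly.
    """

    intervals: list[Interval]
    threshold: float

    def durations(self, kind: str) -> np.ndarray:
        return np.array([iv.duration for iv in self.intervals if iv.kind == kind])

    def total_time(self, kind: str) -> float:
        return float(self.durations(kind).sum()) if self.intervals else 0.0

    @property
    def n_alternations(self) -> int:
        """Number of regime switches (len(intervals) - 1)."""
        return max(0, len(self.intervals) - 1)


def segment(
    velocity: np.ndarray,
    threshold: float = VELOCITY_THRESHOLD,
    t0: float = 0.0,
    dt: float = 0.01,
) -> RegimeSegmentation:
    """Split a velocity series into stop (|v| < thr) and roll (|v| >= thr).

    Runs of equal classification are merged into maximal intervals with exact
    sample-boundary bookkeeping.
    """
    v = np.asarray(velocity, dtype=float)
    if v.size == 0:
        raise ValueError("empty velocity series")
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    rolling = np.abs(v) >= threshold
    edges = np.flatnonzero(np.diff(rolling.astype(np.int8))) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [v.size]])
    intervals = [
        Interval(
            t_start=t0 + dt * int(s),
            t_end=t0 + dt * int(e),
            kind="roll" if rolling[s] else "stop",
        )
        for s, e in zip(starts, ends)
    ]
    return RegimeSegmentation(intervals=intervals, threshold=threshold)


@dataclass
class RollingStats:
    """Ensemble stop/roll statistics.

    All means/sds are across particles except ``t_stop``, which pools stop
    intervals from all retained particles.  ``valid`` is False when fewer
    than ``min_particles`` trajectories survive the frame filter.
    """

    f_roll: float
    v_roll_mean: float
    v_roll_sd: float
    t_stop_mean: float
    t_stop_sd: float
    overall_velocity_mean: float
    overall_velocity_sd: float
    n_particles: int
    n_rolling: int
    n_excluded_short: int
    n_stop_intervals: int
    mean_alternations: float
    valid: bool
    exclusions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "f_roll": self.f_roll,
            "v_roll_mean": self.v_roll_mean,
            "v_roll_sd": self.v_roll_sd,
            "t_stop_mean": self.t_stop_mean,
            "t_stop_sd": self.t_stop_sd,
            "overall_velocity_mean": self.overall_velocity_mean,
            "overall_velocity_sd": self.overall_velocity_sd,
            "n_particles": self.n_particles,
            "n_rolling": self.n_rolling,
            "n_excluded_short": self.n_excluded_short,
            "n_stop_intervals": self.n_stop_intervals,
            "mean_alternations": self.mean_alternations,
            "valid": self.valid,
            "exclusions": self.exclusions,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _nanstats(values: list[float]) -> tuple[float, float]:
    arr = np.array([v for v in values if not math.isnan(v)])
    if arr.size == 0:
        return math.nan, math.nan
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def rolling_stats(
    trajectories: Iterable[UniformTrajectory],
    segmentations: Iterable[RegimeSegmentation] | None = None,
    velocities: Iterable[np.ndarray] | None = None,
    min_frames: int = MIN_FRAMES,
    min_particles: int = MIN_PARTICLES,
    min_displacement: float = MIN_ROLL_DISPLACEMENT,
    threshold: float = VELOCITY_THRESHOLD,
    window: int = SG_WINDOW,
    polyorder: int = SG_POLYORDER,
) -> RollingStats:
    """Ensemble statistics from uniform trajectories.

    When ``segmentations``/``velocities`` are omitted they are computed with
    the defaults.  Rules:

    - trajectories with fewer than ``min_frames`` samples are excluded from
      every statistic;
    - f_roll = fraction of retained particles whose net displacement exceeds
      ``min_displacement`` (um);
    - v_roll per particle = duration-weighted mean velocity over its rolling
      intervals (particles with no rolling interval contribute no v_roll);
    - t_stop pools interior stop-interval durations over retained particles;
      dwells truncated by the start or end of a trajectory are censored and
      only used when no interior stop dwell exists at all;
    - overall velocity per particle = net displacement / total duration;
    - the result is flagged invalid when fewer than ``min_particles``
      particles are retained.
    """
    trajs = list(trajectories)
    if segmentations is None or velocities is None:
        velocities = []
        segmentations = []
        for tr in trajs:
            if tr.n_frames < min_frames:
                velocities.append(None)
                segmentations.append(None)
                continue
            w = min(window, tr.n_frames - 1)
            if w % 2 == 0:
                w -= 1
            v = instantaneous_velocity(tr, window=max(w, 1), polyorder=polyorder)
            velocities.append(v)
            segmentations.append(
                segment(v, threshold=threshold, t0=tr.start_time, dt=tr.dt)
            )
    else:
        segmentations = list(segmentations)
        velocities = list(velocities)

    retained: list[int] = []
    excluded_short = 0
    for i, tr in enumerate(trajs):
        if tr.n_frames < min_frames:
            excluded_short += 1
        else:
            retained.append(i)

    if not retained:
        raise ValueError("no trajectories retained after the frame filter")

    n_rolling = 0
    v_rolls: list[float] = []
    overall: list[float] = []
    stop_durations: list[float] = []
    censored_stops: list[float] = []
    alternations: list[int] = []
    for i in retained:
        tr = trajs[i]
        seg = segmentations[i]
        v = velocities[i]
        if tr.net_displacement > min_displacement:
            n_rolling += 1
        t_roll = 0.0
        vdt_roll = 0.0
        first, last = seg.intervals[0], seg.intervals[-1]
        for iv in seg.intervals:
            if iv.kind == "roll":
                j0 = int(round((iv.t_start - tr.start_time) / tr.dt))
                j1 = int(round((iv.t_end - tr.start_time) / tr.dt))
                vdt_roll += float(np.abs(v[j0:j1]).sum()) * tr.dt
                t_roll += iv.duration
            elif iv is first or iv is last:
                # dwell truncated by the observation window: biased low
                censored_stops.append(iv.duration)
            else:
                stop_durations.append(iv.duration)
        if t_roll > 0:
            v_rolls.append(vdt_roll / t_roll)
        overall.append(tr.net_displacement / tr.duration)
        alternations.append(seg.n_alternations)
    if not stop_durations:
        # no interior stop dwell anywhere (e.g. fully arrested particles):
        # fall back to the censored ones rather than report nothing
        stop_durations = censored_stops

    v_mean, v_sd = _nanstats(v_rolls)
    o_mean, o_sd = _nanstats(overall)
    if stop_durations:
        t_mean, t_sd = _nanstats(stop_durations)
    else:
        t_mean, t_sd = 0.0, 0.0

    n = len(retained)
    return RollingStats(
        f_roll=n_rolling / n,
        v_roll_mean=v_mean,
        v_roll_sd=v_sd,
        t_stop_mean=t_mean,
        t_stop_sd=t_sd,
        overall_velocity_mean=o_mean,
        overall_velocity_sd=o_sd,
        n_particles=n,
        n_rolling=n_rolling,
        n_excluded_short=excluded_short,
        n_stop_intervals=len(stop_durations),
        mean_alternations=float(np.mean(alternations)) if alternations else 0.0,
        valid=n >= min_particles,
        exclusions={
            "short_trajectories": excluded_short,
            "min_frames": min_frames,
            "min_particles": min_particles,
        },
    )


def analyze_trajectories(
    raw: Iterable[tuple[np.ndarray, np.ndarray]],
    dt: float = 0.01,
    source: str = "simulated",
    **kwargs,
) -> RollingStats:
    """Full pipeline from event-timestamped (times, positions) pairs."""
    trajs = [interpolate(t, x, dt=dt, source=source) for t, x in raw]
    return rolling_stats(trajs, **kwargs)
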