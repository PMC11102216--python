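"""Trajectory-level kinematic primitives shared by all tasks.

The workspace is the horizontal plane of the exoskeleton: x points to the
participant's right, y away from the body, units are metres, and the
participant's midline is the line x = 0.  Mirror-matching between arms is
the reflection x -> -x.

Reach directions are reported in degrees.  For rotated-cursor reaching the
signed initial direction is measured relative to the straight start->target
line with the *compensatory* direction positive: a 30 deg counter-clockwise
cursor rotation is countered by reaching clockwise of the target line, so a
fully adapted reach scores +30 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, NoOnsetError, TruncatedTrialError

__all__ = [
    "Trajectory",
    "speed_profile",
    "velocity_profile",
    "peak_speed",
    "path_length",
    "mirror_x",
    "detect_onset",
    "direction_at_latency",
    "direction_at_peak_speed",
    "wrap_angle_deg",
]

_UNIFORMITY_TOL = 1e-9


@dataclass(frozen=True)
class Trajectory:
    """A uniformly sampled planar hand path.

    Parameters
    ----------
    t : array-like
        Sample times in seconds, strictly increasing with a uniform step.
    x, y : array-like
        Hand position in metres, same length as ``t`` (>= 3 samples).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.ndim == x.ndim == y.ndim == 1):
            raise InvalidArgumentError("t, x, y must be one-dimensional")
        if not (t.size == x.size == y.size):
            raise InvalidArgumentError("t, x, y must have equal length")
        if t.size < 3:
            raise InvalidArgumentError("a trajectory needs at least 3 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise InvalidArgumentError("trajectory samples must be finite")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise InvalidArgumentError("t must be strictly increasing")
        if np.ptp(dt) > _UNIFORMITY_TOL:
            raise InvalidArgumentError("t must be uniformly sampled (within 1e-9 s)")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def position_at(self, time: float) -> np.ndarray:
        """Linearly interpolated (x, y) at ``time`` (must lie in the span)."""
        if time < self.t[0] or time > self.t[-1]:
            raise TruncatedTrialError(
                f"time {time:.4f} s outside trajectory span [{self.t[0]:.4f}, {self.t[-1]:.4f}]"
            )
        return np.array([np.interp(time, self.t, self.x), np.interp(time, self.t, self.y)])


def velocity_profile(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (vx, vy) by central differences; one-sided at the endpoints."""
    vx = np.gradient(traj.x, traj.dt)
    vy = np.gradient(traj.y, traj.dt)
    return vx, vy


def speed_profile(traj: Trajectory) -> np.ndarray:
    """Per-sample hand speed in m/s (magnitude of the velocity)."""
    vx, vy = velocity_profile(traj)
    return np.hypot(vx, vy)


def peak_speed(traj: Trajectory) -> float:
    return float(np.max(speed_profile(traj)))


def path_length(traj: Trajectory) -> float:
    """Total travelled distance: the sum of inter-sample segment lengths."""
    return float(np.sum(np.hypot(np.diff(traj.x), np.diff(traj.y))))


def mirror_x(obj, midline_x: float = 0.0):
    """Reflect a point, an (n, 2) array of points, or a Trajectory about x = midline.

    The reflection is x -> 2*midline - x; y is untouched.  It is an involution.
    """
    if isinstance(obj, Trajectory):
        return Trajectory(t=obj.t, x=2.0 * midline_x - obj.x, y=obj.y.copy())
    arr = np.asarray(obj, dtype=float)
    out = arr.copy()
    out[..., 0] = 2.0 * midline_x - arr[..., 0]
    return out


def detect_onset(traj: Trajectory, fraction: float = 0.125, axis: str = "speed") -> float:
    """Movement onset: first sample whose velocity strictly exceeds ``fraction`` of its peak.

    ``axis='forward_y'`` uses the forward (+y, toward-target) velocity
    component, the convention used for rotated-cursor reaching; ``'speed'``
    uses the speed magnitude, appropriate for the matching tasks where
    movement direction varies.  No interpolation: onset is an index-like
    event, returned at the sample time.
    """
    if not 0.0 <= fraction < 1.0:
        raise InvalidArgumentError("fraction must be in [0, 1)")
    if axis == "forward_y":
        signal = velocity_profile(traj)[1]
    elif axis == "speed":
        signal = speed_profile(traj)
    else:
        raise InvalidArgumentError(f"unknown onset axis {axis!r}")
    peak = float(np.max(signal))
    if peak <= 0.0:
        raise NoOnsetError("no positive velocity: onset undefined")
    above = np.nonzero(signal > fraction * peak)[0]
    if above.size == 0:  # unreachable for fraction < 1, kept as a guard
        raise NoOnsetError("velocity never exceeded the onset threshold")
    return float(traj.t[above[0]])


def wrap_angle_deg(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle (deg) into (-180, 180]."""
    wrapped = -((-np.asarray(angle) + 180.0) % 360.0 - 180.0)
    return float(wrapped) if np.isscalar(angle) else wrapped


def _signed_direction(vec: np.ndarray, reference: np.ndarray) -> float:
    """Signed angle (deg) from ``vec`` to ``reference``; clockwise-of-reference positive."""
    ang_vec = np.degrees(np.arctan2(vec[1], vec[0]))
    ang_ref = np.degrees(np.arctan2(reference[1], reference[0]))
    return float(wrap_angle_deg(ang_ref - ang_vec))


def direction_at_latency(
    traj: Trajectory,
    onset: float,
    origin,
    target,
    latency: float = 0.150,
) -> float:
    """Signed initial reach direction (deg) probed ``latency`` s after onset.

    The hand position is linearly interpolated at ``onset + latency``; the
    returned angle is between the origin->position vector and the
    origin->target line, positive when the reach deviates clockwise of the
    target line (the direction that compensates a counter-clockwise cursor
    rotation).
    """
    if latency < 0:
        raise InvalidArgumentError("latency must be non-negative")
    origin = np.asarray(origin, dtype=float)
    target = np.asarray(target, dtype=float)
    pos = traj.position_at(onset + latency)
    vec = pos - origin
    ref = target - origin
    if np.allclose(vec, 0.0) or np.allclose(ref, 0.0):
        raise NoOnsetError("zero-length vector: direction undefined")
    return _signed_direction(vec, ref)


def direction_at_peak_speed(traj: Trajectory) -> float:
    """Absolute movement direction (deg, atan2 convention) at the sample of peak speed."""
    vx, vy = velocity_profile(traj)
    speed = np.hypot(vx, vy)
    i = int(np.argmax(speed))
    if speed[i] <= 0.0:
        raise NoOnsetError("no motion: direction undefined")
    return float(np.degrees(np.arctan2(vy[i], vx[i])))
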