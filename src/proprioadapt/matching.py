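"""Per-participant proprioception metrics for the matching tasks.

APM (position matching) variables, computed on matched positions that have
already been mirrored into the passive arm's frame:

* AE   — mean absolute matching error per direction, combined by
         root-sum-square (general matching accuracy),
* Var  — mean per-target SD of the matched position across repetitions
         (trial-to-trial consistency),
* Area — convex-hull area of the nine per-target mean matched positions
         over the hull of the nine targets (workspace contraction/expansion;
         1 is ideal),
* Shift — mean matched minus mean target position (systematic workspace
         translation; 0 is ideal).

AMM (movement matching) variables, per non-failed trial and averaged:

* RL  — response latency: active minus passive movement-onset time,
* PSR — active/passive peak-speed ratio,
* IDE — absolute angular difference of the movement directions at peak
        speed, wrapped to [0, 180] deg,
* PLR — active/passive path-length ratio,

plus the count of failed trials.  A trial fails when no onset can be
detected in the active trace or the active path is shorter than 25% of the
passive path (the protocol itself does not define failure; this criterion
is a package decision, documented in the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .errors import IncompleteProtocolError, NoOnsetError, UndefinedMetricsError
from .kinematics import (
    Trajectory,
    detect_onset,
    direction_at_peak_speed,
    path_length,
    peak_speed,
    wrap_angle_deg,
)

__all__ = [
    "APMMetrics",
    "AMMMetrics",
    "compute_apm",
    "compute_amm",
    "flag_failed_trial",
    "FAILED_PATH_FRACTION",
]

FAILED_PATH_FRACTION = 0.25   # active path < 25% of passive path => failed trial
ONSET_FRACTION = 0.125        # onset threshold as a fraction of peak velocity


@dataclass(frozen=True)
class APMMetrics:
    ae_x: float
    ae_y: float
    ae_xy: float
    var_x: float
    var_y: float
    var_xy: float
    area_xy: float
    shift_x: float
    shift_y: float
    shift_xy: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class AMMMetrics:
    rl: float
    psr: float
    ide: float
    plr: float
    n_failed: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _hull_area(points: np.ndarray) -> float:
    return float(ConvexHull(points).volume)  # 2-D "volume" is the area


def compute_apm(targets: np.ndarray, matched: np.ndarray) -> APMMetrics:
    """APM metrics from per-trial target and matched positions (passive frame).

    ``targets``/``matched`` are (n_trials, 2); every unique target must occur
    with the same number of repetitions (>= 2) and there must be at least 3
    non-collinear unique targets so workspace areas are defined.
    """
    targets = np.asarray(targets, dtype=float)
    matched = np.asarray(matched, dtype=float)
    if targets.shape != matched.shape or targets.ndim != 2 or targets.shape[1] != 2:
        raise IncompleteProtocolError("targets and matched must both be (n_trials, 2)")

    uniq, inverse, counts = np.unique(
        targets, axis=0, return_inverse=True, return_counts=True
    )
    if uniq.shape[0] < 3:
        raise IncompleteProtocolError("need at least 3 distinct target positions")
    if counts.min() < 2 or counts.max() != counts.min():
        raise IncompleteProtocolError(
            "every target needs the same number of repetitions (>= 2)"
        )

    err = matched - targets
    ae_x = float(np.mean(np.abs(err[:, 0])))
    ae_y = float(np.mean(np.abs(err[:, 1])))

    per_target_sd = np.empty((uniq.shape[0], 2))
    per_target_mean = np.empty((uniq.shape[0], 2))
    for k in range(uniq.shape[0]):
        sel = matched[inverse == k]
        per_target_sd[k] = sel.std(axis=0, ddof=1)
        per_target_mean[k] = sel.mean(axis=0)
    var_x = float(per_target_sd[:, 0].mean())
    var_y = float(per_target_sd[:, 1].mean())

    area_xy = _hull_area(per_target_mean) / _hull_area(uniq)
    shift = matched.mean(axis=0) - targets.mean(axis=0)

    return APMMetrics(
        ae_x=ae_x,
        ae_y=ae_y,
        ae_xy=float(np.hypot(ae_x, ae_y)),
        var_x=var_x,
        var_y=var_y,
        var_xy=float(np.hypot(var_x, var_y)),
        area_xy=float(area_xy),
        shift_x=float(shift[0]),
        shift_y=float(shift[1]),
        shift_xy=float(np.hypot(shift[0], shift[1])),
    )


def flag_failed_trial(active: Trajectory, passive: Trajectory) -> bool:
    """True when the active response is absent or covers < 25% of the passive path."""
    try:
        detect_onset(active, fraction=ONSET_FRACTION, axis="speed")
    except NoOnsetError:
        return True
    return path_length(active) < FAILED_PATH_FRACTION * path_length(passive)


def compute_amm(trials) -> AMMMetrics:
    """AMM metrics from (passive, active, failed) trial tuples (passive frame).

    Active trajectories must already be mirrored into the passive arm's
    frame.  Trials flagged failed on input, or detected as failed by
    :func:`flag_failed_trial`, are excluded from the averages and counted.
    """
    rl, psr, ide, plr = [], [], [], []
    n_failed = 0
    for passive, active, failed in trials:
        if failed or flag_failed_trial(active, passive):
            n_failed += 1
            continue
        onset_p = detect_onset(passive, fraction=ONSET_FRACTION, axis="speed")
        onset_a = detect_onset(active, fraction=ONSET_FRACTION, axis="speed")
        rl.append(onset_a - onset_p)
        psr.append(peak_speed(active) / peak_speed(passive))
        d = wrap_angle_deg(direction_at_peak_speed(active) - direction_at_peak_speed(passive))
        ide.append(abs(d))
        plr.append(path_length(active) / path_length(passive))
    if not rl:
        raise UndefinedMetricsError("all trials failed: AMM metrics undefined")
    return AMMMetrics(
        rl=float(np.mean(rl)),
        psr=float(np.mean(psr)),
        ide=float(np.mean(ide)),
        plr=float(np.mean(plr)),
        n_failed=int(n_failed),
    )
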