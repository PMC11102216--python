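"""Visuomotor-rotation session summaries and adaptation-impairment classification.

A session is a fixed 25 baseline / 125 adaptation / 25 washout sequence of
initial reach directions (compensatory degrees; +30 = full compensation of
the 30 deg counter-clockwise cursor rotation).  Summary measures:

* baseline mean/SD over the 25 baseline trials,
* Initial Adaptation  = mean direction over adaptation trials 1-15,
* Final Adaptation    = mean direction over adaptation trials 111-125,
* Trials to Adapt     = first adaptation trial starting a run of 15
  consecutive trials strictly above a control-derived threshold (the lower
  bound of the controls' 95% range of Final Adaptation); 125 when the
  criterion is never met.

Impairment on each measure is judged against the empirical 95% range
(2.5th-97.5th percentiles, linear-interpolation quantiles) of control data:
Initial/Final Adaptation below the lower bound, Trials to Adapt above the
upper bound; a participant is adaptation-impaired if at least one measure
is flagged.  Comparisons are strict, so a value exactly at a bound is not
impaired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InsufficientNormativeError, ProtocolError

__all__ = [
    "VMRSession",
    "AdaptationMetrics",
    "AdaptationFlags",
    "ControlRanges",
    "summarize_session",
    "control_range",
    "trials_to_adapt",
    "classify_adaptation",
    "with_trials",
    "ADAPTATION_WINDOW",
]

ADAPTATION_WINDOW = 15  # trials: summary windows and the consecutive-run criterion

_PHASE_COUNTS = (25, 125, 25)


@dataclass(frozen=True)
class VMRSession:
    """One participant's rotated-cursor session: 175 initial reach directions."""

    directions: np.ndarray           # (175,) signed degrees, compensatory positive
    phases: np.ndarray               # (175,) in {baseline, adaptation, washout}
    rotation_deg: float = 30.0

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        ph = np.asarray(self.phases)
        if d.size != sum(_PHASE_COUNTS) or ph.size != d.size:
            raise ProtocolError(
                f"expected {sum(_PHASE_COUNTS)} trials, got {d.size} directions / {ph.size} phases"
            )
        counts = [int(np.sum(ph == name)) for name in ("baseline", "adaptation", "washout")]
        if tuple(counts) != _PHASE_COUNTS:
            raise ProtocolError(f"phase counts {counts} != {list(_PHASE_COUNTS)}")
        expected = (
            ["baseline"] * _PHASE_COUNTS[0]
            + ["adaptation"] * _PHASE_COUNTS[1]
            + ["washout"] * _PHASE_COUNTS[2]
        )
        if list(ph) != expected:
            raise ProtocolError("phases must be ordered baseline -> adaptation -> washout")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "phases", ph)

    @property
    def baseline(self) -> np.ndarray:
        return self.directions[: _PHASE_COUNTS[0]]

    @property
    def adaptation(self) -> np.ndarray:
        return self.directions[_PHASE_COUNTS[0] : _PHASE_COUNTS[0] + _PHASE_COUNTS[1]]

    @property
    def washout(self) -> np.ndarray:
        return self.directions[_PHASE_COUNTS[0] + _PHASE_COUNTS[1] :]


@dataclass(frozen=True)
class AdaptationMetrics:
    baseline_mean: float
    baseline_sd: float
    initial_adaptation: float
    final_adaptation: float
    trials_to_adapt: int | None = None   # filled once a control threshold exists


@dataclass(frozen=True)
class AdaptationFlags:
    initial_impaired: bool
    final_impaired: bool
    trials_impaired: bool

    @property
    def any_impaired(self) -> bool:
        return self.initial_impaired or self.final_impaired or self.trials_impaired


@dataclass(frozen=True)
class ControlRanges:
    """Empirical 95% control ranges per adaptation measure."""

    initial: tuple[float, float]
    final: tuple[float, float]
    trials: tuple[float, float]

    @property
    def trials_threshold(self) -> float:
        """The Trials-to-Adapt direction threshold: lower bound of Final Adaptation."""
        return self.final[0]


def summarize_session(session: VMRSession) -> AdaptationMetrics:
    """Baseline statistics and Initial/Final Adaptation for one session."""
    adapt = session.adaptation
    w = ADAPTATION_WINDOW
    return AdaptationMetrics(
        baseline_mean=float(np.mean(session.baseline)),
        baseline_sd=float(np.std(session.baseline, ddof=1)),
        initial_adaptation=float(np.mean(adapt[:w])),
        final_adaptation=float(np.mean(adapt[-w:])),
    )


def control_range(values, coverage: float = 0.95) -> tuple[float, float]:
    """Empirical central ``coverage`` range of control data.

    Uses the linear-interpolation quantile definition at probabilities
    (1-coverage)/2 and 1-(1-coverage)/2 (2.5% / 97.5% by default).
    Requires at least 20 observations.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 20:
        raise InsufficientNormativeError(f"need >= 20 control values, got {vals.size}")
    alpha = (1.0 - coverage) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha], method="linear")
    if lo >= hi:
        warnings.warn("degenerate control range (lower bound >= upper bound)", stacklevel=2)
    return float(lo), float(hi)


def trials_to_adapt(session: VMRSession, threshold: float) -> int:
    """First adaptation trial starting 15 consecutive trials strictly above threshold.

    1-based over the 125 adaptation trials; the run must fit within the
    phase (latest admissible start = trial 111).  Returns 125 on failure to
    adapt.
    """
    adapt = session.adaptation
    above = adapt > threshold
    w = ADAPTATION_WINDOW
    windows = np.lib.stride_tricks.sliding_window_view(above, w)
    hits = np.nonzero(windows.all(axis=1))[0]
    if hits.size == 0:
        return int(adapt.size)
    return int(hits[0]) + 1


def classify_adaptation(metrics: AdaptationMetrics, ranges: ControlRanges) -> AdaptationFlags:
    """Flag impairment per measure against control ranges (strict inequalities)."""
    if metrics.trials_to_adapt is None:
        raise ProtocolError("trials_to_adapt not computed; call trials_to_adapt() first")
    return AdaptationFlags(
        initial_impaired=bool(metrics.initial_adaptation < ranges.initial[0]),
        final_impaired=bool(metrics.final_adaptation < ranges.final[0]),
        trials_impaired=bool(metrics.trials_to_adapt > ranges.trials[1]),
    )


def with_trials(metrics: AdaptationMetrics, n_trials: int) -> AdaptationMetrics:
    """Return a copy of ``metrics`` with the Trials-to-Adapt value filled in."""
    return replace(metrics, trials_to_adapt=int(n_trials))
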