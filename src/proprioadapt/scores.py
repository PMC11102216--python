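"""Normative task-score chain: z / zeta scores, RSS, Box-Cox renormalization.

The global Task Score for a matching task condenses its per-participant
variables into one non-negative impairment score referenced to a normative
(healthy) cohort:

1. each variable is standardized against the normative mean and SD;
2. two-sided variables (ideal at an interior value, e.g. Area at 1, Shift
   at 0, speed/path ratios at 1) are kept as z-scores; one-sided variables
   where only high values are abnormal (AE, Var, RL, IDE) are mapped to
   zeta-scores, zeta(p) = Phi^-1((1+p)/2) with p = Phi(z), so the best
   attainable score is 0;
3. the per-variable scores are combined by root-sum-square (RSS);
4. the RSS is renormalized to a z-score through a one-parameter Box-Cox
   transform fitted by maximum likelihood on the normative RSS values;
5. the renormalized z is mapped through the same zeta transform, so a Task
   Score above 1.96 lies outside 95% of the normative range and flags
   impairment.

Because zeta(0.95) = Phi^-1(0.975) = 1.96, "score > 1.96" is exactly "RSS
beyond the normative 95th percentile" when the Box-Cox stage achieves
normality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import (
    DegenerateNormativeError,
    InsufficientNormativeError,
    InvalidArgumentError,
    SchemaError,
)

__all__ = [
    "ONE_SIDED",
    "TWO_SIDED",
    "APM_SCORE_VARIABLES",
    "AMM_SCORE_VARIABLES",
    "IMPAIRMENT_CUTOFF",
    "NormativeModel",
    "TaskScore",
    "zeta_from_probability",
    "fit_normative_model",
    "variable_scores",
    "rss_score",
    "task_score",
    "measure_impaired",
]

ONE_SIDED = "one_sided_high_bad"
TWO_SIDED = "two_sided"

IMPAIRMENT_CUTOFF = 1.96  # zeta units: outside 95% of the normative range

# Default variable sets: per-direction errors/variability are one-sided,
# workspace area/shift and the AMM ratios are two-sided.
APM_SCORE_VARIABLES: tuple[tuple[str, str], ...] = (
    ("ae_x", ONE_SIDED),
    ("ae_y", ONE_SIDED),
    ("var_x", ONE_SIDED),
    ("var_y", ONE_SIDED),
    ("area_xy", TWO_SIDED),
    ("shift_x", TWO_SIDED),
    ("shift_y", TWO_SIDED),
)
AMM_SCORE_VARIABLES: tuple[tuple[str, str], ...] = (
    ("rl", ONE_SIDED),
    ("ide", ONE_SIDED),
    ("psr", TWO_SIDED),
    ("plr", TWO_SIDED),
)

_P_CLIP = 1.0 - 1e-12


def zeta_from_probability(p: float) -> float:
    """One-sided transform of a cumulative probability onto the z scale.

    zeta(p) = Phi^-1((1 + p) / 2): zeta(0) = 0 (best possible score),
    strictly increasing, and zeta(0.95) = 1.96 (the impairment cut-off).
    """
    p = float(p)
    if not 0.0 <= p < 1.0:
        raise InvalidArgumentError(f"p must be in [0, 1), got {p}")
    return float(stats.norm.ppf((1.0 + p) / 2.0))


@dataclass(frozen=True)
class TaskScore:
    value: float            # zeta units, >= 0
    impaired: bool          # value > 1.96


@dataclass(frozen=True)
class NormativeModel:
    """Per-variable normative moments plus the fitted RSS -> z Box-Cox stage."""

    variables: tuple[tuple[str, str], ...]   # (name, sidedness)
    means: dict
    sds: dict
    boxcox_lambda: float
    rss_mean: float
    rss_sd: float
    n_normative: int
    provenance: dict = field(default_factory=dict)

    # ---- serialization --------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "variables": [list(v) for v in self.variables],
            "means": self.means,
            "sds": self.sds,
            "boxcox_lambda": self.boxcox_lambda,
            "rss_mean": self.rss_mean,
            "rss_sd": self.rss_sd,
            "n_normative": self.n_normative,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "NormativeModel":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(
            variables=tuple((n, s) for n, s in payload["variables"]),
            means=payload["means"],
            sds=payload["sds"],
            boxcox_lambda=payload["boxcox_lambda"],
            rss_mean=payload["rss_mean"],
            rss_sd=payload["rss_sd"],
            n_normative=payload["n_normative"],
            provenance=payload.get("provenance", {}),
        )


def _row_scores(row: Mapping, variables, means, sds) -> dict:
    scores = {}
    for name, sidedness in variables:
        try:
            value = float(row[name])
        except (KeyError, IndexError) as exc:
            raise SchemaError(f"metric {name!r} missing from input") from exc
        z = (value - means[name]) / sds[name]
        if sidedness == TWO_SIDED:
            scores[name] = z
        elif sidedness == ONE_SIDED:
            p = min(float(stats.norm.cdf(z)), _P_CLIP)
            scores[name] = zeta_from_probability(p)
        else:
            raise InvalidArgumentError(f"unknown sidedness {sidedness!r} for {name!r}")
    return scores


def rss_score(scores) -> float:
    """Root-sum-square of per-variable scores."""
    if isinstance(scores, Mapping):
        scores = list(scores.values())
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise InvalidArgumentError("rss_score needs at least one score")
    return float(np.sqrt(np.sum(arr**2)))


def fit_normative_model(
    normative_metrics: pd.DataFrame,
    variables=APM_SCORE_VARIABLES,
    min_n: int = 40,
    provenance: dict | None = None,
) -> NormativeModel:
    """Fit the normative scoring model on a healthy cohort's metrics table.

    ``normative_metrics`` has one row per normative participant and one
    column per variable.  Raises on fewer than ``min_n`` rows, zero-variance
    variables, or non-positive normative RSS values (the Box-Cox stage
    requires RSS > 0).
    """
    df = normative_metrics
    n = len(df)
    if n < min_n:
        raise InsufficientNormativeError(f"need >= {min_n} normative participants, got {n}")
    names = [name for name, _ in variables]
    for name in names:
        if name not in df.columns:
            raise SchemaError(f"normative table lacks column {name!r}")
        if not np.all(np.isfinite(df[name].to_numpy(dtype=float))):
            raise InvalidArgumentError(f"non-finite normative values in {name!r}")
    means = {name: float(df[name].mean()) for name in names}
    sds = {name: float(df[name].std(ddof=1)) for name in names}
    for name, sd in sds.items():
        if not sd > 0:
            raise DegenerateNormativeError(f"normative SD of {name!r} is zero")

    rss = np.array(
        [rss_score(_row_scores(row, variables, means, sds)) for _, row in df.iterrows()]
    )
    if np.any(rss <= 0):
        raise DegenerateNormativeError("non-positive normative RSS; Box-Cox undefined")
    transformed, lam = stats.boxcox(rss)
    t_sd = float(np.std(transformed, ddof=1))
    if not t_sd > 0:
        raise DegenerateNormativeError("degenerate Box-Cox stage (zero variance)")
    return NormativeModel(
        variables=tuple(variables),
        means=means,
        sds=sds,
        boxcox_lambda=float(lam),
        rss_mean=float(np.mean(transformed)),
        rss_sd=t_sd,
        n_normative=n,
        provenance=provenance or {},
    )


def variable_scores(metrics: Mapping, model: NormativeModel) -> dict:
    """Per-variable z (two-sided) or zeta (one-sided) scores for one participant."""
    return _row_scores(metrics, model.variables, model.means, model.sds)


def task_score(metrics: Mapping, model: NormativeModel) -> TaskScore:
    """The global Task Score: RSS -> Box-Cox z -> zeta, impairment at > 1.96."""
    rss = rss_score(variable_scores(metrics, model))
    transformed = special.boxcox(rss, model.boxcox_lambda)
    z = (transformed - model.rss_mean) / model.rss_sd
    p = float(np.clip(stats.norm.cdf(z), 0.0, _P_CLIP))
    value = zeta_from_probability(p)
    return TaskScore(value=value, impaired=bool(value > IMPAIRMENT_CUTOFF))


def measure_impaired(value: float, mean: float, sd: float, sidedness: str) -> bool:
    """Impairment flag for a single measure against normative moments.

    One-sided measures are impaired beyond the normative 95th percentile
    (zeta > 1.96, i.e. z > 1.645); two-sided measures when |z| > 1.96.
    """
    if not sd > 0:
        raise DegenerateNormativeError("normative SD must be positive")
    z = (value - mean) / sd
    if sidedness == ONE_SIDED:
        p = min(float(stats.norm.cdf(z)), _P_CLIP)
        return zeta_from_probability(p) > IMPAIRMENT_CUTOFF
    if sidedness == TWO_SIDED:
        return abs(z) > IMPAIRMENT_CUTOFF
    raise InvalidArgumentError(f"unknown sidedness {sidedness!r}")
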