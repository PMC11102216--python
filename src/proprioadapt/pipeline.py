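"""End-to-end analysis pipeline: simulate -> metrics -> scores -> adaptation -> stats.

The pipeline reproduces, on a synthetic cohort, the structure of the
cohort-level analysis: per-participant proprioception metrics and Task
Scores referenced to a synthetic normative cohort, adaptation measures
referenced to the control group's empirical 95% ranges, bootstrap group
comparisons, Spearman correlation matrices between proprioception and
adaptation with Holm correction, Fisher exact tests of the independence of
impairment flags, impairment prevalence, and quadrant (impairment-profile)
counts.  A run is fully reproducible from its configuration; every output
table carries the configuration hash in a header comment.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .adaptation import (
    ControlRanges,
    classify_adaptation,
    control_range,
    summarize_session,
    trials_to_adapt,
    with_trials,
)
from .cohort import Cohort, PrevalenceConfig, generate_cohort, generate_normative_cohort
from .errors import InvalidArgumentError, UndefinedCorrelationError
from .kinematics import mirror_x
from .matching import compute_amm, compute_apm
from .protocol import ProtocolSpec
from .scores import (
    AMM_SCORE_VARIABLES,
    APM_SCORE_VARIABLES,
    IMPAIRMENT_CUTOFF,
    ONE_SIDED,
    TWO_SIDED,
    NormativeModel,
    fit_normative_model,
    measure_impaired,
    task_score,
)
from .stats import bootstrap_mean_diff, chi2_proportions, fisher_exact_2x2, holm_correct, spearman

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "compute_metrics",
    "compute_adaptation",
    "score_participants",
    "moving_average",
    "quadrant_counts",
]

# Sidedness of the combined (xy) measures used for per-measure impairment flags.
_APM_MEASURE_SIDEDNESS = {
    "ae_xy": ONE_SIDED,
    "var_xy": ONE_SIDED,
    "area_xy": TWO_SIDED,
    "shift_xy": ONE_SIDED,
}
_AMM_MEASURE_SIDEDNESS = {
    "rl": ONE_SIDED,
    "psr": TWO_SIDED,
    "ide": ONE_SIDED,
    "plr": TWO_SIDED,
}
_VMR_MEASURES = ("initial_adaptation", "final_adaptation", "trials_to_adapt")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Serializable run configuration; a run is reproducible from it alone."""

    seed: int = 1234
    n_stroke: int = 48
    n_control: int = 40
    n_normative: int = 120
    p_proprioception: float = 0.55
    p_adaptation: float = 0.50
    impairment_correlation: float = 0.0
    n_boot: int = 99_999
    alpha: float = 0.05
    outdir: str | None = None
    protocol: dict = field(default_factory=dict)   # ProtocolSpec overrides

    def protocol_spec(self) -> ProtocolSpec:
        return ProtocolSpec(**self.protocol)

    def prevalence(self) -> PrevalenceConfig:
        return PrevalenceConfig(
            p_proprioception=self.p_proprioception,
            p_adaptation=self.p_adaptation,
            impairment_correlation=self.impairment_correlation,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise InvalidArgumentError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# small utilities from the figure pipeline
# ---------------------------------------------------------------------------

def moving_average(series, window: int = 5, overlap: int = 4) -> np.ndarray:
    """Sliding-mean smoothing with step = window - overlap (default step 1).

    Only full windows are emitted, indexed at window centres.
    """
    if window < 1:
        raise InvalidArgumentError("window must be >= 1")
    if overlap >= window or overlap < 0:
        raise InvalidArgumentError("overlap must satisfy 0 <= overlap < window")
    arr = np.asarray(series, dtype=float)
    if arr.size < window:
        raise InvalidArgumentError("series shorter than the window")
    step = window - overlap
    views = np.lib.stride_tricks.sliding_window_view(arr, window)[::step]
    return views.mean(axis=1)


def quadrant_counts(flags_x, flags_y) -> pd.DataFrame:
    """2x2 impairment-profile counts and proportions (both / x-only / y-only / neither)."""
    fx = np.asarray(flags_x, dtype=bool)
    fy = np.asarray(flags_y, dtype=bool)
    if fx.size != fy.size:
        raise InvalidArgumentError("flag vectors must have equal length")
    if fx.size == 0:
        raise InvalidArgumentError("empty flag vectors")
    counts = {
        "both": int(np.sum(fx & fy)),
        "x_only": int(np.sum(fx & ~fy)),
        "y_only": int(np.sum(~fx & fy)),
        "neither": int(np.sum(~fx & ~fy)),
    }
    n = fx.size
    return pd.DataFrame(
        {
            "quadrant": list(counts),
            "count": list(counts.values()),
            "proportion": [v / n for v in counts.values()],
        }
    )


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def compute_metrics(cohort: Cohort) -> pd.DataFrame:
    """Per-participant APM + AMM metrics (matched data mirrored into the
    passive arm's frame before metric computation)."""
    rows = []
    for p in cohort.participants:
        apm = compute_apm(p.apm_targets, mirror_x(p.apm_matched))
        amm = compute_amm(
            [(passive, mirror_x(active), failed) for passive, active, failed in p.amm_trials]
        )
        row = {"participant_id": p.participant_id, "group": p.params.group, "tlt": p.params.tlt}
        row.update(apm.as_dict())
        row.update(amm.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def compute_adaptation(cohort: Cohort) -> tuple[pd.DataFrame, ControlRanges]:
    """Adaptation measures for every participant plus control 95% ranges.

    The Trials-to-Adapt direction threshold is the lower bound of the
    control group's Final Adaptation range; its impairment bound is the
    upper end of the controls' Trials-to-Adapt range.
    """
    summaries = {p.participant_id: summarize_session(p.vmr) for p in cohort.participants}
    control_ids = [p.participant_id for p in cohort.participants if p.params.group == "control"]
    if not control_ids:
        raise InvalidArgumentError("cohort has no control participants to set ranges")

    rng_initial = control_range([summaries[i].initial_adaptation for i in control_ids])
    rng_final = control_range([summaries[i].final_adaptation for i in control_ids])
    threshold = rng_final[0]

    trials = {
        p.participant_id: trials_to_adapt(p.vmr, threshold) for p in cohort.participants
    }
    rng_trials = control_range([trials[i] for i in control_ids])
    ranges = ControlRanges(initial=rng_initial, final=rng_final, trials=rng_trials)

    rows = []
    for p in cohort.participants:
        m = with_trials(summaries[p.participant_id], trials[p.participant_id])
        flags = classify_adaptation(m, ranges)
        rows.append(
            {
                "participant_id": p.participant_id,
                "group": p.params.group,
                "baseline_mean": m.baseline_mean,
                "baseline_sd": m.baseline_sd,
                "initial_adaptation": m.initial_adaptation,
                "final_adaptation": m.final_adaptation,
                "trials_to_adapt": m.trials_to_adapt,
                "initial_impaired": flags.initial_impaired,
                "final_impaired": flags.final_impaired,
                "trials_impaired": flags.trials_impaired,
                "adaptation_impaired": flags.any_impaired,
            }
        )
    return pd.DataFrame(rows), ranges


def score_participants(
    metrics: pd.DataFrame,
    normative_metrics: pd.DataFrame,
    seed: int | None = None,
) -> tuple[pd.DataFrame, NormativeModel, NormativeModel]:
    """Task Scores and per-measure impairment flags against a normative table."""
    provenance = {"n_normative": len(normative_metrics), "seed": seed}
    apm_model = fit_normative_model(normative_metrics, APM_SCORE_VARIABLES, provenance=provenance)
    amm_model = fit_normative_model(normative_metrics, AMM_SCORE_VARIABLES, provenance=provenance)

    measure_moments = {
        name: (
            float(normative_metrics[name].mean()),
            float(normative_metrics[name].std(ddof=1)),
            side,
        )
        for name, side in {**_APM_MEASURE_SIDEDNESS, **_AMM_MEASURE_SIDEDNESS}.items()
    }

    rows = []
    for _, row in metrics.iterrows():
        apm = task_score(row, apm_model)
        amm = task_score(row, amm_model)
        rec = {
            "participant_id": row["participant_id"],
            "group": row["group"],
            "apm_task_score": apm.value,
            "amm_task_score": amm.value,
            "apm_impaired": apm.impaired,
            "amm_impaired": amm.impaired,
            "proprioception_impaired": apm.impaired or amm.impaired,
            "tlt": int(row["tlt"]),
            "tlt_impaired": bool(row["tlt"] > 0),
        }
        for name, (mean, sd, side) in measure_moments.items():
            rec[f"{name}_impaired"] = measure_impaired(float(row[name]), mean, sd, side)
        rows.append(rec)
    return pd.DataFrame(rows), apm_model, amm_model


def _fanout_seed(seed: int, k: int) -> int:
    """Counter-based derived seed (stable when analyses are added later)."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31 - 1))


def _group_comparisons(
    participants: pd.DataFrame, adaptation: pd.DataFrame, cfg: PipelineConfig
) -> pd.DataFrame:
    stroke = adaptation[adaptation["group"] == "stroke"]
    control = adaptation[adaptation["group"] == "control"]
    p_stroke = participants[participants["group"] == "stroke"]
    p_control = participants[participants["group"] == "control"]

    rows = []
    comparisons = [
        ("age", p_stroke["age"], p_control["age"], "two-sided"),
        ("baseline_mean", stroke["baseline_mean"], control["baseline_mean"], "two-sided"),
        ("baseline_sd", stroke["baseline_sd"], control["baseline_sd"], "two-sided"),
        ("initial_adaptation", stroke["initial_adaptation"], control["initial_adaptation"], "less"),
        ("final_adaptation", stroke["final_adaptation"], control["final_adaptation"], "less"),
        ("trials_to_adapt", stroke["trials_to_adapt"], control["trials_to_adapt"], "greater"),
    ]
    for k, (measure, xs, ys, alt) in enumerate(comparisons):
        res = bootstrap_mean_diff(
            xs.to_numpy(float),
            ys.to_numpy(float),
            alternative=alt,
            n_boot=cfg.n_boot,
            seed=_fanout_seed(cfg.seed, 1000 + k),
        )
        rows.append(
            {
                "measure": measure,
                "test": f"bootstrap_{alt}",
                "estimate": res.estimate,
                "ci_lo": res.ci_lo,
                "ci_hi": res.ci_hi,
                "statistic": np.nan,
                "p": res.p,
                "n_stroke": int(xs.size),
                "n_control": int(ys.size),
            }
        )
    # biological sex composition (proportion female), Pearson chi-squared
    kf_s = int((p_stroke["sex"] == "F").sum())
    kf_c = int((p_control["sex"] == "F").sum())
    prop = chi2_proportions(
        kf_c, len(p_control), kf_s, len(p_stroke),
        n_boot=cfg.n_boot, seed=_fanout_seed(cfg.seed, 1099),
    )
    rows.append(
        {
            "measure": "sex_female_proportion",
            "test": "chi2",
            "estimate": prop.diff,
            "ci_lo": prop.ci_lo,
            "ci_hi": prop.ci_hi,
            "statistic": prop.chi2,
            "p": prop.p,
            "n_stroke": len(p_stroke),
            "n_control": len(p_control),
        }
    )
    return pd.DataFrame(rows)


def _correlation_family(
    data: pd.DataFrame, xs: list[str], family: str, cfg: PipelineConfig, seed_base: int
) -> pd.DataFrame:
    rows = []
    k = 0
    for x in xs:
        for y in _VMR_MEASURES:
            try:
                res = spearman(
                    data[x].to_numpy(float),
                    data[y].to_numpy(float),
                    n_boot=cfg.n_boot,
                    seed=_fanout_seed(cfg.seed, seed_base + k),
                )
                rho, ci_lo, ci_hi, p = res.rho, res.ci_lo, res.ci_hi, res.p
            except UndefinedCorrelationError:
                # a constant measure (e.g. every TLT equal in a tiny cohort)
                rho = ci_lo = ci_hi = p = np.nan
            rows.append(
                {
                    "family": family,
                    "measure_x": x,
                    "measure_y": y,
                    "rho": rho,
                    "ci_lo": ci_lo,
                    "ci_hi": ci_hi,
                    "p_raw": p,
                    "n": len(data),
                }
            )
            k += 1
    df = pd.DataFrame(rows)
    defined = np.isfinite(df["p_raw"].to_numpy())
    df["p_holm"] = np.nan
    df["significant"] = False
    if defined.any():
        adj, rej = holm_correct(df.loc[defined, "p_raw"].to_numpy(), alpha=cfg.alpha)
        df.loc[defined, "p_holm"] = adj
        df.loc[defined, "significant"] = rej
    return df


def _fisher_family(
    flags: pd.DataFrame, xs: list[str], ys: list[str], family: str, alpha: float
) -> pd.DataFrame:
    rows = []
    for x in xs:
        for y in ys:
            fx = flags[x].to_numpy(bool)
            fy = flags[y].to_numpy(bool)
            table = [
                [int(np.sum(fx & fy)), int(np.sum(fx & ~fy))],
                [int(np.sum(~fx & fy)), int(np.sum(~fx & ~fy))],
            ]
            odds, p = fisher_exact_2x2(table)
            rows.append(
                {
                    "family": family,
                    "measure_x": x,
                    "measure_y": y,
                    "odds_ratio": odds,
                    "p_raw": p,
                    "n": int(fx.size),
                }
            )
    df = pd.DataFrame(rows)
    adj, rej = holm_correct(df["p_raw"].to_numpy(), alpha=alpha)
    df["p_holm"] = adj
    df["significant"] = rej
    return df


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: PipelineConfig
    config_hash: str
    participants: pd.DataFrame
    metrics: pd.DataFrame
    scores: pd.DataFrame
    adaptation: pd.DataFrame
    control_ranges: ControlRanges
    apm_model: NormativeModel
    amm_model: NormativeModel
    group_comparisons: pd.DataFrame
    correlations: pd.DataFrame
    fisher: pd.DataFrame
    prevalence: pd.DataFrame
    quadrants: pd.DataFrame
    profiles: pd.DataFrame


def _impairment_profiles(scores: pd.DataFrame, adaptation: pd.DataFrame) -> pd.DataFrame:
    prof = scores.merge(
        adaptation[
            [
                "participant_id",
                "initial_impaired",
                "final_impaired",
                "trials_impaired",
                "adaptation_impaired",
            ]
        ],
        on="participant_id",
    )
    return prof


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis on a freshly simulated cohort."""
    cfg = config
    chash = cfg.config_hash()

    spec = cfg.protocol_spec()
    normative = generate_normative_cohort(n=cfg.n_normative, seed=cfg.seed, spec=spec)
    cohort = generate_cohort(
        n_stroke=cfg.n_stroke,
        n_control=cfg.n_control,
        prevalence=cfg.prevalence(),
        seed=cfg.seed,
        spec=spec,
    )

    participants = cohort.participants_frame()
    participants["age"] = [p.params.age for p in cohort.participants]

    metrics = compute_metrics(cohort)
    normative_metrics = compute_metrics(normative)
    scores, apm_model, amm_model = score_participants(metrics, normative_metrics, seed=cfg.seed)
    adaptation, ranges = compute_adaptation(cohort)

    group_tbl = _group_comparisons(participants, adaptation, cfg)

    stroke_ids = metrics.loc[metrics["group"] == "stroke", "participant_id"]
    stroke = (
        metrics.merge(
            scores[["participant_id", "apm_task_score", "amm_task_score"]], on="participant_id"
        )
        .merge(adaptation[["participant_id"] + list(_VMR_MEASURES)], on="participant_id")
    )
    stroke = stroke[stroke["participant_id"].isin(stroke_ids)].reset_index(drop=True)

    corr_frames = []
    if len(stroke) >= 4:
        corr_frames.append(
            _correlation_family(
                stroke, ["apm_task_score", "ae_xy", "var_xy", "area_xy", "shift_xy"],
                "apm_vmr", cfg, seed_base=2000,
            )
        )
        corr_frames.append(
            _correlation_family(
                stroke, ["amm_task_score", "rl", "psr", "ide", "plr"],
                "amm_vmr", cfg, seed_base=2100,
            )
        )
        corr_frames.append(
            _correlation_family(stroke, ["tlt"], "tlt_vmr", cfg, seed_base=2200)
        )
    correlations = pd.concat(corr_frames, ignore_index=True) if corr_frames else pd.DataFrame()

    profiles = _impairment_profiles(scores, adaptation)
    stroke_prof = profiles[profiles["group"] == "stroke"].reset_index(drop=True)

    fisher_frames = []
    if len(stroke_prof):
        adap_flags = ["initial_impaired", "final_impaired", "trials_impaired"]
        fisher_frames.append(
            _fisher_family(
                stroke_prof,
                ["apm_impaired", "ae_xy_impaired", "var_xy_impaired", "area_xy_impaired",
                 "shift_xy_impaired"],
                adap_flags, "apm_vmr", cfg.alpha,
            )
        )
        fisher_frames.append(
            _fisher_family(
                stroke_prof,
                ["amm_impaired", "rl_impaired", "psr_impaired", "ide_impaired", "plr_impaired"],
                adap_flags, "amm_vmr", cfg.alpha,
            )
        )
        fisher_frames.append(
            _fisher_family(stroke_prof, ["tlt_impaired"], adap_flags, "tlt_vmr", cfg.alpha)
        )
    fisher = pd.concat(fisher_frames, ignore_index=True) if fisher_frames else pd.DataFrame()

    prevalence_flags = [
        "apm_impaired", "amm_impaired", "proprioception_impaired", "tlt_impaired",
        "initial_impaired", "final_impaired", "trials_impaired", "adaptation_impaired",
    ]
    n_stroke_prof = max(len(stroke_prof), 1)
    prevalence = pd.DataFrame(
        {
            "flag": prevalence_flags,
            "n_impaired": [int(stroke_prof[f].sum()) for f in prevalence_flags],
            "proportion": [float(stroke_prof[f].mean()) for f in prevalence_flags]
            if len(stroke_prof)
            else [np.nan] * len(prevalence_flags),
            "n": [len(stroke_prof)] * len(prevalence_flags),
        }
    )

    quad_frames = []
    for xname in ("apm_impaired", "amm_impaired", "tlt_impaired", "proprioception_impaired"):
        for yname in ("initial_impaired", "final_impaired", "trials_impaired",
                      "adaptation_impaired"):
            q = quadrant_counts(stroke_prof[xname], stroke_prof[yname])
            q.insert(0, "measure_y", yname)
            q.insert(0, "measure_x", xname)
            quad_frames.append(q)
    quadrants = pd.concat(quad_frames, ignore_index=True)

    result = PipelineResult(
        config=cfg,
        config_hash=chash,
        participants=participants,
        metrics=metrics,
        scores=scores,
        adaptation=adaptation,
        control_ranges=ranges,
        apm_model=apm_model,
        amm_model=amm_model,
        group_comparisons=group_tbl,
        correlations=correlations,
        fisher=fisher,
        prevalence=prevalence,
        quadrants=quadrants,
        profiles=profiles,
    )
    if cfg.outdir is not None:
        write_result(result, cfg.outdir)
    return result


def _render_report(result: PipelineResult) -> str:
    cfg = result.config
    prev = result.prevalence.set_index("flag")
    lines = [
        "# Synthetic cohort analysis report",
        "",
        f"- config hash: `{result.config_hash}`  (seed {cfg.seed})",
        f"- cohort: {cfg.n_stroke} stroke / {cfg.n_control} control; "
        f"normative n = {cfg.n_normative} (synthetic normative model, fitted in-run)",
        f"- bootstrap resamples: {cfg.n_boot}; alpha = {cfg.alpha}",
        "",
        "## Impairment prevalence (stroke group)",
        "",
        f"- proprioception (APM or AMM Task Score > {IMPAIRMENT_CUTOFF}): "
        f"{prev.loc['proprioception_impaired', 'proportion']:.1%}",
        f"- adaptation (any VMR measure): {prev.loc['adaptation_impaired', 'proportion']:.1%}",
        "",
        "## Group comparisons",
        "",
        result.group_comparisons.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        "",
        "## Significant correlations after Holm correction",
        "",
    ]
    sig = result.correlations[result.correlations["significant"]]
    lines.append(sig.to_string(index=False) if len(sig) else "(none)")
    lines += ["", "## Significant Fisher independence tests after Holm correction", ""]
    sigf = result.fisher[result.fisher["significant"]]
    lines.append(sigf.to_string(index=False) if len(sigf) else "(none)")
    lines.append("")
    return "\n".join(lines)


def write_result(result: PipelineResult, outdir) -> None:
    """Write all result tables, models, ranges, and a Markdown report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comment = f"config_hash={result.config_hash} seed={result.config.seed}"
    tables = {
        "participants.csv": result.participants,
        "metrics.csv": result.metrics,
        "scores.csv": result.scores,
        "adaptation.csv": result.adaptation,
        "group_comparisons.csv": result.group_comparisons,
        "correlations.csv": result.correlations,
        "fisher.csv": result.fisher,
        "prevalence.csv": result.prevalence,
        "quadrants.csv": result.quadrants,
        "impairment_profiles.csv": result.profiles,
    }
    for name, df in tables.items():
        pio.write_csv(df, outdir / name, header_comment=comment)
    ranges = result.control_ranges
    with open(outdir / "control_ranges.json", "w") as fh:
        json.dump(
            {
                "config_hash": result.config_hash,
                "initial": list(ranges.initial),
                "final": list(ranges.final),
                "trials": list(ranges.trials),
                "trials_threshold": ranges.trials_threshold,
            },
            fh,
            indent=2,
        )
    result.apm_model.to_json(outdir / "normative_apm.json")
    result.amm_model.to_json(outdir / "normative_amm.json")
    (outdir / "report.md").write_text(_render_report(result))
    with open(outdir / "run.log", "w") as fh:
        fh.write(f"config_hash={result.config_hash}\n")
        fh.write(json.dumps(result.config.to_dict(), indent=2, sort_keys=True) + "\n")
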