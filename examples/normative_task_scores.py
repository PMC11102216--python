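"""Fit the normative scoring model and compute Task Scores.

A Task Score condenses the matching variables into one number referenced
to a healthy cohort: per-variable z/zeta scores -> root-sum-square ->
Box-Cox renormalization -> final zeta.  Scores above 1.96 lie outside 95%
of the normative range and flag impairment.
"""

from proprioadapt import (
    APM_SCORE_VARIABLES,
    fit_normative_model,
    generate_normative_cohort,
    task_score,
)
from proprioadapt.pipeline import compute_metrics

normative = generate_normative_cohort(n=120, seed=1)
normative_metrics = compute_metrics(normative)
model = fit_normative_model(normative_metrics, APM_SCORE_VARIABLES,
                            provenance={"n": 120, "seed": 1})
print(f"fitted Box-Cox lambda = {model.boxcox_lambda:.3f} "
      f"on n = {model.n_normative} normative participants")

healthy = normative_metrics.iloc[0]
print(f"healthy participant : APM Task Score = {task_score(healthy, model).value:.2f}")

impaired = healthy.copy()
impaired["ae_x"] += 6 * model.sds["ae_x"]   # grossly inaccurate matching
impaired["area_xy"] = 0.5                   # strongly contracted workspace
score = task_score(impaired, model)
print(f"impaired participant: APM Task Score = {score.value:.2f} "
      f"(impaired = {score.impaired}, cut-off 1.96)")
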