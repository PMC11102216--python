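# Methods

This note documents the models, conventions, and numerical choices behind
`proprioadapt`, in the spirit of a model-description appendix: what is
simulated, what is measured, which decisions were genuinely open, and what
the synthetic results do and do not show about real data.

## Coordinate and angle conventions

The workspace is the horizontal plane: x to the participant's right, y
away from the body, metres, midline at x = 0. Mirror-matching between
arms is the reflection x → −x (an involution; path length and peak speed
are mirror-invariant). The passive (more-affected) arm's grid is centred
at (0.17, 0.30) m as a planar stand-in for the 30° shoulder / 90° elbow
configuration; the mirrored active workspace then lies strictly on the
other side of the midline.

Reach directions are signed degrees relative to the straight start→target
line, with the **compensatory** direction positive: a 30° counter-clockwise
cursor rotation is countered by reaching clockwise, so complete adaptation
is +30°. One consequence: "below the control range" is the impaired
direction for both adaptation magnitude measures.

Note on frames: the APM workspace-shift parameter of the generator is
expressed in the active arm's frame, while the analysed `Shift` metric is
computed after mirroring into the passive frame — the x-component
therefore flips sign between parameter and metric. Round-trip tests
account for this.

## Trajectory model and kinematic primitives

Passive robot movements and simulated reaches are straight minimum-jerk
trajectories, s(u) = 10u³ − 15u⁴ + 6u⁵ along the chord: the speed profile
is bell-shaped, zero at the endpoints, with a single maximum of
1.875·distance/duration at mid-movement. Default sampling is 200 Hz, so
one 5 ms step bounds onset and probe-timing error.

Velocities are obtained by central differences (one-sided at the ends)
with **no smoothing**: synthetic positions are noise-free, and fixing the
differentiation scheme keeps results reproducible without committing to a
filtering choice real data would require.

Movement onset is the first sample whose velocity **strictly** exceeds
12.5% of its peak — forward (+y) velocity for rotated-cursor reaching,
speed magnitude for the matching tasks where direction varies. Onset is
an index-like event and is not interpolated; the 150 ms direction probe is
a continuous-time quantity and uses linear interpolation between samples.

A known property of threshold-based onsets: when the active movement's
duration differs from the passive one's (speed or path ratio ≠ 1), the
12.5% crossing shifts by s*·(T_active − T_passive) with s* ≈ 0.0975 (the
min-jerk phase at which speed reaches 12.5% of peak). Response latency
estimates therefore carry a predictable duration-dependent offset; at the
default parameter spreads its average contribution is well under 10% of
the latency range (verified by the recovery tests).

## Synthetic behaviour models

No generative model of matching or adaptation behaviour is prescribed by
the assessment procedure itself, so the generator uses the minimal models
whose parameters the metrics are designed to recover:

* **Position matching**: matched_i = C + c·(mirror(target_i) − C) + shift
  + ε, with contraction c about the mirrored-grid centroid C, a constant
  workspace shift, and isotropic Gaussian matching noise ε. Then
  Area = c² exactly and Shift equals the (mirrored) generating shift.
* **Movement matching**: the active trace holds at its start for the
  response latency, then executes a min-jerk reach whose peak speed,
  length, and direction are the passive ones scaled by the speed ratio,
  path ratio, and a Gaussian direction error. A parameterized failure
  probability leaves the active arm stationary; failed trials are excluded
  from metric averages and counted. The failure criterion on the analysis
  side (no detectable onset OR active path < 25% of passive path) is a
  package decision — the assessment procedure does not define failure.
* **Adaptation**: the standard linear state-space learner
  x_{t+1} = a·x_t + b·(r_t − x_t), x_0 = 0, observed through additive
  Gaussian execution noise. Its asymptote during adaptation is
  r·b/(1 − a + b) and its convergence factor is (a − b), so rate and
  plateau are independently controllable for recovery tests.

### Cohort hyper-distributions

Healthy parameters are drawn from truncated normals calibrated to printed
protocol anchors (passive peak speeds 0.283 m/s for position matching and
0.20 m/s for movement matching; sampled peak-speed range 0.167–0.406 m/s)
and to plausible control behaviour: near-veridical matching (contraction
1.00 ± 0.06, noise ~8 mm), prompt responses (latency 150 ± 40 ms), and
fast adaptation with a high plateau (a ≈ 0.98, b ≈ 0.15, asymptote
≈ 26–27°). Stroke baseline reaching noise exceeds the control mean by
3.27°, reproducing the published group difference in baseline variability
as a calibration anchor.

Stroke participants receive two independent Bernoulli impairment labels
(proprioception, adaptation) with default prevalences 0.55 / 0.50, drawn
through a Gaussian copula whose correlation is an exposed parameter
(default 0 — the independence structure is the null the analysis should
be able to confirm, and the copula lets a user generate coupled cohorts
to verify power). Impaired draws shift to noisier/contracted matching,
longer latencies, larger direction errors, and slow/low learners
(b ≈ 0.03). The ordinal clinical proprioception score (0–3) is a monotone
threshold function of the matching-noise parameter with a small latent
jitter; controls score 0.

All randomness flows from one integer seed through named, counter-based
streams (participant seed × task stream), so cohorts are bit-reproducible
and adding an analysis does not shift earlier draws.

## Metric definitions where the procedure is underspecified

* **Variability** is the mean over targets of the per-target SD (ddof = 1)
  of matched positions across repetitions — "trial-to-trial variability in
  the matched location" read per location, not pooled.
* **Area** is the convex-hull area of the nine per-target mean matched
  positions over the hull of the nine targets: deterministic and exactly
  scale-consistent (area scales as c² under similarity scaling).
* AE and Var are combined across directions by root-sum-square, matching
  the RSS construction of the Task Score; per-direction components are
  retained because the score consumes them.
* **IDE** is the absolute angular difference wrapped to [0°, 180°],
  symmetric in the two arms.

## Normative scoring

The normative model stores per-variable means/SDs from a healthy cohort
(minimum 40, default 120 synthetic participants — the proprietary
age/sex/handedness-adjusted normative database behind the commercial
implementation cannot be shipped, so scores are reproducible in procedure,
not in values). One-sided variables (AE, Var, RL, IDE — only high values
abnormal) map through zeta(p) = Φ⁻¹((1+p)/2) so their best score is 0;
two-sided variables (Area, Shift components, speed/path ratios) stay as
z-scores. The per-participant RSS is renormalized by a one-parameter
Box-Cox transform fitted by maximum likelihood on the normative RSS values
(all strictly positive under continuous noise), standardized, and mapped
through the same zeta. Since zeta(0.95) = 1.96, "score > 1.96" is "beyond
the normative 95th percentile" whenever the Box-Cox stage achieves
normality; simulation places the realized false-positive rate at ≈ 4–5%.
The cumulative probability is clipped at 1 − 1e-12 before the final zeta
so extreme participants receive large finite scores.

The AMM failed-trial count is computed and reported but not included in
the default AMM score variable set: synthetic normative participants
essentially never fail, the count's normative variance is 0, and a
z-score would be undefined (the fit correctly refuses zero-variance
variables). A caller with a normative cohort that does exhibit failures
can pass a variable set including `n_failed`.

Optional covariate adjustment (scoring against residuals of
metric ~ age + sex + handedness) was considered and deliberately left out
of the default chain: the synthetic generator draws parameters
independently of demographics, so the adjustment would only add variance.
The measure-level impairment helper uses the same machinery (one-sided:
zeta > 1.96 ⇔ z > 1.645; two-sided: |z| > 1.96).

## Adaptation summaries and classification

Baseline statistics use the 25 baseline trials (SD with ddof = 1);
Initial/Final Adaptation are means over adaptation trials 1–15 and
111–125; windows never cross phase boundaries and washout content is
irrelevant to them. The "95% range of control data" is read as empirical
coverage: 2.5th/97.5th percentiles with the linear-interpolation quantile
rule. Trials to Adapt uses the lower bound of the controls' Final
Adaptation range as its threshold and requires 15 **strictly** exceeding
consecutive trials fitting entirely within the adaptation phase (latest
admissible start: trial 111); failure scores 125. Impairment comparisons
are strict, so a value exactly at a bound is not impaired — ties resolve
conservatively.

A consequence of the empirical upper bound worth knowing: if more than
2.5% of controls themselves fail the 15-consecutive-trials criterion, the
control range for Trials to Adapt saturates at 125 and the corresponding
impairment flag cannot fire (no value strictly exceeds 125). At the
default control parameters (asymptote ≈ 26.5°, trial noise ≈ 3.5°) this
happens in some seeds; the flag is then conservative. The two magnitude
flags and the any-measure flag are unaffected.

## Statistics

* **Bootstrap mean-difference test**: each group resampled with
  replacement (default 99,999 resamples); percentile 2.5/97.5 CI; p by the
  percentile-of-zero rule with the +1 continuity correction (minimum
  attainable p = 1/(n_boot+1)). One-tailed directions follow the stated
  hypotheses (stroke lower Initial/Final Adaptation, stroke more Trials to
  Adapt). Simulated null calibration: type-I error 0.05 ± 0.02.
* **Spearman's rho** on midranks with the t-approximation p-value —
  adequate at cohort sizes around 45–48 and far cheaper than exact
  permutation — and a percentile bootstrap over paired resamples for the
  CI (degenerate constant-rank resamples are excluded).
* **Rank partial correlation** by the plug-in formula on rank-transformed
  data, for covariate-controlled association checks.
* **Fisher's exact test** with the probability-mass two-sided rule (sum of
  all margin-preserving tables no more likely than the observed one) and
  the sample odds ratio ad/bc (∞ and undefined cases flagged). Verified
  against full hypergeometric enumeration for every table with total ≤ 30.
* **Proportion comparison** by Pearson chi-squared without continuity
  correction (df = 1), bootstrap CI on the difference.
* **Holm correction** by the step-down running-maximum construction,
  rejection at adjusted p strictly below alpha, applied within each test
  family (each correlation matrix, each Fisher matrix).

## Pipeline and problem sizes

The full run simulates a normative cohort (default 120), a study cohort
(default 48 stroke / 40 control), computes metrics → scores → adaptation →
statistics, and writes tidy CSVs, model/range JSONs, a Markdown report,
and a log; every output carries the SHA-256 config hash, and identical
configs produce byte-identical outputs. Tests and examples run reduced
problem sizes (hundreds of bootstrap resamples, cohorts of 12–60; recovery
checks use 200 simulated participants and the calibration checks 500–1000
draws), chosen so the whole suite completes in about a minute while
keeping Monte-Carlo error well inside the asserted bands.

## What the synthetic cohort does not show

The generator reproduces the statistical *structure* the analysis assumes
— not real stroke behaviour. It omits corrective sub-movements, trial
failures beyond the parameterized flag, joint-space kinematics and
exoskeleton dynamics, fatigue/learning drifts within the matching tasks,
demographic dependence of the metrics, and any genuine coupling between
proprioceptive and adaptation deficits (unless configured). Passing tests
therefore demonstrate correctness of the measurement and inference chain
and calibration under the generator's assumptions; they do not validate
the behavioural model against patient data, and cohort-level published
effect sizes are used only as calibration anchors, not as reproduction
targets.
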