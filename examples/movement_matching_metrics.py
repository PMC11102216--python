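"""Movement-matching (AMM) metrics from simulated passive/active reach pairs.

The robot moves the passive arm 20 cm with a bell-shaped (minimum-jerk)
speed profile peaking at 20 cm/s; the participant mirrors it with the
active arm.  A delayed, slow, misdirected matcher shows up directly in
Response Latency (RL), Peak Speed Ratio (PSR), Initial Direction Error
(IDE), and Path Length Ratio (PLR).
"""

from proprioadapt import DEFAULT_PROTOCOL as SPEC
from proprioadapt import compute_amm, min_jerk_trajectory, mirror_x, simulate_amm_trial
from proprioadapt.cohort import MIN_JERK_PEAK_FACTOR, ParticipantParams


def params(**overrides):
    base = dict(
        group="stroke", age=70, sex="F", handedness="R",
        apm_noise_sd=0.01, apm_contraction=1.0, apm_shift=(0.0, 0.0),
        amm_latency=0.0, amm_speed_ratio=1.0, amm_dir_error_sd=0.0,
        amm_path_ratio=1.0, learner_retention=0.98, learner_rate=0.15,
        baseline_dir_sd=3.5, tlt=0, rng_seed=11,
    )
    base.update(overrides)
    return ParticipantParams(**base)


move_t = MIN_JERK_PEAK_FACTOR * SPEC.amm_movement_length / SPEC.passive_peak_speed_amm
positions = SPEC.amm_positions()

for label, p in [
    ("prompt matcher  ", params()),
    ("impaired matcher", params(amm_latency=0.35, amm_speed_ratio=0.6,
                                amm_dir_error_sd=12.0, amm_path_ratio=1.3)),
]:
    import numpy as np

    trials = []
    rng = np.random.default_rng(3)
    noise_rng = p.rng(2)  # one persistent noise stream across the 36 trials
    for i, j in SPEC.amm_sequence(rng):
        passive = min_jerk_trajectory(positions[i], positions[j], move_t, SPEC.sample_rate)
        active, failed = simulate_amm_trial(passive, p, rng=noise_rng)
        trials.append((passive, mirror_x(active), failed))
    m = compute_amm(trials)
    print(f"{label}: RL={m.rl * 1000:.0f} ms  PSR={m.psr:.2f}  "
          f"IDE={m.ide:.1f} deg  PLR={m.plr:.2f}  failed={m.n_failed}/36")
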