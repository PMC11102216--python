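"""Position-matching (APM) metrics for an intact and an impaired matcher.

Simulates the 54-trial mirror-matching protocol twice: once for a
noiseless veridical matcher and once for a participant with a contracted
workspace (0.8), a 2 cm leftward shift, and 2 cm matching noise.  Area < 1
means the matched workspace is contracted; Shift is the systematic
translation of the matched grid; AE/Var capture accuracy and consistency.
"""

import numpy as np

from proprioadapt import DEFAULT_PROTOCOL, compute_apm, mirror_x, simulate_apm_matching
from proprioadapt.cohort import ParticipantParams


def params(**overrides):
    base = dict(
        group="stroke", age=65, sex="M", handedness="R",
        apm_noise_sd=0.0, apm_contraction=1.0, apm_shift=(0.0, 0.0),
        amm_latency=0.1, amm_speed_ratio=1.0, amm_dir_error_sd=0.0,
        amm_path_ratio=1.0, learner_retention=0.98, learner_rate=0.15,
        baseline_dir_sd=3.5, tlt=0, rng_seed=7,
    )
    base.update(overrides)
    return ParticipantParams(**base)


rng = np.random.default_rng(7)
targets = DEFAULT_PROTOCOL.apm_positions()[DEFAULT_PROTOCOL.apm_sequence(rng)]

for label, p in [
    ("veridical matcher", params()),
    ("impaired matcher ", params(apm_contraction=0.8, apm_shift=(-0.02, 0.0),
                                 apm_noise_sd=0.02, tlt=2)),
]:
    matched = simulate_apm_matching(targets, p)
    m = compute_apm(targets, mirror_x(matched))
    print(f"{label}: AE={m.ae_xy * 100:.2f} cm  Var={m.var_xy * 100:.2f} cm  "
          f"Area={m.area_xy:.3f}  Shift=({m.shift_x * 100:+.2f}, {m.shift_y * 100:+.2f}) cm")
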