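"""Generate a small synthetic assessment cohort and inspect its structure.

Builds 6 stroke and 6 control participants with the default impairment
prevalences, prints the participant table and one participant's generating
parameters, and shows the per-task trial counts.  The printed parameters
(matching noise, workspace contraction, learner rate...) are exactly the
quantities the downstream metrics are designed to recover.
"""

from proprioadapt import generate_cohort

cohort = generate_cohort(n_stroke=6, n_control=6, seed=42)

print(cohort.participants_frame().to_string(index=False))

p = cohort.participants[0]
print(f"\nparticipant {p.participant_id} ({p.params.group}):")
print(f"  apm_noise_sd     = {p.params.apm_noise_sd:.4f} m")
print(f"  apm_contraction  = {p.params.apm_contraction:.3f}")
print(f"  amm_latency      = {p.params.amm_latency:.3f} s")
print(f"  learner (a, b)   = ({p.params.learner_retention:.3f}, {p.params.learner_rate:.3f})")
print(f"  trials: APM {p.apm_targets.shape[0]}, AMM {len(p.amm_trials)}, "
      f"VMR {p.vmr.directions.size}")
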