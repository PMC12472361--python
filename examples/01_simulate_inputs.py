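"""Simulate a full study's worth of inputs with known ground truth.

Builds replicated lab stress transcriptomes (control / cold / desiccated),
field metatranscriptome replicates at chosen latent stress fractions, and a
BLAST-style identity-hit table linking field contigs to the reference
transcripts -- everything the downstream stages consume.
"""

from gmindex import (
    SyntheticScenario,
    simulate_field_samples,
    simulate_identity_hits,
    simulate_lab_experiment,
)

scenario = SyntheticScenario(
    n_transcripts=1000,
    n_up_cold=30, n_down_cold=30, n_up_des=30, n_down_des=30,
    n_constant=50,
    field_stress_levels=(0.2, 0.5, 0.8),
    seed=1,
)

lab, truth = simulate_lab_experiment(scenario)
field = simulate_field_samples(scenario, lab, truth, stressor="cold")
hits = simulate_identity_hits(truth, n_decoys=200, seed=scenario.seed)

print(f"lab matrix: {lab.values.shape[0]} transcripts x {lab.values.shape[1]} samples")
print("conditions:", lab.samples["condition"].value_counts().to_dict())
print("truth composition:", truth.labels.value_counts().to_dict())
print(f"field matrix: {field.values.shape[1]} replicates at latent stress "
      f"{scenario.field_stress_levels}")
print(f"identity hits: {len(hits)} rows ({200} decoys straddling the "
      "98% / 1e-50 retention thresholds)")

# The truth composition shows the planted structure the later stages must
# recover: each count class is exact, and 'dual' transcripts (regulated by
# both stressors) exist so the dataset-1 vs dataset-2 distinction matters.
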