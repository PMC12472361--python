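"""Compare whole marker-set expression profiles between lab and field.

Builds dataset 1 (single-stressor markers only) over lab control + cold
replicates and field samples simulated at high latent cold stress, then
runs Bray-Curtis / Ward.D2 / SIMPROF to ask which groupings are
statistically real.
"""

from gmindex import (
    DatasetSpec,
    RunConfig,
    build_dataset,
    normalize_relative,
    render_newick,
    run_pipeline,
    simprof,
)

config = RunConfig(
    out_dir="scratch/example_run",
    seed=0,
    scenario=dict(
        n_transcripts=300,
        n_up_cold=12, n_down_cold=12, n_up_des=12, n_down_des=12,
        n_constant=25,
        field_stress_levels=[0.9, 0.9, 0.9],  # strongly cold-stressed field
    ),
    n_expected=199, n_simulated=199,
)
results = run_pipeline(config)

dataset = build_dataset(
    results["catalog"],
    normalize_relative(results["field_table"]),
    results["lab"],
    DatasetSpec("dataset1", "cold"),
)
result = simprof(dataset, n_expected=199, n_simulated=199, seed=0)

print(f"root split p-value: {result.dendrogram.p_value:.4f}")
print("SIMPROF clusters (groups with no significant internal structure):")
for cluster in result.clusters:
    print("  -", ", ".join(cluster))
print()
print("newick with p-value annotations:")
print(render_newick(result.dendrogram, result))

# With the field samples generated at s=0.9, the cold-stressed field
# replicates group with the lab cold treatment, while the lab controls and
# the desiccation-stressed field samples fall elsewhere -- the in situ
# stress state is read off the cluster memberships.
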