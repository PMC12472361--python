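"""Evaluate gene marker indices on field samples with known latent stress.

First reproduces the published pair-combination counts from the per-site
marker catalog sizes, then shows the index's core property: on synthetic
field samples drawn at latent stress fraction s, the in-range median index
tracks 100 s.
"""

from gmindex import (
    SyntheticScenario,
    build_catalog,
    classify_regulation,
    compute_gmi_table,
    compute_pair_bounds,
    enumerate_pairs,
    find_constant,
    make_table4_fixture,
    normalize_relative,
    simulate_field_samples,
    simulate_lab_experiment,
    summarize_gmi,
)

print("pair combinations from the published per-site marker set sizes:")
for site, stressor in [("site1", "cold"), ("site3", "cold"), ("site1", "desiccation")]:
    catalog, _ = make_table4_fixture(site)
    n = len(enumerate_pairs(catalog, stressor))
    print(f"  {site} {stressor:12s} -> {n} pairs")
print()

levels = (0.0, 0.25, 0.5, 0.75, 1.0)
scenario = SyntheticScenario(
    seed=11, n_transcripts=500, n_up_cold=10, n_down_cold=10,
    n_up_des=0, n_down_des=0, overlap_fraction=0.0, n_constant=15,
    dispersion=0.005, n_replicates_per_condition=5,
    field_stress_levels=levels, library_size_range=(2e6, 2e6),
)
lab, truth = simulate_lab_experiment(scenario)
field = simulate_field_samples(scenario, lab, truth, "cold")

records_cold = classify_regulation(lab, "cold")
records_des = classify_regulation(lab, "desiccation")
constant = find_constant(records_cold, records_des, lab) & set(truth.ids_with_label("constant"))
catalog = build_catalog(records_cold, records_des, constant)

pairs = compute_pair_bounds(normalize_relative(lab), catalog, "cold")
table = compute_gmi_table(pairs, normalize_relative(field))
print(f"{len(pairs)} marker pairs evaluated per field sample")
print("latent stress s -> in-range median index (expected 100 s):")
for rep, s in enumerate(levels, start=1):
    sub = table[table["sample_id"] == f"field_site1_cold_{rep}"]
    in_range = sub[(sub["gmi"] >= 0) & (sub["gmi"] <= 100)]
    print(f"  s={s:4.2f}: median={in_range['gmi'].median():6.2f}  "
          f"({len(in_range)}/{len(sub)} pairs in range)")

summary = summarize_gmi(table)
print()
print(f"overall: {summary.n_in_range}/{summary.n_total} in range, "
      f"in-range mean {summary.in_range_mean:.1f}, SD {summary.in_range_sd:.1f}")

# At the endpoints (s=0, s=1) roughly half the indices drift just outside
# [0, 100] by noise, exactly as min-max normalization predicts; in between,
# the median recovers the latent stress fraction to within a few points.
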