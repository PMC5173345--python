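"""SRM peak areas to per-class molecular-species proportions.

Generates a small synthetic peak table (two tissues, three subjects, three
injections), gates it by signal-to-noise, closes each ganglioside class to
proportions, and averages injections first, then subjects — the aggregation
order used for group means.
"""

from gangliomics import annotation, quantify, simulate

config = simulate.GeneratorConfig(seed=4, subjects={"retina": 3, "plasma": 3})
records = simulate.generate_peak_table(config)
flagged = annotation.flag_detection(records)
print("S/N gate counts:", flagged["status"].value_counts().to_dict())

props = quantify.species_proportions(flagged)
subject_table, group_means = quantify.average_replicates(props)

# Per-tissue mean composition of GM3 — retina is dominated by 36:1/38:1,
# plasma by 34:1 (each row sums to 1 over the detected species).
for tissue in ("retina", "plasma"):
    top = group_means.loc[(tissue, "GM3")].sort_values(ascending=False)[:4]
    pretty = ", ".join(f"{s}={v:.2f}" for s, v in top.items())
    print(f"{tissue:7s} GM3: {pretty}")

# Species under 1% pooled for the colorscale display.
pooled = quantify.group_minor_species(group_means)
print(f"\ncolumns after pooling minor species: {list(pooled.columns)}")
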