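"""Generate a synthetic double-heterozygote hemisegment dataset.

Shows the generated table format (what the classifier consumes), the pooled
defect fractions per genotype, and how the double heterozygote's rate
exceeds additivity by the configured delta.
"""

from cardiodiv import (
    generate_dataset,
    genotype_table,
    interaction_config,
    summarize_embryos,
)

cfg = interaction_config(delta=0.10, seed=3, embryos_per_genotype=16,
                         hemisegments_per_embryo=12)
table = generate_dataset(cfg)
print("first rows of the generated hemisegment table:")
print(table.head(4).to_string(index=False))

pooled = genotype_table(summarize_embryos(table))
print("\npooled defect fractions per genotype:")
print(pooled.pivot(index="genotype", columns="category",
                   values="fraction").round(3).to_string())
print("\nconfigured probabilities (double = p_A + p_B - p_0 + delta):")
for g, p in cfg.probabilities.items():
    print(f"  {g:<11} {p}")
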