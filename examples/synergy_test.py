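"""Detect a synergistic (super-additive) genetic interaction.

Simulates a double-heterozygote assay in which the double mutant's
symmetric-division defect rate exceeds the additive expectation by
delta = 0.12, then tests H0: beta3 = 0 in the no-intercept model
Y = b1*I_n + b2*I_M + b3*I_n*I_M + e with the Smith-orthogonalization
permutation test (one p-value per defect category).
"""

from cardiodiv import (
    CATEGORIES,
    generate_dataset,
    interaction_config,
    interaction_test,
    summarize_embryos,
)

cfg = interaction_config(delta={"symmetric": 0.12}, seed=42,
                         embryos_per_genotype=16, hemisegments_per_embryo=12)
summaries = summarize_embryos(generate_dataset(cfg))

# the three-genotype contrast: single het A, single het B, double het
sub = summaries[summaries["genotype"] != "wild_type"]
i_n = sub["genotype"].isin(["het_a", "double_het"]).to_numpy(int)
i_m = sub["genotype"].isin(["het_b", "double_het"]).to_numpy(int)

print(f"{'category':<12} {'beta3':>9} {'p-value':>10}  (N = 99,999 permutations)")
for i, category in enumerate(CATEGORIES):
    res = interaction_test(sub[f"prop_{category}"].to_numpy(), i_n, i_m,
                           n_permutations=99_999, seed=100 + i)
    print(f"{category:<12} {res.observed_stat:>9.4f} {res.p_value:>10.5f}")
# beta3 estimates the super-additive excess of the double heterozygote's
# defect proportion; a small p-value for 'symmetric' (where the synergy was
# simulated) and large ones elsewhere is the expected read-out.
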