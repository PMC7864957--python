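"""Score cardiac cell-division defects from per-hemisegment cell counts.

Builds a tiny count table for two embryos, classifies each hemisegment
against the wild-type (4 Tin-CC, 2 Svp-CC, 2 Svp-PC) configuration and
prints the per-embryo proportions and the pooled per-genotype fractions.
"""

import pandas as pd

from cardiodiv import genotype_table, summarize_embryos

rows = [
    # embryo e1, wild-type pattern except one hemisegment with 5 Tin-CCs
    # (a symmetric-division error) and one with a 3/1 Svp-CC/Svp-PC
    # imbalance (an asymmetric-division error)
    ("e1", "mut", 0, 4, 2, 2, False),
    ("e1", "mut", 1, 5, 2, 2, False),
    ("e1", "mut", 2, 4, 3, 1, False),
    ("e1", "mut", 3, 4, 2, 2, False),
    # embryo e2, one hemisegment with a single complete Svp pair
    # (an error in the earlier, precursor-number-determining division)
    ("e2", "mut", 0, 4, 1, 1, False),
    ("e2", "mut", 1, 4, 2, 2, False),
    ("e2", "mut", 2, 4, 2, 2, False),
    ("e2", "mut", 3, 4, 2, 2, False),
]
table = pd.DataFrame(
    rows,
    columns=["embryo_id", "genotype", "hemisegment_index", "tin_cc", "svp_cc",
             "svp_pc", "enlarged_svp_cc"],
)

per_embryo = summarize_embryos(table)
print("per-embryo defect proportions:")
print(per_embryo[["embryo_id", "scored", "prop_asymmetric", "prop_symmetric",
                  "prop_earlier"]].to_string(index=False))

print("\npooled per-genotype fractions (defective / scored hemisegments):")
print(genotype_table(per_embryo).to_string(index=False))
# Each proportion is (defective hemisegments) / (scored hemisegments); the
# pooled fraction weights embryos by how many hemisegments they contribute.
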