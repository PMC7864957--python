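"""Relative transcript quantification by the comparative-Ct (2^-ddCt) method.

A knockdown condition whose target Ct comes up ~1.3 cycles later than the
control (at equal reference-gene Ct) has ~2^-1.3 ~ 0.41-fold expression.
"""

import pandas as pd

from cardiodiv import quantify_table

rows = []
for cond, target_ct in (("control", 24.1), ("knockdown", 25.4)):
    for rep, jitter in enumerate((-0.2, 0.0, 0.2)):
        rows.append({"condition": cond, "gene": "neb", "replicate": rep,
                     "ct": target_ct + jitter})
        rows.append({"condition": cond, "gene": "rp49", "replicate": rep,
                     "ct": 18.0 + jitter})

result = quantify_table(pd.DataFrame(rows), reference_gene="rp49",
                        control_condition="control")
print(result[["gene", "condition", "delta_delta_ct", "fold_change", "fold_lo",
              "fold_hi"]].to_string(index=False))
# fold_change = 2^-ddCt; the [fold_lo, fold_hi] interval propagates the
# replicate standard deviations of target and reference Cts.
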