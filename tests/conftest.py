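import numpy as np
import pandas as pd
import pytest

from cardiodiv import HemisegmentObservation


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def make_obs(embryo_id, tin, svp_cc, svp_pc, flag=False, genotype="wt", index=0):
    return HemisegmentObservation(
        embryo_id=embryo_id,
        genotype=genotype,
        hemisegment_index=index,
        tin_cc=tin,
        svp_cc=svp_cc,
        svp_pc=svp_pc,
        enlarged_svp_cc=flag,
    )


def hemisegment_frame(rows):
    """Build a hemisegment table from (embryo, genotype, tin, svp_cc, svp_pc, flag)."""
    return pd.DataFrame(
        [
            {
                "embryo_id": e,
                "genotype": g,
                "hemisegment_index": i,
                "tin_cc": t,
                "svp_cc": sc,
                "svp_pc": sp,
                "enlarged_svp_cc": f,
            }
            for i, (e, g, t, sc, sp, f) in enumerate(rows)
        ]
    )
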