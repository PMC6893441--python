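"""Relative qPCR quantification with the ddCt method.

A treated condition whose target Ct drops by two cycles (housekeeping
unchanged) corresponds to a four-fold induction: fold = 2^-ddCt.
"""

import pandas as pd

from regulon_coupler import CtTable, ddct_fold_change

table = CtTable(
    pd.DataFrame(
        [
            ["s1", "VC", "ABCA1", 25.0],
            ["s2", "TRT", "ABCA1", 23.0],
            ["s1", "VC", "HPRT1", 20.0],
            ["s2", "TRT", "HPRT1", 20.0],
        ],
        columns=["sample_id", "condition", "gene", "ct"],
    ),
    housekeeping="HPRT1",
)
fold = ddct_fold_change(table, target="ABCA1", treated="TRT", reference="VC")
print(f"ABCA1 fold change (TRT vs VC) = {fold:.1f}")
# dCt(TRT) = 23 - 20 = 3; dCt(VC) = 25 - 20 = 5; ddCt = -2; fold = 2^2 = 4
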