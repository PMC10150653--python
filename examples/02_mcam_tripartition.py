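"""Tri-partition cells by MCAM expression within a group.

Cells with no detectable MCAM are marked neg; the remaining expressers are
ranked and split into two equal halves (low, then high), with the extra
cell of an odd count joining the low half.  The printout shows the rule on
seven cells, four of them expressing.
"""

import pandas as pd

from emtstrat import mcam_tripartition

mcam = pd.Series(
    {"c1": 0.0, "c2": 0.0, "c3": 0.4, "c4": 1.2, "c5": 0.0, "c6": 3.3, "c7": 0.9}
)
groups = pd.Series("malignant", index=mcam.index)

result = mcam_tripartition(mcam, groups)
for obs in mcam.index:
    print(f"{obs}: MCAM={mcam[obs]:.1f} -> {result['mcam_class'].loc[obs]}")
counts = result["mcam_class"].value_counts()
print(f"\nneg={counts['neg']}, low={counts['low']}, high={counts['high']} "
      "(4 expressers split 2/2; an odd count would put the extra cell in low).")
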