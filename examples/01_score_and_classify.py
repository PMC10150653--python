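"""Score the 12-gene EMT signature on a tiny hand-built matrix and classify.

Three cells are constructed at the epithelial end, the middle, and the
mesenchymal end of the spectrum; the printed sEMT values (sum of the six
mesenchymal markers minus the sum of the six epithelial markers) and the
low/med/high classes show how the fixed per-cell boundaries (0 and 5)
carve up the spectrum.
"""

import numpy as np

from emtstrat import (
    EMT_EPITHELIAL_GENES,
    EMT_MESENCHYMAL_GENES,
    ExpressionMatrix,
    SignatureRegistry,
    ThresholdConfig,
    classify_emt,
    score_all,
)

genes = list(EMT_MESENCHYMAL_GENES) + list(EMT_EPITHELIAL_GENES)
#                     mesenchymal x6   epithelial x6
cells = {
    "epithelial_like": [0.1] * 6 + [1.5] * 6,   # sEMT = 0.6 - 9.0 = -8.4
    "hybrid_like":     [0.6] * 6 + [0.2] * 6,   # sEMT = 3.6 - 1.2 =  2.4
    "mesenchymal_like": [1.4] * 6 + [0.1] * 6,  # sEMT = 8.4 - 0.6 =  7.8
}
matrix = ExpressionMatrix(
    obs_ids=list(cells),
    gene_ids=genes,
    values=np.array(list(cells.values())),
    scale="log_normalized",
    obs_kind="cell",
)

scores = score_all(matrix, SignatureRegistry.with_defaults())
strata = classify_emt(scores, ThresholdConfig.cell_defaults())

print("cell                 sEMT   class")
for obs in matrix.obs_ids:
    print(f"{obs:<20} {scores.scores['sEMT'].loc[obs]:>5.1f}   "
          f"{strata['emt_class'].loc[obs]}")
print("\nHigher sEMT = more mesenchymal; class low is sEMT<0, med is [0,5), "
      "high is >=5.")
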