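"""Expression utilities: CPM, group log2 fold change, and qPCR 2^-ddCt.

A toy feather-bulb count table contrasts black- and white-feathered birds:
the candidate pigment gene is silenced in white feathers, which shows up
as a large negative log2 fold change (white vs black) and a near-zero
2^-ddCt relative expression in the qPCR confirmation.
"""

import pandas as pd

from plumagemap import expr

counts = pd.DataFrame(
    {
        "black_1": [900, 40, 210], "black_2": [1100, 55, 190], "black_3": [950, 35, 205],
        "white_1": [2, 42, 200], "white_2": [0, 58, 195], "white_3": [3, 38, 215],
    },
    index=["PMEL-like", "bystander_1", "bystander_2"],
)
c = expr.cpm(counts)
fc = expr.group_log2fc(c, ["white_1", "white_2", "white_3"], ["black_1", "black_2", "black_3"])
print("log2 fold change (white vs black feather bulbs):")
print(fc.round(2).to_string())

# qPCR confirmation: candidate gene CT in white birds ~8 cycles later than
# black (calibrator), reference gene unchanged.
fold = expr.ddct_fold(ct_target=[33.8, 34.1, 33.9], ct_reference=[20.1, 20.0, 20.2],
                      ct_target_calibrator=[25.9, 26.1, 26.0], ct_reference_calibrator=[20.0, 20.1, 19.9])
print(f"\nqPCR 2^-ddCt, white relative to black: {fold:.4f}")
print("(~0.004x: the candidate gene is effectively off in white feather bulbs)")
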