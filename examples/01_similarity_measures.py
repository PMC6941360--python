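"""Compare the three mixed-type similarity measures on a small table.

Builds a toy attribute table with a rare Boolean function flag, a
categorical cluster label and a continuous profile, then prints a few
pairwise similarities under Gower, Wilson and the frequency-aware
measure. Watch the pair sharing the *rare* TRUE flag: only the
frequency-aware measure rewards it.
"""

import numpy as np
import pandas as pd

from dimr import AttributeTable, build_matrix

values = pd.DataFrame(
    {
        "flag_plurip": [True, True, False, False, False, False],
        "prox_clust": ["c1", "c1", "c1", "c2", "c2", "c2"],
        "eb_profile": [0.1, 0.3, 0.2, 1.8, 2.1, 1.6],
    },
    index=[f"g{i}" for i in range(1, 7)],
)
table = AttributeTable(values, types={"flag_plurip": "categorical",
                                      "prox_clust": "categorical",
                                      "eb_profile": "continuous"})

print("attribute table:")
print(values, "\n")

for measure in ("gower", "wilson", "dimrs"):
    S = build_matrix(table, measure).S
    print(f"{measure:>6}:  s(g1,g2)={S[0, 1]:.3f}  "
          f"s(g3,g4)={S[2, 3]:.3f}  s(g5,g6)={S[4, 5]:.3f}")

print(
    "\nWithin each measure, compare the rare-flag pair (g1,g2) with the\n"
    "frequent-values pair (g5,g6): the frequency-aware measure (dimrs)\n"
    "separates them most strongly, because a shared *rare* TRUE flag\n"
    "contributes 1 - 2*1/30 = 0.93 while a shared frequent level\n"
    "contributes much less; Gower scores every exact match 1 (and drops\n"
    "FALSE/FALSE flag pairs entirely), so it cannot reward rarity."
)
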