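"""Compute a three-attribute Hill-number diversity profile for two plots.

Builds a tiny community by hand — counts, traits, and a phylogeny — and
prints the effective number of taxonomic, functional, and phylogenetic
entities at q = 0, 1, 2.
"""

import numpy as np
import pandas as pd

from divgrad import CommunityMatrix, TraitTable, diversity_profile, parse_newick

cm = CommunityMatrix(
    plots=("ridge", "valley"),
    taxa=("Inga_alba", "Protium_nodulosum", "Iriartea_deltoidea"),
    counts=np.array([[12, 3, 1], [2, 2, 2]]),
)
traits = TraitTable(pd.DataFrame(
    {"SLA": [14.2, 9.8, 21.5], "LT": [0.21, 0.33, 0.18],
     "WD": [0.62, 0.71, 0.38]},
    index=cm.taxa,
))
tree = parse_newick(
    "((Inga_alba:60,Protium_nodulosum:60):40,Iriartea_deltoidea:100);")

profile = diversity_profile(cm, traits, tree)
print(profile.pivot_table(index=["attribute", "q"], columns="plot",
                          values="value").round(2))
print()
print("TD counts equally abundant taxa; FD counts maximally distinct")
print("functional types (pairwise Gower distances); PD is effective total")
print("branch length (q=0 equals Faith's PD). The even 'valley' plot beats")
print("the dominated 'ridge' plot at q >= 1 even with identical richness.")
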