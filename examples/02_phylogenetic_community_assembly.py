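"""NRI/NTI: are the taxa in a sample phylogenetically clustered?

Builds a pure-birth tree, assembles one community from a single clade
(clustered) and one spread over the whole tree (overdispersed), and compares
their MPD standardized effect sizes under the taxon-label-shuffle null.
"""

import numpy as np
import pandas as pd

from mgomics import FeatureTable, cophenetic_matrix, ses_phylo, simulate_tree

tree = simulate_tree(n_tips=24, seed=7)
dmat = cophenetic_matrix(tree)
ids = list(dmat.ids)

# clustered community: the 6 tips closest to the first tip
order = np.argsort(dmat.data[0])
clustered = [ids[i] for i in order[:6]]
# dispersed community: 6 tips maximising spread (every 4th by distance rank)
dispersed = [ids[i] for i in order[::4][:6]]

presence = pd.DataFrame(0.0, index=["clustered", "dispersed"], columns=ids)
presence.loc["clustered", clustered] = 1
presence.loc["dispersed", dispersed] = 1
table = FeatureTable(presence, feature_kind="taxon_cluster")

res = ses_phylo(table, dmat, statistic="mpd", n_null=999, seed=1)
print(res.table[["observed", "null_mean", "null_sd", "ses", "index_value",
                 "rank_p"]].round(3))
print("\nindex_value is the Net Relatedness Index (NRI = -SES of MPD):")
print("positive = taxa closer on the tree than the null expects (clustering),")
print("negative = more spread out (overdispersion); rank_p near 1/(n_null+1)")
print("marks significant clustering.")
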