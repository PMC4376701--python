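"""Cluster samples on ratio profiles and fit the multivariate regression tree.

The 36 pairwise expression ratios are clustered with 1 - Spearman
correlation and UPGMA linkage; cutting at k=2/k=4 and majority-voting the
histology labels the pathway groups.  A multivariate regression tree on
the one-hot group response then reveals which few ratios carry the
classification.
"""

from pearlsex import SimConfig, cut_and_label, fit_mrt, simulate_ct
from pearlsex.features import hierarchical_cluster, ratio_features, spearman_distance
from pearlsex.mrt import MRTParams, variance_partition
from pearlsex.qpcr import relative_expression

ct, meta = simulate_ct(SimConfig(seed=1))
feat = ratio_features(relative_expression(ct))

dendro = hierarchical_cluster(spearman_distance(feat))
assign = cut_and_label(dendro, meta)
print("cluster sizes:", assign.assignments["label"].value_counts().to_dict())

tree = fit_mrt(feat.values, assign.assignments["label"], MRTParams(seed=1))
print("\n" + tree.render())
print("\nvariance partition:")
print(variance_partition(tree).to_string(index=False))
# A four-leaf tree with relative error 0 explains 100% of the response
# variance using three ratio features; each split's share of the root
# sum of squares is listed in the partition table.
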