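"""qPCR QC: amplification efficiency, reference stability, group ANOVA.

Checks a primer pair's efficiency from a dilution series, ranks candidate
reference genes with the NormFinder-style decomposition, and compares a
target gene's relative expression across gonad categories with one-way
ANOVA + Tukey letters.
"""

import pandas as pd

from pearlsex import SimConfig, simulate_ct
from pearlsex.qpcr import group_comparison, normfinder_stability, pcr_efficiency, relative_expression

# 1. amplification efficiency from a standard curve (QC gate: 90-110%)
series = [(d, 30.0 - 3.4 * d) for d in (-4, -3, -2, -1, 0)]
eff = pcr_efficiency("foxl2", series)
print(f"foxl2 slope {eff.slope:.3f} -> E = {eff.efficiency_percent:.1f}% "
      f"({'pass' if eff.in_range else 'FAIL'})")

# 2. reference stability on a screening panel (lower = more stable)
ct, meta = simulate_ct(SimConfig(seed=1))
groups = meta.set_index("sample_id")["true_class"]
panel = ["ef1a", "gapdh1", "foxl2", "c43476", "c54338", "fem1-like"]
for r in normfinder_stability(ct, groups, candidate_genes=panel):
    print(f"  {r.gene_id:16s} stability {r.stability:.3f}")

# 3. group comparison of one target gene
rel = relative_expression(ct)
stats = group_comparison(rel, groups, "foxl2")
print("\nfoxl2 by pathway class (mean +/- sd, Tukey letter):")
print(stats.summary.to_string())
print(f"ANOVA F = {stats.anova_f:.1f}, p = {stats.anova_p:.2e}")
# Groups sharing no letter differ significantly at alpha = 0.05; the
# last stability row is the best reference pair.
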