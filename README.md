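# pearlsex

Molecular signatures of the sexual pathway in the pearl-oyster gonad.

The black-lip pearl oyster *Pinctada margaritifera* is a protandrous
hermaphrodite: individuals mature as males and may later switch to
female. Histology alone cannot tell which developmental trajectory —
**male pathway (MP)**, **female pathway (FP)**, or their *early*
variants **eMP/eFP** covering regressed and undifferentiated gonads — a
gonad is engaged on, because the molecular program precedes any visible
germ cells. `pearlsex` implements a dual histo-molecular analysis that
goes from raw expression data to a pathway call per animal, for
reproductive biologists and hatchery geneticists who need to sex oysters
(or similar hermaphroditic bivalves) from gonad expression data.

The pipeline has five stages, each usable on its own:

1. **Stringent differential expression** (`pearlsex.de`) — median-of-ratios
   size factors s_j, an exact negative-binomial test conditioned on the
   per-contig total (Var = μ + αμ², method-of-moments dispersion α),
   Benjamini–Hochberg FDR, and the stringent filter *FoldChange > 10 or
   < 0.1 and padj < 0.001*. Candidate markers are the contigs selected in
   **all five** contrasts of gametogenic males against each
   female-pathway category (M vs F, FR, MRF, UndF, InvF).
2. **qPCR quantification** (`pearlsex.qpcr`) — relative expression
   2^−ΔCt with the two-reference combination (mean of ef1a/gapdh1 Cts =
   geometric mean on the expression scale), amplification-efficiency QC
   (E = (10^(−1/slope) − 1) × 100, gate 90–110%), NormFinder-style
   reference stability, and one-way ANOVA with Tukey compact letters.
3. **Ratio features and clustering** (`pearlsex.features`) — all
   C(9,2) = 36 pairwise expression ratios (scale-free per sample),
   1 − Spearman correlation distance on log2 ratio profiles, UPGMA
   dendrograms, and majority-vote labeling of the k=2 / k=4 cuts.
4. **Multivariate regression tree** (`pearlsex.mrt`) — CART on the
   one-hot class response: splits maximize the reduction ΔSS of the
   multivariate sum of squares, with weakest-link cost-complexity
   pruning, stratified k-fold cross-validation and size selection
   (minimum CV error / one-SE / fixed leaf count).
5. **Fixed 3-gene-pair classifier** (`pearlsex.pathway`) — the decision
   rule distilled from the tree:

   ```
   c43476/fem1-like < 0.02              ->  MP
   else  foxl2/c54338  >= 12.2          ->  FP
   else  foxl2/fem1-like >= 0.1         ->  eFP,  otherwise eMP
   ```

   Ratios cancel per-sample scale, so the same rules run on qPCR 2^−ΔCt
   values and on normalized RNAseq counts.

A seeded synthetic-data module (`pearlsex.simulate`) generates NB count
matrices with nine planted pathway markers and qPCR Ct tables whose four
classes are separable by the three signature ratios, so the whole chain
is testable end-to-end without any external data.

## Worked example

```python
from pearlsex import SimConfig, simulate_ct, fit_mrt, cut_and_label
from pearlsex.features import hierarchical_cluster, ratio_features, spearman_distance
from pearlsex.mrt import MRTParams
from pearlsex.qpcr import relative_expression

ct, meta = simulate_ct(SimConfig(seed=1))          # 44 samples x 11 genes
feat = ratio_features(relative_expression(ct))     # 44 x 36 ratios
dendro = hierarchical_cluster(spearman_distance(feat))
assign = cut_and_label(dendro, meta)               # MP/FP/eMP/eFP groups
tree = fit_mrt(feat.values, assign.assignments["label"], MRTParams(seed=1))
print(tree.render())
```

prints

```
n = 44, classes = ['MP', 'eMP', 'FP', 'eFP']
Error: 0; CV Error: 0; SE: 0
c43476/fem1-like < 0.07679 (dSS 35.5% of total)
  yes: leaf [MP] n=12 (MP=12, eMP=0, FP=0, eFP=0)
  no:  foxl2/fem1-like < 0.303 (dSS 34.3% of total)
    yes: leaf [eMP] n=12 (MP=0, eMP=12, FP=0, eFP=0)
    no:  foxl2/c54338 < 18.42 (dSS 30.1% of total)
      yes: leaf [eFP] n=11 (MP=0, eMP=0, FP=0, eFP=11)
      no:  leaf [FP] n=9 (MP=0, eMP=0, FP=9, eFP=0)
```

A four-leaf tree with resubstitution error 0 — all of the multivariate
response variance explained — built from exactly the three signature
ratios: the first split isolates the twelve active males, the second
separates early-male from female-pattern gonads, the third splits active
females from the early female pathway. The thresholds (0.077, 0.30,
18.4) are data-driven midpoints lying between the class design levels.
`examples/` contains this and three more narrative scripts (marker
discovery, classifier calls, qPCR QC); a thin CLI (`pearlsex --help`)
exposes every stage as a subcommand.

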