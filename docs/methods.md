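# Methods

This note records the models, parameter choices and numerical
conventions behind `pearlsex`, and what the synthetic-data generators do
and do not emulate.

## Gonad categories and pathway classes

A gonad sample carries a histological description (sex as seen in
sections × gametogenic stage) and a molecular label describing its
expression pattern. The vocabulary has 18 labels; the consistency rules
(`pearlsex.types`) encode which histology each label admits — e.g. `MRF`
is a histologically regressed male with a female expression pattern, the
`Und*` labels require undetermined sex and carry no stage (we admit
`stage=none` for them rather than guessing a stage). Unknown labels are
rejected, never coerced: silent relabeling would corrupt the
majority-vote cluster labeling downstream.

The analysis target is the four-level **pathway class**: MP and FP for
gonads in active male/female gametogenesis, eMP and eFP for regressed or
undifferentiated gonads whose molecular pattern already commits them to
a pathway.

## Differential expression

*Normalization.* Median-of-ratios size factors: s_j = median over
contigs (restricted to contigs positive in every library) of
counts[i,j] / geomean_i. Factors are defined up to a common constant
(the geometric-mean reference); all downstream quantities are invariant
to that constant.

*Test.* For a two-condition comparison the per-contig dispersion α
(Var = μ + αμ²) is estimated by method of moments on normalized counts,
pooled across the two conditions after removing condition means, floored
at 1e-8. This is deliberately simpler than a fitted dispersion–mean
trend: at the ≥10-fold effects the selection filter targets, per-gene
moment estimates are adequate, and the choice keeps the test
self-contained and testable. The price is a small residual
anti-conservativeness (measured type-I error 0.048–0.064 at nominal
0.05 over 2000 null genes).

The test itself is exact and conditioned on the per-contig total
T = K_A + K_B: each condition total K_g is modelled as negative binomial
with mean q₀·s_g (q₀ the pooled concentration, s_g the summed size
factors) and moment-matched size r_g = s_g² / (α·Σ_{j∈g} s_j²), which
reproduces Var K_g = q₀ s_g + α q₀² Σ s_j² for unequal library factors.
The two-sided p-value sums the probabilities of all splits (a, T−a) no
more likely than the observed one, normalized by the total over splits;
at α → 0 this reduces to the conditional binomial (Poisson limit), which
the tests verify against an independent binomial oracle.

*Selection.* Benjamini–Hochberg step-up with stable tie handling;
stringent filter FoldChange > 10 or < 0.1 **and** padj < 0.001. A
contig with zero counts in one condition but signal in the other has an
infinite fold change and counts as passing the ">10" arm iff padj
clears α (it is the strongest possible tenfold signal); contigs zero in
both conditions are never selected. Candidate markers must survive all
five contrasts (M vs F, FR, MRF, UndF, InvF); survivors are classed by
directional tenfold rules on per-category mean normalized expression,
applied most-specific-first (eFP → F → FP → MP) so each gene gets
exactly one class.

*VST.* The display-scale transform is log2(normalized + 1), used only
for heatmap-style output and never for inference.

## qPCR quantification

Relative expression is 2^−(Ct_target − Ct_ref) with the reference Ct
being the arithmetic mean of the ef1a and gapdh1 Cts — equivalently the
geometric mean of the two single-reference expressions, the standard way
to combine two references. Technical replicate Cts are averaged
*before* the transform (averaging after would estimate a different,
upward-biased quantity). Amplification efficiency is assumed 100% in
the transform (plain base 2); the measured E from dilution-series slopes
is a QC gate only (90–110%). Cts outside [10, 40] warn but do not
error.

Reference stability follows the Andersen decomposition on log2
expression: per gene and group, the intergroup deviation d_ig (group
mean − gene grand mean, centered across genes within each group so a
global per-group shift — i.e. loading — cancels) and the unbiased
intragroup variance combine into
stability = mean_g(|d_ig| + sqrt(σ²_ig / n_g)); gene pairs are scored on
the per-sample average log2 signal. Two caveats are inherent to this
model and documented here because the tests respect them: (i) it
presumes a candidate-reference panel — with strongly regulated genes
included, the across-gene centering attributes part of their regulation
to every gene; (ii) the pair score rewards *counter-regulated* pairs
whose deviations cancel. The recovery test therefore screens the
references against the four signature genes and asserts they are the two
most stable single genes; best-pair recovery is tested on a panel
without counter-regulation.

Group comparisons: Shapiro–Wilk per group and Bartlett across groups are
reported as QC flags (not gates); one-way ANOVA; Tukey HSD at α = 0.05
(statsmodels); compact letter display via insert-and-absorb with
alphabetical letters in first-appearance order, so two categories share
a letter iff their Tukey comparison is non-significant.

## Ratio features and clustering

For the canonical gene order (foxl2, c43476, c45042, c19309, c54338,
vit6, zglp1, dmrt, fem1-like) every unordered pair {A, B} with A first
yields the feature A/B; nine genes give exactly 36 features.
Denominators below 1e-12 are floored with a logged warning. Ratios are
kept on the raw scale for the tree and classifier (whose thresholds live
on that scale) and log2-transformed for correlation and clustering
(symmetry of A/B vs B/A).

Sample distance is 1 − Spearman ρ between log2 ratio profiles (average
ranks for ties; a constant profile is an error naming the sample).
Linkage is UPGMA by default (complete and Ward available), computed by
scipy; tie handling follows scipy's deterministic ordering. Cutting at
k = 2 labels the two main clusters male/female pathway by majority
histological sex among gametogenic (early/intermediate/mature) members;
within each, the k = 4 sub-cluster with the larger fraction of
regressed/undetermined samples becomes the early variant. Votes that
tie, clusters that fail to split 2+2, or two clusters voting the same
sex raise errors demanding manual labels — no silent choice.

## Multivariate regression tree

Response: one-hot indicator matrix of the K classes; node impurity: the
total sum of squares about the node mean vector (for one-hot responses
this equals n·Gini, so the MRT specializes CART classification).
Candidate thresholds are midpoints between consecutive distinct sorted
feature values; a split must satisfy minsplit ≤ node size, children ≥
minbucket, and ΔSS ≥ cp·SS(root). Routing: value < threshold goes
left, ≥ goes right.

**Tie-break.** Ratio features are log-linearly dependent
(A/B = (A/D)/(B/D)), so distinct features routinely induce the *same*
sample partition and hence identical ΔSS — ties are structural, not
numerical accidents. Breaking them by feature index would
deterministically prefer whichever gene happens to be named first.
Splits are therefore ranked by (1) ΔSS, (2) widest gap between the two
feature values bounding the threshold, measured on the log scale for
positive features so it is unit-free — the maximum-margin, most robust
boundary — then (3) lowest feature index and (4) lowest threshold. The
exhaustive-search oracle in the test suite implements the same
convention independently.

Defaults minsplit = 5, minbucket = 2, cp = 0.01, 10 CV folds: classical
tree defaults (minsplit = 20) cannot produce a four-leaf tree at the
n ≈ 10-per-class sample sizes this package targets, so smaller defaults
preserve the procedure's shape at small n; all are configurable.

Pruning is weakest-link: repeatedly collapse the internal node(s)
minimizing g(t) = (SS(t) − SS over t's leaves)/(|leaves| − 1), recording
cp = g/SS(root); this yields the nested subtree sequence with
non-decreasing cp and non-increasing size. Cross-validation is
stratified by class (round-robin within class after a seeded shuffle;
classes smaller than the fold count reduce it with a warning); each
fold's tree sequence is evaluated at the geometric means of consecutive
master-sequence cp values; cv_error is the summed held-out SS divided by
the full data's root SS, and cv_se is the standard deviation over folds
of the per-fold error estimates divided by √k. The CV convention is
reported in the output because tree-package conventions differ. Size
selection: `min_cv`, `one_se` (smallest tree within one SE of the
minimum), or `fixed_leaves(k)`.

The per-split variance partition ΔSS/SS(root) sums to
1 − relative error (conservation is asserted to 1e-9 relative
tolerance).

## Fixed rule set

The classifier applies, in order: r1 = c43476/fem1-like < 0.02 → MP
(strict, so a sample exactly at 0.02 is *not* male-pathway);
r2 = foxl2/c54338 ≥ 12.2 → FP (inclusive); r3 = foxl2/fem1-like ≥ 0.1 →
eFP else eMP. The orientation of the third rule — female side at or
above the critical value — follows the marker identities (foxl2 marks
the female program, fem1-like the male one) and is mirrored by the
synthetic class design; it is called out here because only the critical
value itself, not its side, is pinned by the source analysis. The
boundary of r3 is inclusive for eFP by symmetry with r2. Expressions
are floored at 1e-12 (logged) before ratios. Because all three
statistics are within-sample ratios, predictions are invariant to any
positive rescaling of a sample's expression vector — verified as a
property test — which justifies applying one rule set across platforms
(qPCR relative expression, normalized RNAseq counts), with the caveat
that cross-platform ratio comparability is assumed, not checked.

## Synthetic data

The generators define the study conditions for every recovery test.

*Counts* (`simulate_counts`): 2000 background contigs plus nine markers
over nine molecular categories (M 12, F 11, MR 3, FR 4, and 2 each of
MRF, UndF, InvF, UndM, InvM — 40 libraries; rare categories get two
libraries because a single library makes empirical tenfold rules
unstable at the default dispersion). Counts are NB with Var = μ + αμ²,
α = 0.1, baseline means log-uniform on [20, 200] (markers fixed at 50 to
bound the exact test's enumeration), library factors log-normal
(sd 0.3). Planted effects are graded — at the default log2 effect 4.0:
32× in large (n ≥ 4) contrast categories, 256× in the two-library
categories, 4096× in the categories that *define* a class (MRF/UndF for
eFP genes, F for F genes) — so every directional class rule separates by
≥ 64× on expectation and empirical tenfold ratios and exact-test
p-values stay clear of their thresholds at NB dispersion 0.1.
Background contigs have no class effect.

*Ct tables* (`simulate_ct`): the default design mirrors a 44-sample
histology set (ME/MI/MM/MR = 4/4/4/9, FE/FI/FM/FR = 3/4/2/8, Und = 6);
true classes are MP/FP for gametogenic males/females, eMP/eFP for
regressed gonads, and alternating eMP/eFP for the undetermined ones.
Two reference genes sit at Ct 19/21 with ±0.03-cycle inter-group wobble.
Only the four signature genes carry strong class effects; their log2
relative-expression class means were chosen by an explicit margin
analysis with three goals: (i) the three signature ratios hit the design
values (r1 = 0.005 in MP vs ~0.2–0.5 elsewhere; r2 = 50 in FP vs 2;
r3 = 1 in eFP vs 0.01 in eMP), each ≥ 4× from its rule threshold;
(ii) at every tree node the designed ratio is the unique
max-ΔSS/max-margin split — every "shadow" feature (gene-pair
combinations that separate the same partition, which exist by linear
dependence) keeps ≥ 1.3 log2 less margin than the designed winner;
(iii) the four classes remain separable after per-sample Gaussian Ct
noise (sd 0.25 cycles biological + 0.15 technical per replicate, two
replicates). The five other targets get small balanced class profiles
(≤ 0.3 log2, maximal in eMP so pairings with signature genes cannot
widen a shadow margin at the early-male node).

Measured recovery under these defaults (100 seeds): the selected tree
uses exactly the three designed ratios with four leaves in 99/100 and
has resubstitution error 0 in 100/100; the rule classifier reproduces
the true classes 44/44 at zero noise and in the large majority of noisy
seeds; UPGMA clustering recovers the four classes exactly at zero noise
and in 62/100 noisy seeds (rank-correlation clustering near class
boundaries is genuinely harder than the tree's axis-aligned splits — the
failing seeds typically split one pathway 3+1 and raise a loud error
rather than mislabel).

What the generators do **not** emulate: real library-size heterogeneity
beyond log-normal factors, dispersion–mean trends, correlated genes,
batch or plate effects, partial-efficiency amplification, or biological
within-category structure (stages inside a pathway differ only through
the mild profiles). Passing recovery tests therefore demonstrates
correctness of the algorithms under the stated statistical model, not
performance on real gonad data.

## Known limitations

- The NB exact test with moment dispersions is mildly anti-conservative
  (≤ 0.065 at nominal 0.05 in our calibration runs); with genome-scale
  multiplicity and the tenfold filter this does not affect selection,
  but the per-gene p-values should not be reused as calibrated
  single-test statistics.
- NormFinder-style scores are only meaningful on candidate-reference
  panels (see above).
- The published per-sample calls, the 1,937-contig count and the printed
  thresholds (0.02 / 12.2 / 0.1) derive from the study's own data, which
  are not bundled; the thresholds enter as fixed rule parameters, and
  recovery is demonstrated on the synthetic conditions instead.
- No missing-value handling and no surrogate splits in the tree; inputs
  must be complete.
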