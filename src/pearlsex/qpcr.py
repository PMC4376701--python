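"""qPCR relative expression, reference-gene QC and group comparisons.

Relative expression follows the 2^-dCt convention with two reference
genes, ef1a and gapdh1: replicate Cts are averaged first, the two
reference Cts are averaged per sample (equivalently, their geometric mean
on the expression scale), and each target's value is
2^-(Ct_target - Ct_reference).  Amplification efficiency E is a QC gate
computed from dilution-series slopes; the transform itself assumes E =
100% (plain base 2), matching standard practice for the dCt method.

Reference stability is scored by an Andersen-style ("NormFinder-style")
decomposition of log2 expression into intergroup deviations and
intragroup variances; group comparisons use one-way ANOVA with Tukey HSD
and a compact letter display, with Shapiro-Wilk and Bartlett checks
reported as QC flags.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import CtTable, RelExprTable

__all__ = [
    "EfficiencyResult",
    "StabilityResult",
    "GroupStats",
    "combine_references",
    "relative_expression",
    "pcr_efficiency",
    "normfinder_stability",
    "group_comparison",
    "compact_letter_display",
]

logger = logging.getLogger(__name__)


@dataclass
class EfficiencyResult:
    """Amplification efficiency from a standard-curve dilution series."""

    gene_id: str
    slope: float  # Ct vs log10 dilution
    efficiency_percent: float  # E = (10^(-1/slope) - 1) * 100
    in_range: bool  # 90 <= E <= 110


@dataclass
class StabilityResult:
    """Stability score of a candidate reference gene (or gene pair)."""

    gene_id: str  # single gene, or "geneA+geneB" for a pair
    intragroup_var: dict[str, float]
    intergroup_dev: dict[str, float]
    stability: float


@dataclass
class GroupStats:
    """Per-category summary of a one-way comparison of one gene."""

    gene_id: str
    summary: pd.DataFrame  # index: category; columns mean, sd, n, letter
    anova_f: float
    anova_p: float
    tukey_p: pd.DataFrame  # category x category matrix of pairwise p-values
    shapiro_p: dict[str, float] = field(default_factory=dict)
    bartlett_p: float = np.nan
    degenerate: bool = False


def _mean_ct(table: CtTable) -> pd.DataFrame:
    """Replicate-averaged Ct, samples x genes."""
    return table.records.pivot_table(
        index="sample_id", columns="gene_id", values="ct", aggfunc="mean", sort=False
    )


def combine_references(table: CtTable) -> pd.Series:
    """Per-sample combined reference Ct (arithmetic mean of the references).

    Averaging reference Cts equals taking the geometric mean of the
    single-reference expression values on the 2^-dCt scale.
    """
    refs = table.reference_genes
    if len(refs) < 1:
        raise ValueError("no reference genes declared")
    ct = _mean_ct(table)
    missing_cols = [g for g in refs if g not in ct.columns]
    if missing_cols:
        raise ValueError(f"reference genes never measured: {missing_cols}")
    sub = ct[refs]
    bad = sub.index[sub.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"missing reference measurement for samples: {bad}")
    return sub.mean(axis=1)


def relative_expression(table: CtTable) -> RelExprTable:
    """2^-dCt relative expression of every target gene in every sample.

    Technical replicate Cts are averaged before the transform.
    """
    ct = _mean_ct(table)
    ref = combine_references(table)
    targets = table.target_genes
    missing = ct[targets].isna()
    if missing.to_numpy().any():
        where = [
            (s, g)
            for s in ct.index
            for g in targets
            if bool(missing.loc[s, g])
        ]
        raise ValueError(f"missing target measurements: {where[:5]}")
    dct = ct[targets].sub(ref, axis=0)
    return RelExprTable(values=np.power(2.0, -dct))


def pcr_efficiency(
    gene_id: str, dilution_series: list[tuple[float, float]]
) -> EfficiencyResult:
    """Amplification efficiency from (log10 dilution, Ct) pairs.

    E = (10^(-1/slope) - 1) x 100; a primer pair passes QC when E lies in
    [90, 110]%.  A non-negative slope means no amplification and is an
    error.
    """
    if len(dilution_series) < 3:
        raise ValueError("need at least 3 dilution points")
    x = np.array([d for d, _ in dilution_series], dtype=float)
    y = np.array([c for _, c in dilution_series], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero-variance dilution levels")
    slope = float(np.polyfit(x, y, 1)[0])
    if slope >= 0:
        raise ValueError(f"{gene_id}: non-negative standard-curve slope {slope:.3g}")
    eff = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    return EfficiencyResult(gene_id, slope, eff, 90.0 <= eff <= 110.0)


def _log2_expression(data: CtTable | RelExprTable) -> pd.DataFrame:
    if isinstance(data, CtTable):
        # -Ct is log2 expression up to a per-sample loading constant; the
        # decomposition's per-group across-gene centering removes that
        # constant, so no reference normalization is applied here
        ct = _mean_ct(data)
        genes = data.target_genes + data.reference_genes
        return -ct[genes]
    return np.log2(data.values.clip(lower=1e-12))


def normfinder_stability(
    data: CtTable | RelExprTable,
    groups: dict[str, str] | pd.Series,
    candidate_genes: list[str] | None = None,
) -> list[StabilityResult]:
    """Andersen-style stability ranking of candidate reference genes.

    On log2 expression, per gene i and group g the unbiased intragroup
    variance s2_ig and the intergroup deviation d_ig (gene group mean
    minus gene grand mean, centered across genes within each group so a
    global per-group shift cancels) combine into

        stability(i) = mean_g ( |d_ig| + sqrt(s2_ig / n_g) ).

    Pair stabilities are computed on the per-sample average log2 signal of
    the two genes; results are sorted most-stable first and the best pair
    is appended.
    """
    x = _log2_expression(data)
    if candidate_genes is not None:
        x = x[candidate_genes]
    groups = pd.Series(groups)
    common = [s for s in x.index if s in groups.index]
    x = x.loc[common]
    grp = groups.loc[common]
    sizes = grp.value_counts()
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise ValueError(f"groups of size 1 not allowed: {bad}")
    if sizes.size < 2:
        raise ValueError("need at least 2 groups")
    if x.shape[1] < 3:
        raise ValueError("need at least 3 candidate genes")

    # per-group across-gene mean (removes a global group shift)
    group_gene_means = x.groupby(grp).mean()  # groups x genes
    grand_means = x.mean(axis=0)  # per gene
    dev = group_gene_means.sub(grand_means, axis=1)
    dev = dev.sub(dev.mean(axis=1), axis=0)  # center across genes per group

    def gene_stability(col: pd.Series, devs: pd.Series) -> tuple[float, dict, dict]:
        intravar, interdev = {}, {}
        terms = []
        for g, n_g in sizes.items():
            s2 = float(col[grp == g].var(ddof=1))
            d = float(devs[g])
            intravar[g] = s2
            interdev[g] = d
            terms.append(abs(d) + np.sqrt(max(s2, 0.0) / n_g))
        return float(np.mean(terms)), intravar, interdev

    results = []
    for gene in x.columns:
        stab, intra, inter = gene_stability(x[gene], dev[gene])
        results.append(StabilityResult(gene, intra, inter, stab))
    results.sort(key=lambda r: (r.stability, r.gene_id))

    best_pair: StabilityResult | None = None
    for g1, g2 in itertools.combinations(x.columns, 2):
        avg = (x[g1] + x[g2]) / 2.0
        davg = (dev[g1] + dev[g2]) / 2.0
        stab, intra, inter = gene_stability(avg, davg)
        cand = StabilityResult(f"{g1}+{g2}", intra, inter, stab)
        if best_pair is None or cand.stability < best_pair.stability:
            best_pair = cand
    if best_pair is not None:
        results.append(best_pair)
    return results


def compact_letter_display(
    categories: list[str], sig_pairs: set[frozenset[str]]
) -> dict[str, str]:
    """Letters such that two categories share a letter iff not significant.

    Insert-and-absorb: start with one letter group holding everything;
    for each significant pair split the groups containing both members;
    absorb redundant groups; assign letters alphabetically over groups
    ordered by their first category.  Deterministic in the category order.
    """
    cats = list(categories)
    groups: list[set[str]] = [set(cats)]
    for pair in sorted(sig_pairs, key=lambda p: sorted(p)):
        a, b = sorted(pair)
        new_groups: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                new_groups.extend([g - {a}, g - {b}])
            else:
                new_groups.append(g)
        # absorb: drop duplicates and strict subsets of another group
        groups = []
        for i, g in enumerate(new_groups):
            redundant = any(
                (g < h) or (g == h and i > j) for j, h in enumerate(new_groups) if i != j
            )
            if g and not redundant:
                groups.append(g)
    # order groups by first category appearance for stable letters
    order = {c: i for i, c in enumerate(cats)}
    groups.sort(key=lambda g: min(order[c] for c in g) if g else len(cats))
    letters: dict[str, str] = {c: "" for c in cats}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, g in enumerate(groups):
        for c in cats:
            if c in g:
                letters[c] += alphabet[i % len(alphabet)]
    return letters


def group_comparison(
    rel: RelExprTable,
    categories: dict[str, str] | pd.Series,
    gene: str,
    alpha: float = 0.05,
) -> GroupStats:
    """One-way ANOVA + Tukey HSD of one gene's relative expression.

    Shapiro-Wilk (per group) and Bartlett (across groups) p-values are
    reported as QC flags; the compact letter display encodes the Tukey
    significance pattern at the given alpha.
    """
    categories = pd.Series(categories)
    common = [s for s in rel.sample_ids if s in categories.index]
    vals = rel.values.loc[common, gene]
    grp = categories.loc[common]
    cats = list(dict.fromkeys(grp))
    sizes = grp.value_counts()
    if len(cats) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 categories with >= 2 samples each")

    arrays = [vals[grp == c].to_numpy(dtype=float) for c in cats]
    degenerate = all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1

    shapiro_p = {}
    for c, a in zip(cats, arrays):
        if np.ptp(a) > 0 and len(a) >= 3:
            shapiro_p[c] = float(stats.shapiro(a).pvalue)
        else:
            shapiro_p[c] = np.nan
    try:
        bartlett_p = float(stats.bartlett(*arrays).pvalue)
    except ValueError:
        bartlett_p = np.nan

    if degenerate:
        summary = pd.DataFrame(
            {
                "mean": [a.mean() for a in arrays],
                "sd": [a.std(ddof=1) for a in arrays],
                "n": [len(a) for a in arrays],
                "letter": ["a"] * len(cats),
            },
            index=cats,
        )
        tk = pd.DataFrame(1.0, index=cats, columns=cats)
        return GroupStats(gene, summary, np.nan, np.nan, tk, shapiro_p, bartlett_p, True)

    f_stat, p_val = stats.f_oneway(*arrays)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tuk = pairwise_tukeyhsd(vals.to_numpy(dtype=float), grp.to_numpy(), alpha=alpha)
    tk = pd.DataFrame(1.0, index=cats, columns=cats)
    sig_pairs: set[frozenset[str]] = set()
    res = tuk.summary().data[1:]
    for row in res:
        g1, g2, _, p_adj = str(row[0]), str(row[1]), row[2], float(row[3])
        tk.loc[g1, g2] = tk.loc[g2, g1] = p_adj
        if p_adj < alpha:
            sig_pairs.add(frozenset({g1, g2}))

    letters = compact_letter_display(cats, sig_pairs)
    summary = pd.DataFrame(
        {
            "mean": [a.mean() for a in arrays],
            "sd": [a.std(ddof=1) for a in arrays],
            "n": [len(a) for a in arrays],
            "letter": [letters[c] for c in cats],
        },
        index=cats,
    )
    return GroupStats(gene, summary, float(f_stat), float(p_val), tk, shapiro_p, bartlett_p)
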