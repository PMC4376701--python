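"""Stringent negative-binomial differential expression.

Count normalization uses the classic median-of-ratios size factors; the
two-condition test is an exact negative-binomial test conditioned on the
per-contig total (per-condition NB totals, all splits of the observed sum
whose probability does not exceed the observed split's are accumulated).
Per-contig dispersion comes from a pooled method-of-moments estimate —
adequate at the tenfold-and-up effect sizes the selection filter targets,
and documented as a deviation from trend-fitted dispersions.

A contig is *selected* when FoldChange > 10 or < 0.1 and the
Benjamini-Hochberg adjusted p-value is below 0.001; candidate markers are
the contigs selected in all five male-vs-female-pathway contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import CountMatrix, MarkerClass

__all__ = [
    "DEResult",
    "size_factors",
    "normalize",
    "vst",
    "nb_test",
    "bh_adjust",
    "stringent_filter",
    "candidate_intersection",
    "MARKER_CONTRASTS",
]

#: The five two-group contrasts whose intersection defines candidate
#: markers: gametogenic males against each female-pathway category.
MARKER_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("M", "F"),
    ("M", "FR"),
    ("M", "MRF"),
    ("M", "UndF"),
    ("M", "InvF"),
)

_DISPERSION_FLOOR = 1e-8


@dataclass
class DEResult:
    """Per-contig two-condition differential expression result."""

    contig_id: str
    baseMeanA: float
    baseMeanB: float
    foldChange: float  # baseMeanB / baseMeanA; inf when A == 0 < B; nan when both 0
    pval: float
    padj: float = np.nan


def size_factors(cm: CountMatrix) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    For each sample j, s_j is the median over contigs of
    counts[i, j] / geometric_mean_i, where the geometric-mean reference is
    computed only over contigs with no zero count in any sample.
    """
    counts = cm.counts.astype(float)
    if counts.size == 0 or np.all(counts == 0):
        raise ValueError("cannot compute size factors of an all-zero matrix")
    if np.any(counts.sum(axis=0) == 0):
        raise ValueError("every sample needs at least one nonzero count")
    positive = np.all(counts > 0, axis=1)
    if not np.any(positive):
        raise ValueError("no contig is positive in every sample; size factors undefined")
    ref = np.exp(np.mean(np.log(counts[positive]), axis=1))
    ratios = counts[positive] / ref[:, None]
    return np.median(ratios, axis=0)


def normalize(cm: CountMatrix) -> CountMatrix:
    """Return a copy with size factors and the normalized matrix filled in."""
    s = size_factors(cm)
    return CountMatrix(
        contig_ids=list(cm.contig_ids),
        sample_ids=list(cm.sample_ids),
        counts=cm.counts.copy(),
        size_factors=s,
        normalized=cm.counts / s[None, :],
    )


def vst(cm: CountMatrix) -> np.ndarray:
    """Display-scale variance-stabilized expression: log2(normalized + 1).

    Used for heatmap-style output only, never for testing; monotone in the
    counts.
    """
    if cm.normalized is None:
        cm = normalize(cm)
    return np.log2(cm.normalized + 1.0)


def _mom_dispersion(norm_counts: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Pooled method-of-moments NB dispersion per contig.

    Within each condition the condition mean is removed; residual variance
    pooled across conditions gives  alpha = (var - mean) / mean^2, floored.
    ``norm_counts`` is contigs x samples (normalized scale).
    """
    n_contigs = norm_counts.shape[0]
    ss = np.zeros(n_contigs)
    df = 0
    means_acc = np.zeros(n_contigs)
    n_tot = 0
    for idx in groups:
        x = norm_counts[:, idx]
        if x.shape[1] >= 2:
            mu = x.mean(axis=1, keepdims=True)
            ss += ((x - mu) ** 2).sum(axis=1)
            df += x.shape[1] - 1
        means_acc += x.sum(axis=1)
        n_tot += x.shape[1]
    grand_mean = means_acc / n_tot
    if df == 0:
        return np.full(n_contigs, _DISPERSION_FLOOR)
    var = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - grand_mean) / np.where(grand_mean > 0, grand_mean**2, 1.0)
    return np.maximum(alpha, _DISPERSION_FLOOR)


def _exact_nb_pvalue(
    k_a: int,
    k_b: int,
    s_a: float,
    s_b: float,
    ss_a: float,
    ss_b: float,
    q0: float,
    alpha: float,
) -> float:
    """Two-sided exact test of H0: equal concentration, conditioned on the sum.

    Under H0 the condition total K_g (sum of per-library NB counts with
    means q0*s_j and common dispersion alpha) is modelled as NB with mean
    q0*s_g and moment-matched size r_g = s_g^2 / (alpha * ss_g), where s_g
    and ss_g are the sum and sum of squares of the condition's size
    factors (Var K_g = q0 s_g + alpha q0^2 ss_g).  The p-value accumulates
    the probabilities of all splits (a, b) of T = k_a + k_b no more likely
    than the observed one, normalized by the total over all splits.
    """
    total = k_a + k_b
    if total == 0:
        return 1.0
    m_a, m_b = q0 * s_a, q0 * s_b
    a = np.arange(total + 1)
    if alpha <= _DISPERSION_FLOOR * 1.01:
        # Poisson limit: conditional law is Binomial(T, s_a / (s_a + s_b))
        logp = stats.binom.logpmf(a, total, s_a / (s_a + s_b))
    else:
        r_a = s_a**2 / (alpha * ss_a)
        r_b = s_b**2 / (alpha * ss_b)
        logp_a = stats.nbinom.logpmf(a, r_a, r_a / (r_a + m_a))
        logp_b = stats.nbinom.logpmf(total - a, r_b, r_b / (r_b + m_b))
        logp = logp_a + logp_b
    obs = logp[k_a]
    mx = logp.max()
    w = np.exp(logp - mx)
    keep = logp <= obs + 1e-12
    return float(min(1.0, w[keep].sum() / w.sum()))


def nb_test(
    cm: CountMatrix,
    condition_a: list[str],
    condition_b: list[str],
) -> list[DEResult]:
    """Exact conditioned NB test of every contig between two conditions.

    Returns one :class:`DEResult` per contig with per-condition mean
    normalized counts, the fold change meanB/meanA, and the two-sided
    p-value.  ``padj`` is left NaN; apply :func:`bh_adjust` downstream.
    """
    if not condition_a or not condition_b:
        raise ValueError("both conditions need at least one sample")
    cm = normalize(cm) if cm.normalized is None else cm
    idx = {s: i for i, s in enumerate(cm.sample_ids)}
    missing = [s for s in list(condition_a) + list(condition_b) if s not in idx]
    if missing:
        raise ValueError(f"samples not in count matrix: {missing}")
    ia = np.array([idx[s] for s in condition_a])
    ib = np.array([idx[s] for s in condition_b])

    norm = cm.normalized
    alpha = _mom_dispersion(norm[:, np.concatenate([ia, ib])], [np.arange(len(ia)), np.arange(len(ia), len(ia) + len(ib))])

    s = cm.size_factors
    s_a, s_b = float(s[ia].sum()), float(s[ib].sum())
    ss_a, ss_b = float((s[ia] ** 2).sum()), float((s[ib] ** 2).sum())
    results: list[DEResult] = []
    for i, contig in enumerate(cm.contig_ids):
        k_a = int(cm.counts[i, ia].sum())
        k_b = int(cm.counts[i, ib].sum())
        mean_a = float(norm[i, ia].mean())
        mean_b = float(norm[i, ib].mean())
        if k_a + k_b == 0:
            results.append(DEResult(contig, 0.0, 0.0, np.nan, 1.0))
            continue
        q0 = (k_a + k_b) / (s_a + s_b)  # pooled concentration under H0
        p = _exact_nb_pvalue(k_a, k_b, s_a, s_b, ss_a, ss_b, q0, float(alpha[i]))
        if mean_a == 0.0:
            fc = np.inf
        else:
            fc = mean_b / mean_a
        results.append(DEResult(contig, mean_a, mean_b, fc, p))
    return results


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Order-preserving with the input; ties broken stably by input order;
    monotonicity enforced by the running minimum from the largest p down.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def stringent_filter(
    results: list[DEResult],
    fc_hi: float = 10.0,
    fc_lo: float = 0.1,
    alpha: float = 0.001,
) -> list[str]:
    """Contigs passing the tenfold-change + padj filter.

    Keeps contigs with (foldChange > fc_hi or < fc_lo, infinite fold
    changes counting as the strongest '>10' signal) and padj < alpha.
    Contigs with zero counts in both conditions are never selected.
    """
    selected = []
    for r in results:
        if np.isnan(r.padj):
            raise ValueError("padj not computed; run bh_adjust first")
        if np.isnan(r.foldChange):
            continue
        fc_pass = r.foldChange > fc_hi or r.foldChange < fc_lo
        if fc_pass and r.padj < alpha:
            selected.append(r.contig_id)
    return selected


def attach_padj(results: list[DEResult]) -> list[DEResult]:
    """Fill the padj field of a result list in place (BH over all contigs)."""
    padj = bh_adjust(np.array([r.pval for r in results]))
    for r, q in zip(results, padj):
        r.padj = float(q)
    return results


def _group_means(cm: CountMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Mean normalized count per contig per molecular label."""
    cm = normalize(cm) if cm.normalized is None else cm
    cols = {s: i for i, s in enumerate(cm.sample_ids)}
    out = {}
    for lbl, sub in meta.groupby("molecular_label"):
        ids = [cols[s] for s in sub["sample_id"]]
        out[lbl] = cm.normalized[:, ids].mean(axis=1)
    return pd.DataFrame(out, index=cm.contig_ids)


_FP_SET = ("MRF", "UndF", "InvF", "F", "FR")
_EFP_SET = ("MRF", "UndF")
_MP_SET = ("UndM", "InvM", "M", "MR")


def _assign_class(means: pd.Series, fold: float = 10.0) -> MarkerClass | None:
    """Directional class rules on group means, most specific first.

    eFP: >= tenfold higher in MRF and UndF than every other category.
    F:   >= tenfold higher in gametogenic females than every other category.
    FP:  >= tenfold higher in each female-pathway category than in M.
    MP:  >= tenfold higher in each male-pathway category than in every
         female-pathway category.
    """
    eps = 1e-12
    cats = means.index

    def hi(group: tuple[str, ...], others: list[str]) -> bool:
        gmin = min(means[g] for g in group if g in cats)
        omax = max((means[o] for o in others if o in cats), default=0.0)
        return gmin >= fold * max(omax, eps)

    others_efp = [c for c in cats if c not in _EFP_SET]
    if all(g in cats for g in _EFP_SET) and hi(_EFP_SET, others_efp):
        return MarkerClass.eFP
    others_f = [c for c in cats if c != "F"]
    if "F" in cats and hi(("F",), others_f):
        return MarkerClass.F
    if "M" in cats and all(g in cats for g in _FP_SET):
        if min(means[g] for g in _FP_SET) >= fold * max(means["M"], eps):
            return MarkerClass.FP
    female_side = [c for c in cats if c in _FP_SET]
    male_present = [g for g in _MP_SET if g in cats]
    if male_present and female_side:
        if min(means[g] for g in male_present) >= fold * max(
            max(means[c] for c in female_side), eps
        ):
            return MarkerClass.MP
    return None


def candidate_intersection(
    cm: CountMatrix,
    meta: pd.DataFrame,
    fc_hi: float = 10.0,
    fc_lo: float = 0.1,
    alpha: float = 0.001,
) -> dict[str, MarkerClass]:
    """Candidate sexual-pathway markers by five-contrast intersection.

    Runs the exact NB test plus stringent filter for each of the five
    contrasts (M vs F, FR, MRF, UndF, InvF), intersects the selections,
    and assigns each surviving contig a marker class by the directional
    tenfold rules on per-category mean normalized expression.
    """
    needed = {"M"} | set(lbl for _, lbl in MARKER_CONTRASTS)
    present = set(meta["molecular_label"])
    absent = sorted(needed - present)
    if absent:
        raise ValueError(f"metadata missing molecular labels: {absent}")

    cm = normalize(cm)
    by_label = {lbl: list(sub["sample_id"]) for lbl, sub in meta.groupby("molecular_label")}
    common: set[str] | None = None
    for ref, other in MARKER_CONTRASTS:
        res = nb_test(cm, by_label[ref], by_label[other])
        attach_padj(res)
        sel = set(stringent_filter(res, fc_hi=fc_hi, fc_lo=fc_lo, alpha=alpha))
        common = sel if common is None else (common & sel)

    means = _group_means(cm, meta)
    out: dict[str, MarkerClass] = {}
    for contig in cm.contig_ids:
        if contig not in (common or set()):
            continue
        mclass = _assign_class(means.loc[contig])
        if mclass is not None:
            out[contig] = mclass
    return out
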