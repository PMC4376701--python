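"""Synthetic gonad RNAseq counts and qPCR Ct tables.

The generator reproduces the statistical *structure* the downstream
analysis assumes, so that every stage — stringent differential expression,
ratio features, clustering, the multivariate regression tree and the fixed
3-gene-pair classifier — can be exercised and its parameter recovery
verified without the original sequencing accession.

Two generators are provided:

``simulate_counts``
    Negative-binomial contig counts over the histo-molecular gonad
    categories, with nine planted marker genes whose class effects clear
    the tenfold differential-expression filter, plus class-neutral
    background contigs.

``simulate_ct``
    A qPCR cycle-threshold table emulating the 44-sample assay: two
    stable reference genes and nine targets whose derived 2^-dCt values
    place every sample in one of the four ratio-separable pathway classes
    (MP, FP, eMP, eFP).  Only the four signature genes (foxl2, c43476,
    c54338, fem1-like) carry strong class effects; the class-mean table
    was chosen so each of the three signature ratios is the unique best
    split of the corresponding regression-tree node (see docs/methods.md
    for the margin analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    CANONICAL_GENE_ORDER,
    REFERENCE_GENES,
    CountMatrix,
    CtTable,
    MarkerClass,
    PathwayClass,
)

__all__ = ["SimConfig", "simulate_counts", "simulate_ct", "MARKER_CLASSES", "DESIGNED_RATIOS"]

#: Planted marker class of each of the nine candidate genes.
MARKER_CLASSES: dict[str, MarkerClass] = {
    "foxl2": MarkerClass.FP,
    "c43476": MarkerClass.FP,
    "c45042": MarkerClass.FP,
    "c19309": MarkerClass.eFP,
    "c54338": MarkerClass.eFP,
    "vit6": MarkerClass.F,
    "zglp1": MarkerClass.F,
    "dmrt": MarkerClass.MP,
    "fem1-like": MarkerClass.MP,
}

#: The three gene-pair ratios the Ct generator designs its classes around.
DESIGNED_RATIOS: tuple[str, str, str] = (
    "c43476/fem1-like",
    "foxl2/c54338",
    "foxl2/fem1-like",
)

# ---------------------------------------------------------------------------
# RNAseq count design
# ---------------------------------------------------------------------------

# Default library design (molecular label, n libraries).  Rare categories
# get two libraries each: a single library per category makes empirical
# tenfold class-rule ratios unstable at NB dispersion 0.1.
DEFAULT_COUNT_DESIGN: tuple[tuple[str, int], ...] = (
    ("M", 12),
    ("MR", 3),
    ("MRF", 2),
    ("UndM", 2),
    ("InvM", 2),
    ("F", 11),
    ("FR", 4),
    ("UndF", 2),
    ("InvF", 2),
)

_MALE_SIDE = ("M", "MR", "UndM", "InvM")
_FEMALE_SIDE = ("F", "FR", "MRF", "UndF", "InvF")


def _count_effects(log2_effect: float) -> dict[str, dict[str, float]]:
    """Per-gene multiplicative class effects (by molecular label).

    The base effect ``e = 2**log2_effect`` (16x at the default 4.0) is the
    minimum planted separation; the categories that *define* a marker class
    (MRF/UndF for eFP genes, gametogenic F for F genes) get ``e**2`` so the
    four directional class rules stay mutually exclusive on expectation.
    """
    e = 2.0**log2_effect
    eff: dict[str, dict[str, float]] = {}
    # Levels are graded so every directional class rule separates by >= 64x
    # on expectation and every contrast group sits >= 32x (n >= 4 groups)
    # or >= 256x (n = 2 groups) from the male baseline: at NB dispersion
    # 0.1 this keeps empirical tenfold-rule ratios and exact-test p-values
    # clear of their thresholds.
    for gene, mclass in MARKER_CLASSES.items():
        if mclass is MarkerClass.FP:
            # high across the whole female pathway; extra in the rare
            # regressed/undetermined/inversion categories
            eff[gene] = {"F": 2 * e, "FR": 2 * e, "MRF": 16 * e, "UndF": 16 * e, "InvF": 16 * e}
        elif mclass is MarkerClass.eFP:
            # dominant in the early-female categories; the rest of the
            # female pathway still clears the tenfold contrast filter
            eff[gene] = {"MRF": 4 * e**3, "UndF": 4 * e**3, "InvF": 16 * e, "F": 2 * e, "FR": 2 * e}
        elif mclass is MarkerClass.F:
            eff[gene] = {"F": 4 * e**3, "MRF": 16 * e, "UndF": 16 * e, "InvF": 16 * e, "FR": 2 * e}
        else:  # MP
            eff[gene] = {lbl: 4 * e for lbl in _MALE_SIDE}
    return eff


# ---------------------------------------------------------------------------
# qPCR Ct design
# ---------------------------------------------------------------------------

# Histological design of the qPCR sample set (category, stage, n).
DEFAULT_QPCR_DESIGN: tuple[tuple[str, str, str, int], ...] = (
    # (label prefix, histo_sex, histo_stage, n)
    ("ME", "male", "early", 4),
    ("MI", "male", "intermediate", 4),
    ("MM", "male", "mature", 4),
    ("MR", "male", "regression", 9),
    ("FE", "female", "early", 3),
    ("FI", "female", "intermediate", 4),
    ("FM", "female", "mature", 2),
    ("FR", "female", "regression", 8),
    ("Und", "undetermined", "none", 6),
)

# log2 relative-expression class means of the four signature genes, per
# pathway class (MP, FP, eMP, eFP).  These fix the three signature ratios
# at  c43476/fem1-like = (0.005, 0.5, 0.2, 0.5),
#     foxl2/c54338     = (2, 50, 2, 2),
#     foxl2/fem1-like  = (~0.001, 8, 0.01, 1),
# i.e. MP sits below the 0.02 rule threshold on the first ratio, FP above
# 12.2 on the second, and eFP above 0.1 / eMP below it on the third, each
# with at least a fourfold margin.
_SIGNATURE_LOG2: dict[str, dict[PathwayClass, float]] = {
    "foxl2": {
        PathwayClass.MP: -6.64,
        PathwayClass.FP: 1.0,
        PathwayClass.eMP: -6.64,
        PathwayClass.eFP: -2.0,
    },
    "c43476": {
        PathwayClass.MP: 3.0 + float(np.log2(0.005)),  # r1 = 0.005 in MP exactly
        PathwayClass.FP: -3.0,
        PathwayClass.eMP: -2.32,
        PathwayClass.eFP: -3.0,
    },
    "c54338": {
        PathwayClass.MP: -7.64,
        PathwayClass.FP: 1.0 - float(np.log2(50.0)),  # r2 = 50 in FP exactly
        PathwayClass.eMP: -7.64,
        PathwayClass.eFP: -3.0,
    },
    "fem1-like": {
        PathwayClass.MP: 3.0,
        PathwayClass.FP: -2.0,
        PathwayClass.eMP: 0.0,
        PathwayClass.eFP: -2.0,
    },
}

# The five other target genes: small class effects (<= 0.3 log2), clearly
# less stable than the references for the stability ranking, yet far too
# small to compete with the signature ratios for tree splits (shadow-split
# margins keep >= 1.3 log2 slack to the designed winners).  The eMP entry
# of each profile is its maximum, which bounds the margin a pairing with a
# signature gene can gain at the early-male tree node by twice the profile
# amplitude.
_MILD_BASE_LOG2 = {"c45042": -3.0, "c19309": -4.0, "vit6": -2.0, "zglp1": -5.0, "dmrt": -4.5}
_MILD_PROFILE_LOG2: dict[str, dict[PathwayClass, float]] = {
    "c45042": {PathwayClass.MP: -0.3, PathwayClass.FP: 0.2, PathwayClass.eMP: 0.3, PathwayClass.eFP: -0.2},
    "c19309": {PathwayClass.MP: 0.2, PathwayClass.FP: -0.3, PathwayClass.eMP: 0.3, PathwayClass.eFP: 0.1},
    "vit6": {PathwayClass.MP: -0.2, PathwayClass.FP: 0.3, PathwayClass.eMP: 0.3, PathwayClass.eFP: -0.3},
    "zglp1": {PathwayClass.MP: 0.3, PathwayClass.FP: -0.2, PathwayClass.eMP: 0.3, PathwayClass.eFP: 0.2},
    "dmrt": {PathwayClass.MP: 0.2, PathwayClass.FP: 0.2, PathwayClass.eMP: 0.3, PathwayClass.eFP: -0.3},
}

#: Reference-gene baseline Ct values; the combined (mean) reference Ct is 20.
_REFERENCE_CT = {"ef1a": 19.0, "gapdh1": 21.0}
#: Small deterministic inter-group wobble of the references (cycles); kept
#: well below the mild targets' class effects so stability ranking favors
#: the references.
_REFERENCE_GROUP_WOBBLE = {
    "ef1a": {PathwayClass.MP: 0.03, PathwayClass.FP: -0.03, PathwayClass.eMP: 0.0, PathwayClass.eFP: 0.03},
    "gapdh1": {PathwayClass.MP: -0.03, PathwayClass.FP: 0.03, PathwayClass.eMP: 0.03, PathwayClass.eFP: -0.03},
}


@dataclass
class SimConfig:
    """Parameters of the synthetic-data generators.

    Attributes
    ----------
    seed
        Seed for all randomness (bit-identical outputs under a fixed seed).
    n_background_contigs
        Class-neutral contigs added to the count matrix (default 2000).
    count_design
        (molecular label, n libraries) pairs for the count generator.
    marker_log2_effect
        Minimum planted log2 fold effect of marker genes (default 4.0,
        i.e. 16-fold, comfortably above the tenfold selection filter).
    nb_dispersion
        NB dispersion alpha, with Var = mu + alpha * mu^2 (default 0.1).
    libsize_log_sd
        Log-normal sd of per-library size factors (default 0.3).
    baseline_mean_range
        Range of baseline contig means (log-uniform draw).
    qpcr_design
        (category, histo sex, histo stage, n samples) for the Ct generator;
        the default mirrors the 44-sample histology set.
    ct_noise_sd
        Biological (per-sample) Ct noise, cycles (default 0.25).
    ct_replicate_sd
        Technical replicate Ct noise, cycles (default 0.15).
    n_ct_replicates
        Technical qPCR replicates per (sample, gene).
    """

    seed: int = 0
    n_background_contigs: int = 2000
    count_design: tuple[tuple[str, int], ...] = DEFAULT_COUNT_DESIGN
    marker_log2_effect: float = 4.0
    nb_dispersion: float = 0.1
    libsize_log_sd: float = 0.3
    baseline_mean_range: tuple[float, float] = (20.0, 200.0)
    qpcr_design: tuple[tuple[str, str, str, int], ...] = DEFAULT_QPCR_DESIGN
    ct_noise_sd: float = 0.25
    ct_replicate_sd: float = 0.15
    n_ct_replicates: int = 2

    def __post_init__(self) -> None:
        if any(n <= 0 for _, n in self.count_design):
            raise ValueError("count design categories must have n >= 1")
        if any(n <= 0 for *_, n in self.qpcr_design):
            raise ValueError("qPCR design categories must have n >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("NB dispersion must be >= 0")
        if self.ct_noise_sd < 0 or self.ct_replicate_sd < 0:
            raise ValueError("Ct noise sds must be >= 0")
        if self.marker_log2_effect * np.log10(2) <= 1.0:
            raise ValueError(
                "marker_log2_effect must exceed the tenfold filter "
                "(log2 effect > log2(10) ~ 3.32)"
            )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, dispersion alpha) draws; Poisson limit at alpha = 0."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    size = 1.0 / alpha  # number of failures r; Var = mu + mu^2/r
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate an RNAseq count matrix with nine planted marker genes.

    Returns the count matrix (size factors not yet estimated) and sample
    metadata with columns ``sample_id, histo_sex, histo_stage,
    molecular_label``.  Planted markers carry pathway-consistent class
    effects of at least ``2**marker_log2_effect``; background contigs have
    no class effect.
    """
    rng = np.random.default_rng(config.seed)
    labels: list[str] = []
    sample_ids: list[str] = []
    for lbl, n in config.count_design:
        for i in range(n):
            labels.append(lbl)
            sample_ids.append(f"{lbl}{i + 1}")
    n_samples = len(sample_ids)

    markers = list(CANONICAL_GENE_ORDER)
    n_contigs = len(markers) + config.n_background_contigs
    contig_ids = markers + [f"bg{i:05d}" for i in range(config.n_background_contigs)]

    lo, hi = config.baseline_mean_range
    baselines = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_contigs))
    # fixed moderate baseline for the planted markers keeps the conditioned
    # exact test's enumeration bounded even under the strongest effects
    baselines[: len(markers)] = 50.0
    lib_factors = np.exp(rng.normal(0.0, config.libsize_log_sd, size=n_samples))

    effects = _count_effects(config.marker_log2_effect)
    mean = baselines[:, None] * lib_factors[None, :]
    for gi, gene in enumerate(markers):
        gene_eff = effects[gene]
        per_sample = np.array([gene_eff.get(lbl, 1.0) for lbl in labels])
        mean[gi, :] = mean[gi, :] * per_sample

    counts = _nb_draw(rng, mean, config.nb_dispersion)

    # histological annotation consistent with the molecular label
    _HISTO = {
        "M": ("male", "mature"),
        "MR": ("male", "regression"),
        "MRF": ("male", "regression"),
        "UndM": ("undetermined", "none"),
        "InvM": ("inversion", "none"),
        "F": ("female", "mature"),
        "FR": ("female", "regression"),
        "UndF": ("undetermined", "none"),
        "InvF": ("inversion", "none"),
    }
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "histo_sex": [_HISTO[lbl][0] for lbl in labels],
            "histo_stage": [_HISTO[lbl][1] for lbl in labels],
            "molecular_label": labels,
        }
    )
    cm = CountMatrix(contig_ids=contig_ids, sample_ids=sample_ids, counts=counts)
    return cm, meta


def _qpcr_true_classes(design) -> list[tuple[str, str, str, PathwayClass]]:
    """Expand the qPCR design into per-sample rows with true pathway class.

    Gametogenic males/females are on the active pathways (MP/FP); regressed
    gonads are on the early pathways (eMP/eFP); undetermined gonads
    alternate deterministically between eMP and eFP.
    """
    rows = []
    und_toggle = 0
    for prefix, sex, stage, n in design:
        for i in range(n):
            sid = f"{prefix}{i + 1}"
            if sex == "male":
                cls = PathwayClass.eMP if stage == "regression" else PathwayClass.MP
            elif sex == "female":
                cls = PathwayClass.eFP if stage == "regression" else PathwayClass.FP
            else:  # undetermined: no germ cells, early pathway either way
                cls = PathwayClass.eMP if und_toggle % 2 == 0 else PathwayClass.eFP
                und_toggle += 1
            rows.append((sid, sex, stage, cls))
    return rows


def target_ct_mean(gene: str, cls: PathwayClass) -> float:
    """Design (noise-free) Ct of a target gene in a pathway class.

    Ct = combined reference Ct (20) - log2 relative expression.
    """
    if gene in _SIGNATURE_LOG2:
        log2_expr = _SIGNATURE_LOG2[gene][cls]
    else:
        log2_expr = _MILD_BASE_LOG2[gene] + _MILD_PROFILE_LOG2[gene][cls]
    return 20.0 - log2_expr


def simulate_ct(config: SimConfig) -> tuple[CtTable, pd.DataFrame]:
    """Simulate the qPCR Ct table of the 44-sample assay.

    Returns the Ct table (targets + two reference genes, with technical
    replicates) and metadata carrying the histological annotation and the
    *true* pathway class of every sample, for parameter-recovery tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    rows = _qpcr_true_classes(config.qpcr_design)

    records = []
    for sid, sex, stage, cls in rows:
        for gene in CANONICAL_GENE_ORDER:
            base = target_ct_mean(gene, cls)
            sample_ct = base + rng.normal(0.0, config.ct_noise_sd)
            for rep in range(1, config.n_ct_replicates + 1):
                ct = sample_ct + rng.normal(0.0, config.ct_replicate_sd)
                records.append((sid, gene, rep, ct))
        for gene in REFERENCE_GENES:
            base = _REFERENCE_CT[gene] + _REFERENCE_GROUP_WOBBLE[gene][cls]
            sample_ct = base + rng.normal(0.0, config.ct_noise_sd)
            for rep in range(1, config.n_ct_replicates + 1):
                ct = sample_ct + rng.normal(0.0, config.ct_replicate_sd)
                records.append((sid, gene, rep, ct))

    table = CtTable(
        records=pd.DataFrame(records, columns=["sample_id", "gene_id", "replicate", "ct"]),
        gene_roles={
            **{g: "target" for g in CANONICAL_GENE_ORDER},
            **{g: "reference" for g in REFERENCE_GENES},
        },
    )
    meta = pd.DataFrame(
        [(sid, sex, stage, cls.value) for sid, sex, stage, cls in rows],
        columns=["sample_id", "histo_sex", "histo_stage", "true_class"],
    )
    return table, meta
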