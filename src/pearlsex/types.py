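"""Domain vocabulary and core data containers.

The gonad of the protandrous hermaphrodite pearl oyster *Pinctada
margaritifera* is described here on two levels at once: a *histological*
level (sex seen under the microscope x gametogenic stage) and a *molecular*
level (whether the gonad shows a male or a female gene-expression pattern).
The combined histo-molecular label is the :class:`GonadCategory`; the
developmental trajectory a gonad is engaged on is the :class:`PathwayClass`
(male pathway MP, female pathway FP, or their "early" variants eMP/eFP
covering regressed and undifferentiated gonads).

Containers defined here carry no computation; the analysis stages live in
:mod:`pearlsex.de`, :mod:`pearlsex.qpcr`, :mod:`pearlsex.features`,
:mod:`pearlsex.mrt` and :mod:`pearlsex.pathway`.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HistoSex",
    "HistoStage",
    "MolecularLabel",
    "GonadCategory",
    "PathwayClass",
    "MarkerClass",
    "CountMatrix",
    "CtTable",
    "RelExprTable",
    "RatioFeatureMatrix",
    "CANONICAL_GENE_ORDER",
    "REFERENCE_GENES",
    "validate_category",
    "CategoryError",
]

#: Canonical order of the nine candidate marker genes.  Ratio features are
#: named "A/B" with A before B in this order, which makes feature names
#: deterministic across the whole pipeline.
CANONICAL_GENE_ORDER: tuple[str, ...] = (
    "foxl2",
    "c43476",
    "c45042",
    "c19309",
    "c54338",
    "vit6",
    "zglp1",
    "dmrt",
    "fem1-like",
)

#: The two reference genes used for qPCR normalization.
REFERENCE_GENES: tuple[str, str] = ("ef1a", "gapdh1")


class HistoSex(str, enum.Enum):
    """Sex of the gonad as seen in histological sections."""

    male = "male"
    female = "female"
    undetermined = "undetermined"
    inversion = "inversion"


class HistoStage(str, enum.Enum):
    """Gametogenic stage of the gonad in histological sections."""

    early = "early"
    intermediate = "intermediate"
    mature = "mature"
    regression = "regression"
    none = "none"


class MolecularLabel(str, enum.Enum):
    """Histo-molecular gonad category label.

    Labels combine the histological description with the molecular
    expression pattern: e.g. ``MRF`` is a histologically regressed male
    whose gonad already shows a female expression pattern, ``UndF`` an
    undifferentiated gonad with a female pattern, ``InvM`` a gonad in
    sexual inversion toward male.
    """

    M = "M"
    F = "F"
    ME = "ME"
    MI = "MI"
    MM = "MM"
    MR = "MR"
    FE = "FE"
    FI = "FI"
    FM = "FM"
    FR = "FR"
    UndM = "UndM"
    UndF = "UndF"
    InvM = "InvM"
    InvF = "InvF"
    MRF = "MRF"
    FRM = "FRM"
    Und = "Und"
    Inv = "Inv"


# Consistency rules: molecular label -> (required histological sex,
# admissible histological stages).  Generic gametogenesis labels (M, F)
# admit any developing/ripe stage; undetermined and inversion labels carry
# no meaningful stage and admit only `none`.
_CATEGORY_RULES: dict[MolecularLabel, tuple[HistoSex, frozenset[HistoStage]]] = {
    MolecularLabel.M: (
        HistoSex.male,
        frozenset({HistoStage.early, HistoStage.intermediate, HistoStage.mature}),
    ),
    MolecularLabel.ME: (HistoSex.male, frozenset({HistoStage.early})),
    MolecularLabel.MI: (HistoSex.male, frozenset({HistoStage.intermediate})),
    MolecularLabel.MM: (HistoSex.male, frozenset({HistoStage.mature})),
    MolecularLabel.MR: (HistoSex.male, frozenset({HistoStage.regression})),
    MolecularLabel.MRF: (HistoSex.male, frozenset({HistoStage.regression})),
    MolecularLabel.F: (
        HistoSex.female,
        frozenset({HistoStage.early, HistoStage.intermediate, HistoStage.mature}),
    ),
    MolecularLabel.FE: (HistoSex.female, frozenset({HistoStage.early})),
    MolecularLabel.FI: (HistoSex.female, frozenset({HistoStage.intermediate})),
    MolecularLabel.FM: (HistoSex.female, frozenset({HistoStage.mature})),
    MolecularLabel.FR: (HistoSex.female, frozenset({HistoStage.regression})),
    MolecularLabel.FRM: (HistoSex.female, frozenset({HistoStage.regression})),
    MolecularLabel.UndM: (HistoSex.undetermined, frozenset({HistoStage.none})),
    MolecularLabel.UndF: (HistoSex.undetermined, frozenset({HistoStage.none})),
    MolecularLabel.Und: (HistoSex.undetermined, frozenset({HistoStage.none})),
    MolecularLabel.InvM: (HistoSex.inversion, frozenset({HistoStage.none})),
    MolecularLabel.InvF: (HistoSex.inversion, frozenset({HistoStage.none})),
    MolecularLabel.Inv: (HistoSex.inversion, frozenset({HistoStage.none})),
}

#: Categories with a female molecular expression pattern (female pathway).
FEMALE_PATTERN_LABELS = frozenset(
    {
        MolecularLabel.F,
        MolecularLabel.FE,
        MolecularLabel.FI,
        MolecularLabel.FM,
        MolecularLabel.FR,
        MolecularLabel.UndF,
        MolecularLabel.MRF,
        MolecularLabel.InvF,
    }
)

#: Categories with a male molecular expression pattern (male pathway).
MALE_PATTERN_LABELS = frozenset(
    {
        MolecularLabel.M,
        MolecularLabel.ME,
        MolecularLabel.MI,
        MolecularLabel.MM,
        MolecularLabel.MR,
        MolecularLabel.UndM,
        MolecularLabel.FRM,
        MolecularLabel.InvM,
    }
)


class CategoryError(ValueError):
    """Raised on a histologically inconsistent gonad-category combination."""


class PathwayClass(str, enum.Enum):
    """Sexual pathway a gonad sample is engaged on."""

    MP = "MP"  #: male pathway, active spermatogenesis
    FP = "FP"  #: female pathway, active oogenesis
    eMP = "eMP"  #: early male pathway (regressed/undifferentiated, male pattern)
    eFP = "eFP"  #: early female pathway (regressed/undifferentiated, female pattern)


class MarkerClass(str, enum.Enum):
    """Class of a candidate marker gene, by the category set it is high in."""

    FP = "FP"  #: entire female pathway (MRF + UndF + InvF + F + FR)
    eFP = "eFP"  #: early female pathway (MRF + UndF)
    F = "F"  #: gametogenic females only (FE + FI + FM)
    MP = "MP"  #: male pathway (UndM + InvM + M + MR)


@dataclass(frozen=True)
class GonadCategory:
    """A validated histo-molecular gonad category."""

    histo_sex: HistoSex
    histo_stage: HistoStage
    molecular_label: MolecularLabel

    def __post_init__(self) -> None:
        sex, stages = _CATEGORY_RULES[self.molecular_label]
        if self.histo_sex is not sex:
            raise CategoryError(
                f"label {self.molecular_label.value!r} requires histological sex "
                f"{sex.value!r}, got {self.histo_sex.value!r}"
            )
        if self.histo_stage not in stages:
            allowed = sorted(s.value for s in stages)
            raise CategoryError(
                f"label {self.molecular_label.value!r} admits stages {allowed}, "
                f"got {self.histo_stage.value!r}"
            )

    @property
    def pathway_pattern(self) -> str:
        """'female' or 'male' molecular expression pattern of this category."""
        return "female" if self.molecular_label in FEMALE_PATTERN_LABELS else "male"


def validate_category(
    histo_sex: HistoSex | str,
    histo_stage: HistoStage | str,
    molecular_label: MolecularLabel | str,
) -> GonadCategory:
    """Validate a (sex, stage, label) triple and return the category.

    Raises
    ------
    CategoryError
        If the combination contradicts the histo-molecular vocabulary,
        e.g. a female gonad labelled ``MR``.
    """
    try:
        label = MolecularLabel(molecular_label)
    except ValueError:
        valid = ", ".join(m.value for m in MolecularLabel)
        raise CategoryError(
            f"unknown molecular label {molecular_label!r}; valid labels: {valid}"
        ) from None
    return GonadCategory(HistoSex(histo_sex), HistoStage(histo_stage), label)


@dataclass
class CountMatrix:
    """Raw (and optionally normalized) RNAseq contig counts.

    Parameters
    ----------
    counts
        Non-negative integer matrix, contigs x samples.
    contig_ids, sample_ids
        Row / column identifiers.
    size_factors
        Optional per-sample positive scaling constants (median-of-ratios).
    normalized
        Optional ``counts / size_factors`` matrix; kept consistent with the
        other two fields when present.
    """

    contig_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    size_factors: np.ndarray | None = None
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.contig_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.contig_ids)} contigs x {len(self.sample_ids)} samples"
            )
        if len(set(self.contig_ids)) != len(self.contig_ids):
            raise ValueError("duplicate contig ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if self.size_factors.shape != (len(self.sample_ids),):
                raise ValueError("size_factors length must match sample count")
            if np.any(self.size_factors <= 0):
                raise ValueError("size factors must be positive")
        if self.normalized is not None:
            if self.size_factors is None:
                raise ValueError("normalized matrix requires size factors")
            expected = self.counts / self.size_factors[np.newaxis, :]
            if not np.allclose(self.normalized, expected):
                raise ValueError("normalized matrix inconsistent with counts/size_factors")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.contig_ids, columns=self.sample_ids)


# Typical instrument range for a cycle threshold; values outside trigger a
# warning (QC), not an error.
CT_TYPICAL_RANGE = (10.0, 40.0)


@dataclass
class CtTable:
    """Long-format qPCR cycle-threshold measurements.

    ``records`` has columns ``sample_id, gene_id, replicate, ct``.
    ``gene_roles`` maps each gene to ``"target"`` or ``"reference"``;
    ``efficiencies`` optionally carries per-gene amplification efficiencies
    (fractions, 1.0 = perfect doubling) from standard-curve QC.
    """

    records: pd.DataFrame
    gene_roles: dict[str, str]
    efficiencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"sample_id", "gene_id", "replicate", "ct"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"CtTable records missing columns: {sorted(missing)}")
        ct = self.records["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)):
            raise ValueError("non-finite Ct values")
        lo, hi = CT_TYPICAL_RANGE
        n_out = int(np.sum((ct < lo) | (ct > hi)))
        if n_out:
            logger.warning(
                "%d Ct values outside the typical [%g, %g] cycle range", n_out, lo, hi
            )
        bad_roles = set(self.gene_roles.values()) - {"target", "reference"}
        if bad_roles:
            raise ValueError(f"unknown gene roles: {sorted(bad_roles)}")
        unknown = set(self.records["gene_id"]) - set(self.gene_roles)
        if unknown:
            raise ValueError(f"genes without a declared role: {sorted(unknown)}")

    @property
    def reference_genes(self) -> list[str]:
        return sorted(g for g, r in self.gene_roles.items() if r == "reference")

    @property
    def target_genes(self) -> list[str]:
        # preserve canonical order where applicable, then any extras
        targets = {g for g, r in self.gene_roles.items() if r == "target"}
        ordered = [g for g in CANONICAL_GENE_ORDER if g in targets]
        ordered += sorted(targets - set(ordered))
        return ordered

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["sample_id"]))


@dataclass
class RelExprTable:
    """Samples x target-genes matrix of 2^-dCt relative expression values.

    Values are strictly positive unless an explicit floor was applied
    (floor events are logged by the producer).
    """

    values: pd.DataFrame  # index: sample_id, columns: gene_id

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if np.any(~np.isfinite(arr)):
            raise ValueError("non-finite relative expression values")
        if np.any(arr < 0):
            raise ValueError("relative expression values must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class RatioFeatureMatrix:
    """Samples x gene-pair-ratio feature matrix.

    Feature names are ``"A/B"`` with A before B in the canonical gene
    order; values are ``relExpr(A) / relExpr(B)`` (raw scale).  For nine
    genes there are exactly 36 features.
    """

    values: pd.DataFrame  # index: sample_id, columns: "A/B" feature names

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("ratio features must be finite and positive")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)
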