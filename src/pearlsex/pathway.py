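"""The fixed 3-gene-pair expression-ratio classifier of sexual pathway.

Three expression ratios of four genes are enough to call the pathway of a
gonad sample:

1. ``c43476 / fem1-like`` — below 0.02 the sample is on the **male
   pathway** (MP): the male marker fem1-like dwarfs the female-pathway
   marker c43476.
2. otherwise ``foxl2 / c54338`` — at or above 12.2 the sample is on the
   **female pathway** (FP): foxl2 dominates even the early-female marker.
3. otherwise ``foxl2 / fem1-like`` — at or above 0.1 the sample is on the
   **early female pathway** (eFP), below it on the **early male pathway**
   (eMP).  The orientation follows the marker identities: foxl2 marks the
   female and fem1-like the male program (flagged in the docs, since only
   the critical value itself, not its side, is fixed by the source data).

Boundary semantics: the first threshold is strict (MP iff ratio < 0.02);
the second and third are inclusive (>= goes to FP / eFP).  Ratios are
per-sample scale-free, so predictions are invariant to multiplying a
sample's whole expression vector by any positive constant — which is what
lets the same rule set run on qPCR relative expressions and on normalized
RNAseq counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import PathwayClass, RelExprTable

__all__ = ["RuleSet", "PathwayPrediction", "classify_pathway", "batch_predict"]

logger = logging.getLogger(__name__)

#: Floor applied to expression values before forming ratios.
EXPRESSION_FLOOR = 1e-12


@dataclass(frozen=True)
class RuleSet:
    """Ordered threshold rules of the 3-gene-pair classifier."""

    theta1: float = 0.02  # c43476 / fem1-like, strict <  -> MP
    theta2: float = 12.2  # foxl2 / c54338, inclusive >=  -> FP
    theta3: float = 0.1  # foxl2 / fem1-like, inclusive >= -> eFP
    gene_r1: tuple[str, str] = ("c43476", "fem1-like")
    gene_r2: tuple[str, str] = ("foxl2", "c54338")
    gene_r3: tuple[str, str] = ("foxl2", "fem1-like")

    def __post_init__(self) -> None:
        if min(self.theta1, self.theta2, self.theta3) <= 0:
            raise ValueError("thresholds must be positive")

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for pair in (self.gene_r1, self.gene_r2, self.gene_r3):
            for g in pair:
                seen[g] = None
        return list(seen)


@dataclass
class PathwayPrediction:
    """Per-sample classifier output with full rule trace."""

    sample_id: str
    r1: float
    r2: float
    r3: float
    predicted: PathwayClass
    trace: list[str] = field(default_factory=list)
    annotation: dict = field(default_factory=dict)


def _ratio(expr: pd.Series, num: str, den: str, sample: str) -> float:
    for g in (num, den):
        if g not in expr.index:
            raise ValueError(f"sample {sample!r}: missing gene {g!r}")
        v = expr[g]
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"sample {sample!r}: non-positive expression for {g!r}: {v}")
    a, b = float(expr[num]), float(expr[den])
    if a < EXPRESSION_FLOOR or b < EXPRESSION_FLOOR:
        logger.warning(
            "sample %s: flooring expression below %g for ratio %s/%s",
            sample,
            EXPRESSION_FLOOR,
            num,
            den,
        )
    return max(a, EXPRESSION_FLOOR) / max(b, EXPRESSION_FLOOR)


def classify_pathway(
    expression: pd.Series, rules: RuleSet | None = None, sample_id: str = "?"
) -> PathwayPrediction:
    """Classify one sample's expression row into {MP, FP, eFP, eMP}."""
    rules = rules or RuleSet()
    r1 = _ratio(expression, *rules.gene_r1, sample_id)
    r2 = _ratio(expression, *rules.gene_r2, sample_id)
    r3 = _ratio(expression, *rules.gene_r3, sample_id)
    trace = []
    name1 = "/".join(rules.gene_r1)
    name2 = "/".join(rules.gene_r2)
    name3 = "/".join(rules.gene_r3)
    if r1 < rules.theta1:
        trace.append(f"{name1} = {r1:.4g} < {rules.theta1:g} -> MP")
        cls = PathwayClass.MP
    else:
        trace.append(f"{name1} = {r1:.4g} >= {rules.theta1:g}")
        if r2 >= rules.theta2:
            trace.append(f"{name2} = {r2:.4g} >= {rules.theta2:g} -> FP")
            cls = PathwayClass.FP
        else:
            trace.append(f"{name2} = {r2:.4g} < {rules.theta2:g}")
            if r3 >= rules.theta3:
                trace.append(f"{name3} = {r3:.4g} >= {rules.theta3:g} -> eFP")
                cls = PathwayClass.eFP
            else:
                trace.append(f"{name3} = {r3:.4g} < {rules.theta3:g} -> eMP")
                cls = PathwayClass.eMP
    return PathwayPrediction(sample_id, r1, r2, r3, cls, trace)


def batch_predict(
    table: RelExprTable | pd.DataFrame,
    rules: RuleSet | None = None,
    metadata: pd.DataFrame | None = None,
) -> tuple[list[PathwayPrediction], pd.DataFrame]:
    """Classify every sample of an expression table; build a report.

    ``table`` may hold qPCR relative expressions or normalized RNAseq
    counts (samples x genes) — ratios are per-sample scale-free.  The
    report mirrors the published prediction-table layout: sample id,
    histological sex/stage and cluster label when provided, the three
    ratios and the predicted group, plus per-class summary counts in
    ``report.attrs['class_counts']``.
    """
    rules = rules or RuleSet()
    df = table.values if isinstance(table, RelExprTable) else table
    if df.empty:
        raise ValueError("empty expression table")
    meta = None
    if metadata is not None:
        meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata

    preds: list[PathwayPrediction] = []
    rows = []
    for sid in df.index:
        p = classify_pathway(df.loc[sid], rules, sample_id=str(sid))
        if meta is not None and sid in meta.index:
            p.annotation = {k: meta.loc[sid, k] for k in meta.columns}
        preds.append(p)
        row = {"sample_id": sid}
        if p.annotation:
            for key in ("histo_sex", "histo_stage", "cluster_label"):
                if key in p.annotation:
                    row[key] = p.annotation[key]
        row.update(
            {"r1": p.r1, "r2": p.r2, "r3": p.r3, "predicted_group": p.predicted.value}
        )
        rows.append(row)
    report = pd.DataFrame(rows)
    report.attrs["class_counts"] = report["predicted_group"].value_counts().to_dict()
    return preds, report
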