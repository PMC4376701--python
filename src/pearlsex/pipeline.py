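"""End-to-end pipeline: simulate/load -> markers -> ratios -> tree -> calls.

``run_pipeline`` chains the analysis stages in their natural order —
marker discovery on counts, qPCR relative expression, ratio features,
Spearman/UPGMA clustering, multivariate regression tree, and the fixed
3-gene-pair classifier — writing every artifact with a provenance header.
Deterministic (byte-identical numeric outputs) under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import de, features, io, mrt, pathway, qpcr
from .simulate import SimConfig, simulate_counts, simulate_ct
from .types import REFERENCE_GENES

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Inputs, outputs and stage parameters of the full pipeline.

    When ``counts_path``/``ct_path`` are None the synthetic generators
    provide the inputs (seeded by ``seed``).
    """

    out_dir: str | Path = "pearlsex_out"
    seed: int = 0
    counts_path: str | Path | None = None
    counts_meta_path: str | Path | None = None
    ct_path: str | Path | None = None
    ct_meta_path: str | Path | None = None
    reference_genes: tuple[str, str] = REFERENCE_GENES
    fc_hi: float = 10.0
    fc_lo: float = 0.1
    alpha: float = 0.001
    linkage: str = "average"
    mrt_params: mrt.MRTParams = field(default_factory=mrt.MRTParams)
    tree_rule: str = "min_cv"
    rules: pathway.RuleSet = field(default_factory=pathway.RuleSet)
    run_marker_discovery: bool = True

    def __post_init__(self) -> None:
        if min(self.fc_hi, self.alpha) <= 0 or self.fc_lo <= 0:
            raise ValueError("thresholds must be positive")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage attribution
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the artifact bundle.

    The bundle maps artifact names to in-memory objects; every tabular
    artifact is also written under ``config.out_dir`` with a provenance
    header (seed, version, config hash).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # hash the analysis parameters only, not output locations, so the same
    # seed + parameters give byte-identical artifacts anywhere
    params = {
        k: v
        for k, v in vars(config).items()
        if k not in {"out_dir"} and not k.endswith("_path")
    }
    header = io.provenance_header(config.seed, {"config": repr(params)})
    bundle: dict = {}

    def write_csv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        with path.open("w") as fh:
            fh.write(header)
            df.to_csv(fh, index=index)

    # -- inputs ------------------------------------------------------------
    @_stage("inputs")
    def load_inputs():
        sim = SimConfig(seed=config.seed)
        if config.counts_path is None:
            cm, cmeta = simulate_counts(sim)
        else:
            cm = io.read_counts(config.counts_path)
            cmeta = io.read_metadata(config.counts_meta_path)
        if config.ct_path is None:
            ct, qmeta = simulate_ct(sim)
        else:
            ct = io.read_ct(config.ct_path, config.reference_genes)
            qmeta = io.read_metadata(config.ct_meta_path)
        return cm, cmeta, ct, qmeta

    cm, cmeta, ct, qmeta = load_inputs()
    bundle["counts"], bundle["counts_meta"] = cm, cmeta
    bundle["ct"], bundle["ct_meta"] = ct, qmeta

    # -- marker discovery on counts ---------------------------------------
    if config.run_marker_discovery:
        @_stage("markers")
        def markers():
            sel = de.candidate_intersection(
                cm, cmeta, fc_hi=config.fc_hi, fc_lo=config.fc_lo, alpha=config.alpha
            )
            return pd.DataFrame(
                [(g, c.value) for g, c in sel.items()], columns=["gene", "marker_class"]
            )

        marker_df = markers()
        bundle["markers"] = marker_df
        write_csv(marker_df, "markers.csv")

    # -- qPCR relative expression -----------------------------------------
    @_stage("qpcr")
    def relexpr():
        missing = [g for g in config.reference_genes if g not in ct.gene_roles]
        if missing:
            raise ValueError(f"reference genes missing from Ct table: {missing}")
        return qpcr.relative_expression(ct)

    rel = relexpr()
    bundle["relexpr"] = rel
    write_csv(rel.values, "relexpr.csv", index=True)

    # -- ratio features and clustering ------------------------------------
    @_stage("features")
    def feats():
        return features.ratio_features(rel)

    feat = feats()
    bundle["features"] = feat
    write_csv(feat.values, "features.csv", index=True)

    @_stage("cluster")
    def cluster():
        dist = features.spearman_distance(feat)
        dendro = features.hierarchical_cluster(dist, method=config.linkage)
        assign = features.cut_and_label(dendro, qmeta)
        return dendro, assign

    dendro, assign = cluster()
    bundle["dendrogram"], bundle["clusters"] = dendro, assign
    (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    write_csv(assign.assignments, "clusters.csv", index=True)

    # -- multivariate regression tree -------------------------------------
    @_stage("mrt")
    def tree():
        labels = assign.assignments["label"]
        return mrt.fit_mrt(feat.values, labels, config.mrt_params, rule=config.tree_rule)

    fitted = tree()
    bundle["tree"] = fitted
    (out / "tree.json").write_text(header + fitted.to_json() + "\n")
    (out / "tree.txt").write_text(fitted.render() + "\n")

    # -- fixed-rule classification ----------------------------------------
    @_stage("classify")
    def classify():
        meta_for_report = qmeta.assign(
            cluster_label=assign.assignments["label"].reindex(qmeta["sample_id"]).to_numpy()
        )
        return pathway.batch_predict(rel, config.rules, meta_for_report)

    preds, report = classify()
    bundle["predictions"], bundle["report"] = preds, report
    write_csv(report, "predictions.csv")

    logger.info("pipeline complete; artifacts in %s", out)
    return bundle
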