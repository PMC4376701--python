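"""Gene-pair ratio features and Spearman hierarchical clustering.

Instead of clustering samples on the nine relative expression values
directly, samples are described by all pairwise expression *ratios*
(36 features for nine genes).  Ratios cancel per-sample scale, so the
profile depends only on the balance between genes — which is exactly what
distinguishes the male and female pathway.

Clustering uses 1 - Spearman correlation between per-sample log2 ratio
profiles and average-linkage (UPGMA) agglomeration.  Cutting the tree at
k=2 separates male- from female-pathway samples; cutting at k=4 splits
each pathway into its "early" (regressed/undetermined) and active
gametogenesis sub-cluster.  Cluster-to-label mapping is by explicit
majority vote over the histological annotation (ties are an error, never
a silent choice).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .types import CANONICAL_GENE_ORDER, PathwayClass, RatioFeatureMatrix, RelExprTable

__all__ = [
    "ratio_features",
    "spearman_distance",
    "hierarchical_cluster",
    "cut_and_label",
    "Dendrogram",
    "ClusterAssignment",
    "RATIO_FLOOR",
]

logger = logging.getLogger(__name__)

#: Denominator floor applied before dividing (dropout protection).
RATIO_FLOOR = 1e-12


@dataclass
class Dendrogram:
    """Agglomeration history of a hierarchical clustering."""

    linkage: np.ndarray  # scipy linkage matrix (merge pairs + heights)
    sample_ids: list[str]
    method: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.sample_ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Newick rendering with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


@dataclass
class ClusterAssignment:
    """Sample cluster memberships at k=2 and k=4 with pathway labels."""

    assignments: pd.DataFrame  # index sample_id; columns k2_cluster, k4_cluster, label
    cluster_labels: dict[int, PathwayClass]  # k4 cluster index -> class
    vote_tallies: dict[int, dict[str, int]]  # provenance of the majority votes


def ratio_features(
    rel: RelExprTable, gene_order: tuple[str, ...] = CANONICAL_GENE_ORDER
) -> RatioFeatureMatrix:
    """All pairwise expression ratios A/B, A before B in canonical order.

    Denominators below :data:`RATIO_FLOOR` are floored (and the event
    logged); with n genes the result has exactly n(n-1)/2 features.
    """
    genes = [g for g in gene_order if g in rel.gene_ids]
    extra = [g for g in rel.gene_ids if g not in genes]
    genes += extra
    if len(genes) != len(set(genes)):
        raise ValueError("duplicate gene names")
    if len(genes) < 2:
        raise ValueError("need at least two genes for ratio features")
    vals = rel.values[genes].to_numpy(dtype=float)
    floored = vals < RATIO_FLOOR
    if floored.any():
        logger.warning("floored %d expression values below %g", floored.sum(), RATIO_FLOOR)
    vals = np.maximum(vals, RATIO_FLOOR)
    cols = {}
    for i, j in itertools.combinations(range(len(genes)), 2):
        cols[f"{genes[i]}/{genes[j]}"] = vals[:, i] / vals[:, j]
    return RatioFeatureMatrix(values=pd.DataFrame(cols, index=rel.values.index))


def spearman_distance(features: RatioFeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    """1 - Spearman rank correlation between per-sample log2 profiles.

    Ties are handled by average ranks; a constant profile has no rank
    ordering and is an error naming the sample.
    """
    df = features.values if isinstance(features, RatioFeatureMatrix) else features
    if df.shape[1] < 2:
        raise ValueError("need at least 2 features per sample")
    x = np.log2(np.maximum(df.to_numpy(dtype=float), RATIO_FLOOR))
    const = np.ptp(x, axis=1) == 0
    if const.any():
        bad = [df.index[i] for i in np.flatnonzero(const)]
        raise ValueError(f"constant profile, Spearman undefined for samples: {bad}")
    ranks = np.apply_along_axis(rankdata, 1, x)
    rho = np.corrcoef(ranks)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=df.index, columns=df.index)


def hierarchical_cluster(distance: pd.DataFrame, method: str = "average") -> Dendrogram:
    """Agglomerative clustering (UPGMA by default) of a distance matrix."""
    d = distance.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if method not in {"average", "complete", "ward"}:
        raise ValueError(f"unsupported linkage method {method!r}")
    z = hierarchy.linkage(squareform(d, checks=False), method=method)
    return Dendrogram(linkage=z, sample_ids=list(distance.index), method=method)


_GAMETOGENIC_STAGES = {"early", "intermediate", "mature"}
_EARLY_STAGES = {"regression", "none"}


def _majority(counts: dict[str, int], what: str) -> str:
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        raise ValueError(
            f"tie in majority vote for {what}: {dict(counts)}; manual labeling required"
        )
    if not ranked or ranked[0][1] == 0:
        raise ValueError(f"no votes available to label {what}: {dict(counts)}")
    return ranked[0][0]


def cut_and_label(
    dendro: Dendrogram,
    metadata: pd.DataFrame,
    k2: int = 2,
    k4: int = 4,
) -> ClusterAssignment:
    """Cut the dendrogram at k=2 and k=4 and name the pathway clusters.

    The two main clusters are labelled male/female pathway by majority
    histological sex among gametogenic (early/intermediate/mature stage)
    samples; within each pathway the sub-cluster with a majority of
    regressed or undetermined samples is the "early" (e-) variant.
    Hierarchical cuts guarantee the k=4 clusters nest in the k=2 ones.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    missing = [s for s in dendro.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"metadata missing samples: {missing}")

    c2 = hierarchy.fcluster(dendro.linkage, t=k2, criterion="maxclust")
    c4 = hierarchy.fcluster(dendro.linkage, t=k4, criterion="maxclust")
    df = pd.DataFrame(
        {"k2_cluster": c2, "k4_cluster": c4}, index=pd.Index(dendro.sample_ids, name="sample_id")
    )

    # label the k2 clusters by majority sex of gametogenic members
    k2_label: dict[int, str] = {}
    tallies: dict[int, dict[str, int]] = {}
    for cl in sorted(set(c2)):
        members = df.index[df["k2_cluster"] == cl]
        votes = {"male": 0, "female": 0}
        for s in members:
            if meta.loc[s, "histo_stage"] in _GAMETOGENIC_STAGES:
                sex = meta.loc[s, "histo_sex"]
                if sex in votes:
                    votes[sex] += 1
        tallies[cl] = votes
        k2_label[cl] = _majority(votes, f"main cluster {cl} (pathway sex)")
    if len(set(k2_label.values())) < len(k2_label):
        raise ValueError(
            f"both main clusters voted the same pathway: {k2_label}; manual labeling required"
        )

    # within each pathway, the sub-cluster with majority regressed or
    # undetermined samples is the early variant
    cluster_labels: dict[int, PathwayClass] = {}
    vote_tallies: dict[int, dict[str, int]] = {}
    for cl2, sex in k2_label.items():
        subclusters = sorted(set(df.loc[df["k2_cluster"] == cl2, "k4_cluster"]))
        if len(subclusters) != 2:
            raise ValueError(
                f"pathway cluster {cl2} splits into {len(subclusters)} sub-clusters, "
                "expected 2; adjust k or inspect the dendrogram"
            )
        early_frac = {}
        for cl4 in subclusters:
            members = df.index[df["k4_cluster"] == cl4]
            n_early = sum(meta.loc[s, "histo_stage"] in _EARLY_STAGES for s in members)
            early_frac[cl4] = (n_early, len(members))
            vote_tallies[cl4] = {"early_stage": n_early, "total": len(members)}
        fracs = {cl: n / tot for cl, (n, tot) in early_frac.items()}
        a, b = subclusters
        if fracs[a] == fracs[b]:
            raise ValueError(
                f"tie in early-stage vote between sub-clusters {a} and {b}: {early_frac}; "
                "manual labeling required"
            )
        early_cl = a if fracs[a] > fracs[b] else b
        course_cl = b if early_cl == a else a
        if sex == "male":
            cluster_labels[early_cl] = PathwayClass.eMP
            cluster_labels[course_cl] = PathwayClass.MP
        else:
            cluster_labels[early_cl] = PathwayClass.eFP
            cluster_labels[course_cl] = PathwayClass.FP

    df["label"] = [cluster_labels[cl].value for cl in df["k4_cluster"]]
    vote_tallies.update({-cl: t for cl, t in tallies.items()})  # keep k2 tallies too
    return ClusterAssignment(assignments=df, cluster_labels=cluster_labels, vote_tallies=vote_tallies)
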