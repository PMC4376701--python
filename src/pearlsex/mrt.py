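"""Multivariate regression tree (CART with cost-complexity pruning).

The tree models a multivariate response — here the one-hot indicator
matrix of the four pathway sub-clusters — by recursive binary splitting
on the gene-pair ratio features.  Node impurity is the total sum of
squares of the response about the node mean vector; each split maximizes
the impurity reduction dSS subject to minimum node sizes and a complexity
threshold.  Weakest-link pruning yields the nested subtree sequence, and
stratified k-fold cross-validation selects the tree size (minimum CV
error, one-SE rule, or a fixed leaf count).

Split ties: because ratio features are log-linearly dependent (A/B equals
(A/D)/(B/D)), several features routinely achieve *identical* dSS by
inducing the same sample partition.  Ties are therefore broken by the
widest relative gap between the two feature values bounding the
threshold (the most robust boundary), then by lowest feature index, then
by lowest threshold — all deterministic.

Thresholds are midpoints of the bounding observed values; routing sends
``value < threshold`` left and ``value >= threshold`` right.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MRTParams",
    "MRTNode",
    "MRTree",
    "encode_response",
    "grow",
    "prune_sequence",
    "cross_validate",
    "select_tree",
    "variance_partition",
    "predict",
    "fit_mrt",
]

logger = logging.getLogger(__name__)

_REL_TOL = 1e-9


@dataclass
class MRTParams:
    """Tree-growing and cross-validation parameters.

    minsplit
        Minimum node size eligible for splitting (default 5 — chosen for
        the small gonad sample sets this package targets; configurable).
    minbucket
        Minimum child size (default 2).
    cp
        Complexity threshold: a split must achieve dSS >= cp * SS(root).
    xval
        Cross-validation folds (default 10), stratified by class.
    seed
        Seed for the CV fold shuffle.
    """

    minsplit: int = 5
    minbucket: int = 2
    cp: float = 0.01
    xval: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.minsplit < 2 or self.minbucket < 1:
            raise ValueError("minsplit >= 2 and minbucket >= 1 required")
        if self.minbucket > self.minsplit / 2:
            logger.warning(
                "minbucket (%d) exceeds minsplit/2 (%g); splits may be impossible",
                self.minbucket,
                self.minsplit / 2,
            )
        if not 0 <= self.cp < 1:
            raise ValueError("cp must lie in [0, 1)")


@dataclass
class MRTNode:
    """One node of the tree; leaves have ``feature is None``."""

    node_id: int
    n: int
    ss: float  # response SS about this node's mean vector
    mean: np.ndarray  # mean response vector
    sample_idx: np.ndarray  # row indices (training data)
    feature: str | None = None
    feature_idx: int | None = None
    threshold: float | None = None
    delta_ss: float = 0.0
    left: "MRTNode | None" = None
    right: "MRTNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def leaves(self) -> list["MRTNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def internal(self) -> list["MRTNode"]:
        if self.is_leaf:
            return []
        return [self] + self.left.internal() + self.right.internal()


@dataclass
class MRTree:
    """A fitted multivariate regression tree."""

    root: MRTNode
    feature_names: list[str]
    class_names: list[str]
    ss_root: float
    n: int
    params: MRTParams
    cp_table: pd.DataFrame | None = None  # cp, n_leaves, rel_error[, cv_error, cv_se]
    stats: dict = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    @property
    def relative_error(self) -> float:
        """SS over leaves divided by SS at the root (resubstitution)."""
        leaf_ss = sum(l.ss for l in self.root.leaves())
        return leaf_ss / self.ss_root if self.ss_root > 0 else 0.0

    @property
    def split_features(self) -> list[str]:
        return [nd.feature for nd in self.root.internal()]

    def leaf_majority(self, node: MRTNode) -> str:
        return self.class_names[int(np.argmax(node.mean))]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def node_dict(nd: MRTNode) -> dict:
            d = {
                "node_id": nd.node_id,
                "n": nd.n,
                "ss": nd.ss,
                "mean": [float(v) for v in nd.mean],
            }
            if nd.is_leaf:
                d["majority_class"] = self.leaf_majority(nd)
            else:
                d.update(
                    feature=nd.feature,
                    threshold=nd.threshold,
                    delta_ss=nd.delta_ss,
                    frac_root_ss=nd.delta_ss / self.ss_root if self.ss_root else 0.0,
                    left=node_dict(nd.left),
                    right=node_dict(nd.right),
                )
            return d

        return {
            "n": self.n,
            "ss_root": self.ss_root,
            "classes": self.class_names,
            "relative_error": self.relative_error,
            "stats": self.stats,
            "tree": node_dict(self.root),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=kwargs.pop("indent", 2), **kwargs)

    def render(self) -> str:
        """Indented text rendering of the tree structure."""
        lines = [
            f"n = {self.n}, classes = {self.class_names}",
            f"Error: {self.relative_error:.4g}"
            + (
                f"; CV Error: {self.stats['cv_error']:.4g}; SE: {self.stats['cv_se']:.4g}"
                if "cv_error" in self.stats
                else ""
            ),
        ]

        def walk(nd: MRTNode, depth: int, prefix: str) -> None:
            pad = "  " * depth
            if nd.is_leaf:
                counts = ", ".join(
                    f"{c}={v * nd.n:.0f}" for c, v in zip(self.class_names, nd.mean)
                )
                lines.append(f"{pad}{prefix}leaf [{self.leaf_majority(nd)}] n={nd.n} ({counts})")
            else:
                frac = 100 * nd.delta_ss / self.ss_root if self.ss_root else 0
                lines.append(
                    f"{pad}{prefix}{nd.feature} < {nd.threshold:.4g} "
                    f"(dSS {frac:.1f}% of total)"
                )
                walk(nd.left, depth + 1, "yes: ")
                walk(nd.right, depth + 1, "no:  ")

        walk(self.root, 0, "")
        return "\n".join(lines)


def encode_response(labels: list[str] | pd.Series) -> pd.DataFrame:
    """One-hot indicator matrix of class labels (columns in first-seen order)."""
    labels = pd.Series(labels).astype(str)
    classes = list(dict.fromkeys(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for a response with variance")
    mat = np.zeros((len(labels), len(classes)))
    for j, c in enumerate(classes):
        mat[:, j] = (labels == c).to_numpy(dtype=float)
    return pd.DataFrame(mat, columns=classes, index=labels.index)


def _node_ss(y: np.ndarray) -> float:
    return float(((y - y.mean(axis=0)) ** 2).sum()) if len(y) else 0.0


def _split_gap(lo: float, hi: float) -> float:
    """Separation width between the two values bounding a threshold.

    For positive features (ratios) the gap is measured on the log scale so
    it is invariant to the feature's unit; otherwise absolute.
    """
    if lo > 0 and hi > 0:
        return float(np.log(hi / lo))
    return float(hi - lo)


def _best_split_feature(
    x: np.ndarray, y: np.ndarray, minbucket: int
) -> tuple[float, float, float] | None:
    """Best (dss, threshold, gap) for one feature column, or None.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values; dss computed with cumulative sums in O(n log n).
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    n = len(xs)
    csum = np.cumsum(ys, axis=0)
    csum2 = np.cumsum(ys**2, axis=0)
    tot = csum[-1]
    tot2 = csum2[-1]
    ss_node = float(tot2.sum() - (tot**2).sum() / n)

    best: tuple[float, float, float] | None = None
    # split after position i: left = xs[:i+1], right = xs[i+1:]
    for i in range(n - 1):
        if xs[i] == xs[i + 1]:
            continue
        n_l = i + 1
        n_r = n - n_l
        if n_l < minbucket or n_r < minbucket:
            continue
        s_l = csum[i]
        s2_l = csum2[i]
        ss_l = float(s2_l.sum() - (s_l**2).sum() / n_l)
        s_r = tot - s_l
        s2_r = tot2 - s2_l
        ss_r = float(s2_r.sum() - (s_r**2).sum() / n_r)
        dss = ss_node - ss_l - ss_r
        thr = 0.5 * (xs[i] + xs[i + 1])
        gap = _split_gap(xs[i], xs[i + 1])
        cand = (dss, thr, gap)
        if best is None:
            best = cand
            continue
        if dss > best[0] * (1 + _REL_TOL) + _REL_TOL:
            best = cand
        elif abs(dss - best[0]) <= _REL_TOL * max(1.0, abs(best[0])):
            # tie within a feature: widest gap, then lowest threshold
            if gap > best[2] * (1 + _REL_TOL) + _REL_TOL:
                best = cand
    return best


def _choose_split(
    X: np.ndarray, y: np.ndarray, minbucket: int
) -> tuple[int, float, float, float] | None:
    """(feature_idx, threshold, dss, gap) of the winning split, or None.

    Maximize dss; ties broken by widest gap, then lowest feature index,
    then lowest threshold (evaluation order makes the last two implicit).
    """
    best: tuple[int, float, float, float] | None = None
    for j in range(X.shape[1]):
        res = _best_split_feature(X[:, j], y, minbucket)
        if res is None:
            continue
        dss, thr, gap = res
        if best is None:
            best = (j, thr, dss, gap)
            continue
        tol = _REL_TOL * max(1.0, abs(best[2]))
        if dss > best[2] + tol:
            best = (j, thr, dss, gap)
        elif abs(dss - best[2]) <= tol and gap > best[3] * (1 + _REL_TOL) + _REL_TOL:
            best = (j, thr, dss, gap)
    return best


def grow(
    features: pd.DataFrame,
    response: pd.DataFrame,
    params: MRTParams | None = None,
) -> MRTree:
    """Grow a multivariate regression tree by greedy recursive splitting."""
    params = params or MRTParams()
    if features.shape[1] == 0:
        raise ValueError("empty feature set")
    if features.isna().to_numpy().any() or response.isna().to_numpy().any():
        raise ValueError("missing values are not supported")
    X = features.to_numpy(dtype=float)
    Y = response.to_numpy(dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("features and response must have the same number of rows")

    ss_root = _node_ss(Y)
    counter = [0]

    def build(idx: np.ndarray) -> MRTNode:
        y = Y[idx]
        node = MRTNode(
            node_id=counter[0],
            n=len(idx),
            ss=_node_ss(y),
            mean=y.mean(axis=0),
            sample_idx=idx,
        )
        counter[0] += 1
        if len(idx) < params.minsplit or node.ss <= _REL_TOL * max(ss_root, 1.0):
            return node
        choice = _choose_split(X[idx], y, params.minbucket)
        if choice is None:
            return node
        j, thr, dss, _gap = choice
        if ss_root > 0 and dss < params.cp * ss_root:
            return node
        node.feature = features.columns[j]
        node.feature_idx = j
        node.threshold = float(thr)
        node.delta_ss = float(dss)
        mask = X[idx, j] < thr
        node.left = build(idx[mask])
        node.right = build(idx[~mask])
        return node

    root = build(np.arange(X.shape[0]))
    return MRTree(
        root=root,
        feature_names=list(features.columns),
        class_names=list(response.columns),
        ss_root=ss_root,
        n=X.shape[0],
        params=params,
    )


def _subtree_stats(node: MRTNode) -> tuple[float, int]:
    """(SS over the subtree's leaves, number of leaves)."""
    leaves = node.leaves()
    return sum(l.ss for l in leaves), len(leaves)


def _collapse(node: MRTNode) -> None:
    node.feature = None
    node.feature_idx = None
    node.threshold = None
    node.delta_ss = 0.0
    node.left = None
    node.right = None


def prune_sequence(tree: MRTree) -> list[tuple[float, MRTree]]:
    """Weakest-link cost-complexity pruning.

    Returns (cp, subtree) pairs from the full tree up to the root-only
    tree, with cp = alpha / SS(root) increasing and size non-increasing;
    the subtrees are nested.
    """
    seq: list[tuple[float, MRTree]] = []
    current = copy.deepcopy(tree)
    alpha = 0.0
    while True:
        seq.append((alpha / tree.ss_root if tree.ss_root else alpha, copy.deepcopy(current)))
        internal = current.root.internal()
        if not internal:
            break
        links = []
        for nd in internal:
            leaf_ss, n_leaves = _subtree_stats(nd)
            g = (nd.ss - leaf_ss) / (n_leaves - 1)
            links.append((g, nd))
        g_min = min(g for g, _ in links)
        for g, nd in links:
            if g <= g_min * (1 + _REL_TOL) + _REL_TOL:
                _collapse(nd)
        alpha = max(alpha, g_min)
    return seq


def _cp_table(seq: list[tuple[float, MRTree]]) -> pd.DataFrame:
    rows = [
        {"cp": cp, "n_leaves": t.n_leaves, "rel_error": t.relative_error}
        for cp, t in seq
    ]
    return pd.DataFrame(rows)


def _stratified_folds(
    labels: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Round-robin class-stratified fold assignment."""
    fold_of = np.empty(len(labels), dtype=int)
    offset = 0
    for c in dict.fromkeys(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            fold_of[i] = (pos + offset) % k
        offset += len(idx)  # stagger classes across folds
    return [np.flatnonzero(fold_of == f) for f in range(k)]


def _prune_at_cp(seq: list[tuple[float, MRTree]], cp: float) -> MRTree:
    """Largest subtree whose creation cp does not exceed the requested cp."""
    chosen = seq[0][1]
    for c, t in seq:
        if c <= cp * (1 + _REL_TOL) + _REL_TOL:
            chosen = t
        else:
            break
    return chosen


def _predict_response(tree: MRTree, X: np.ndarray) -> np.ndarray:
    out = np.empty((X.shape[0], len(tree.class_names)))
    for i in range(X.shape[0]):
        nd = tree.root
        while not nd.is_leaf:
            nd = nd.left if X[i, nd.feature_idx] < nd.threshold else nd.right
        out[i] = nd.mean
    return out


def cross_validate(
    features: pd.DataFrame,
    response: pd.DataFrame,
    params: MRTParams | None = None,
) -> tuple[MRTree, pd.DataFrame]:
    """Grow, prune and cross-validate; returns (full tree, cp table).

    The cp table carries, per nested subtree size, the resubstitution
    relative error plus cross-validated error and its standard error
    (both normalized by the full data's root SS).  Folds are stratified
    by class; classes smaller than the fold count reduce it with a
    warning.  Deterministic under the params seed.
    """
    params = params or MRTParams()
    labels = response.to_numpy().argmax(axis=1)
    class_sizes = np.bincount(labels)
    k = min(params.xval, len(features))
    if class_sizes.min() < k:
        k_new = max(2, int(class_sizes.min()))
        logger.warning(
            "smallest class (n=%d) below %d folds; using %d folds",
            class_sizes.min(),
            k,
            k_new,
        )
        k = k_new
    if len(features) < k:
        raise ValueError("need at least as many samples as folds")

    full = grow(features, response, params)
    seq = prune_sequence(full)
    table = _cp_table(seq)

    # rpart-style evaluation cps: geometric means of consecutive cp values
    cps = table["cp"].to_numpy()
    eval_cp = np.sqrt(np.maximum(cps, 1e-30) * np.maximum(np.roll(cps, -1), 1e-30))
    eval_cp[-1] = np.inf  # root-only row

    rng = np.random.default_rng(params.seed)
    folds = _stratified_folds(labels, k, rng)
    Y = response.to_numpy(dtype=float)
    contrib = np.zeros((k, len(seq)))  # per-fold test SS per subtree size
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(features)), test_idx)
        f_tr = features.iloc[train_idx]
        y_tr = response.iloc[train_idx]
        t_full = grow(f_tr, y_tr, params)
        t_seq = prune_sequence(t_full)
        X_te = features.iloc[test_idx].to_numpy(dtype=float)
        y_te = Y[test_idx]
        for s, cp_eval in enumerate(eval_cp):
            sub = t_seq[-1][1] if np.isinf(cp_eval) else _prune_at_cp(t_seq, cp_eval)
            pred = _predict_response(sub, X_te)
            contrib[f, s] = ((y_te - pred) ** 2).sum()

    ss_root = full.ss_root
    cv_error = contrib.sum(axis=0) / ss_root
    fold_est = contrib * k / ss_root  # per-fold estimate of the error
    cv_se = fold_est.std(axis=0, ddof=1) / np.sqrt(k)
    table["cv_error"] = cv_error
    table["cv_se"] = cv_se
    full.cp_table = table
    return full, table


def select_tree(
    full: MRTree,
    rule: str = "min_cv",
    k_leaves: int | None = None,
) -> MRTree:
    """Select a subtree from the pruning sequence by the given rule.

    ``fixed_leaves`` returns the nested subtree with ``k_leaves`` leaves;
    ``min_cv`` the size minimizing cross-validated error; ``one_se`` the
    smallest tree within one SE of that minimum.
    """
    if full.cp_table is None:
        raise ValueError("run cross_validate first (cp table missing)")
    seq = prune_sequence(full)
    table = full.cp_table
    by_size = {t.n_leaves: (cp, t) for cp, t in seq}

    if rule == "fixed_leaves":
        if k_leaves is None:
            raise ValueError("fixed_leaves rule needs k_leaves")
        if k_leaves not in by_size:
            raise ValueError(
                f"no nested subtree with {k_leaves} leaves; available sizes: "
                f"{sorted(by_size)}"
            )
        chosen = by_size[k_leaves][1]
    elif rule in {"min_cv", "one_se"}:
        if "cv_error" not in table.columns:
            raise ValueError("cp table lacks cv_error; run cross_validate")
        i_min = int(table["cv_error"].idxmin())
        if rule == "min_cv":
            size = int(table.loc[i_min, "n_leaves"])
        else:
            limit = table.loc[i_min, "cv_error"] + table.loc[i_min, "cv_se"]
            ok = table[table["cv_error"] <= limit + _REL_TOL]
            size = int(ok["n_leaves"].min())
        chosen = by_size[size][1]
    else:
        raise ValueError(f"unknown selection rule {rule!r}")

    chosen = copy.deepcopy(chosen)
    chosen.cp_table = table
    chosen.stats = dict(full.stats)
    row = table[table["n_leaves"] == chosen.n_leaves].iloc[0]
    chosen.stats["rel_error"] = float(row["rel_error"])
    if "cv_error" in table.columns:
        chosen.stats["cv_error"] = float(row["cv_error"])
        chosen.stats["cv_se"] = float(row["cv_se"])
    return chosen


def variance_partition(tree: MRTree) -> pd.DataFrame:
    """Per-split fraction of the root SS explained, in split order.

    Fractions sum to 1 - relative_error (100% for a zero-error tree).
    """
    rows = []
    # breadth-first: the first split is the root's
    queue = [tree.root]
    while queue:
        nd = queue.pop(0)
        if nd.is_leaf:
            continue
        rows.append(
            {
                "feature": nd.feature,
                "threshold": nd.threshold,
                "delta_ss": nd.delta_ss,
                "percent_variance": 100.0 * nd.delta_ss / tree.ss_root if tree.ss_root else 0.0,
            }
        )
        queue.extend([nd.left, nd.right])
    return pd.DataFrame(rows)


def predict(tree: MRTree, features: pd.DataFrame) -> pd.Series:
    """Majority class of the leaf each sample is routed to."""
    missing = [f for f in tree.split_features if f not in features.columns]
    if missing:
        raise ValueError(f"features missing split variables: {missing}")
    # map tree feature indices onto this frame's columns
    name_to_col = {c: i for i, c in enumerate(features.columns)}
    X = features.to_numpy(dtype=float)
    out = []
    for i in range(X.shape[0]):
        nd = tree.root
        while not nd.is_leaf:
            v = X[i, name_to_col[nd.feature]]
            nd = nd.left if v < nd.threshold else nd.right
        out.append(tree.leaf_majority(nd))
    return pd.Series(out, index=features.index, name="predicted_class")


def fit_mrt(
    features: pd.DataFrame,
    labels: list[str] | pd.Series,
    params: MRTParams | None = None,
    rule: str = "min_cv",
    k_leaves: int | None = None,
) -> MRTree:
    """Convenience wrapper: encode labels, grow, cross-validate, select."""
    response = encode_response(pd.Series(labels, index=features.index))
    full, _ = cross_validate(features, response, params)
    return select_tree(full, rule=rule, k_leaves=k_leaves)
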