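"""CART-style classification trees over phenotype features, and the NIPBL-like filter.

Recursive partitioning is used to find which growth and gestalt features
discriminate NIPBL-positive cases, and the resulting two-feature rule
(weight < -2.4 SD AND birth weight >= -4.4 SD) is then applied to the
mutation-negative group to estimate how many undetected (likely mosaic)
NIPBL cases it contains.

The tree induction here is deliberately minimal and fully deterministic:
greedy binary splitting on Gini impurity decrease, candidate thresholds at
midpoints between consecutive distinct observed feature values, a node split
only while it holds at least ``min_split`` observations and lies above the
depth cap (depth counts edges from the root; the default cap of 3 allows up
to 8 leaves). No pruning, no surrogate splits. Records missing the split
feature are either excluded from the subtree (default) or routed with the
majority branch. Left branch takes values strictly below the threshold,
right branch values at or above it, matching the ">= -4.4 SD" phrasing of
the published rule; ties in impurity gain resolve to the lowest feature
index, then the smallest threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import PatientRecord, percent_truncated

_GAIN_TOL = 1e-12


def gini_impurity(class_counts: Sequence[int]) -> float:
    """Gini impurity 1 - sum(p_k^2) of a node's class counts."""
    counts = np.asarray(class_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("class counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise ValueError("class counts must not be all zero")
    p = counts / total
    return float(1.0 - (p**2).sum())


@dataclass
class TreeConfig:
    min_split: int = 3  # smallest node that may be split further
    max_depth: int = 3  # edges from the root
    missing_policy: str = "exclude"  # or "majority"

    def __post_init__(self) -> None:
        if self.min_split < 2:
            raise ValueError("min_split must be >= 2")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.missing_policy not in ("exclude", "majority"):
            raise ValueError("missing_policy must be 'exclude' or 'majority'")


@dataclass
class TreeNode:
    depth: int
    counts: dict[str, int]
    prediction: str
    # internal-node fields
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    majority_side: str = "right"  # routing side for missing values, fixed at fit
    leaf_id: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class ClassificationTree:
    root: TreeNode
    feature_names: list[str]
    classes: list[str]
    config: TreeConfig
    n_excluded: int = 0

    def to_dict(self) -> dict:
        def node_dict(n: TreeNode) -> dict:
            d = {"counts": n.counts, "prediction": n.prediction, "depth": n.depth}
            if n.is_leaf:
                d["leaf_id"] = n.leaf_id
            else:
                d.update(
                    feature=self.feature_names[n.feature],
                    threshold=n.threshold,
                    majority_side=n.majority_side,
                    left=node_dict(n.left),
                    right=node_dict(n.right),
                )
            return d

        return {
            "features": self.feature_names,
            "classes": self.classes,
            "min_split": self.config.min_split,
            "max_depth": self.config.max_depth,
            "missing_policy": self.config.missing_policy,
            "n_excluded": self.n_excluded,
            "root": node_dict(self.root),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def format_text(self) -> str:
        lines: list[str] = []

        def walk(n: TreeNode, prefix: str) -> None:
            if n.is_leaf:
                lines.append(
                    f"{prefix}leaf#{n.leaf_id}: predict {n.prediction} {n.counts}"
                )
            else:
                name = self.feature_names[n.feature]
                lines.append(f"{prefix}if {name} < {n.threshold:g}: {n.counts}")
                walk(n.left, prefix + "  ")
                lines.append(f"{prefix}else ({name} >= {n.threshold:g}):")
                walk(n.right, prefix + "  ")

        walk(self.root, "")
        return "\n".join(lines)

    def depth(self) -> int:
        def d(n: TreeNode) -> int:
            return 0 if n.is_leaf else 1 + max(d(n.left), d(n.right))

        return d(self.root)


def _class_counts(labels: np.ndarray, classes: list[str]) -> dict[str, int]:
    return {c: int((labels == c).sum()) for c in classes}


def best_split(X: np.ndarray, y: np.ndarray) -> tuple[int, float, float] | None:
    """Exhaustive search over (feature, midpoint) splits maximising Gini decrease.

    Gain for a feature is computed over the rows where it is observed:
    impurity(observed) - weighted child impurity, weighted by the observed
    fraction of the node so features with many missing values are not
    favoured. Returns (feature, threshold, gain) or None when no split has
    positive gain. Ties: lowest feature index, then smallest threshold.
    """
    n, n_feat = X.shape
    classes, y_codes = np.unique(y, return_inverse=True)
    k = classes.size
    best: tuple[int, float, float] | None = None
    for f in range(n_feat):
        col = X[:, f]
        obs = np.isfinite(col)
        n_obs = int(obs.sum())
        if n_obs < 2:
            continue
        v = col[obs]
        lab = y_codes[obs]
        order = np.argsort(v, kind="stable")
        v, lab = v[order], lab[order]
        distinct = np.nonzero(np.diff(v) > 0)[0]  # split after position i
        if distinct.size == 0:
            continue
        onehot = np.zeros((n_obs, k))
        onehot[np.arange(n_obs), lab] = 1.0
        cum = onehot.cumsum(axis=0)
        total = cum[-1]
        parent_imp = 1.0 - ((total / n_obs) ** 2).sum()
        for i in distinct:
            left = cum[i]
            right = total - left
            nl, nr = i + 1.0, n_obs - i - 1.0
            imp_l = 1.0 - ((left / nl) ** 2).sum()
            imp_r = 1.0 - ((right / nr) ** 2).sum()
            gain = (n_obs / n) * (
                parent_imp - (nl / n_obs) * imp_l - (nr / n_obs) * imp_r
            )
            thr = (v[i] + v[i + 1]) / 2.0
            if gain <= _GAIN_TOL:
                continue
            if (
                best is None
                or gain > best[2] + _GAIN_TOL
                or (abs(gain - best[2]) <= _GAIN_TOL and (f, thr) < (best[0], best[1]))
            ):
                best = (f, thr, gain)
    return best


def fit_tree(
    X,
    y,
    feature_names: Sequence[str] | None = None,
    config: TreeConfig | None = None,
) -> ClassificationTree:
    """Fit a classification tree by greedy recursive binary partitioning.

    ``X`` is (n, features) with NaN for missing, ``y`` string class labels.
    Deterministic given input order: ties between equal-gain splits go to the
    lowest feature index, then the smallest threshold. A record missing the
    chosen split feature is excluded from the subtree (default policy) or
    routed to the branch that received the majority of observed records.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a nonempty 2-D feature matrix")
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y lengths differ")
    config = config or TreeConfig()
    feature_names = (
        list(feature_names)
        if feature_names is not None
        else [f"x{i}" for i in range(X.shape[1])]
    )
    classes = sorted({str(c) for c in y})
    y = y.astype(str)
    excluded = 0
    next_leaf = iter(range(10**6))

    def majority(labels: np.ndarray) -> str:
        counts = _class_counts(labels, classes)
        top = max(counts.values())
        return next(c for c in classes if counts[c] == top)  # ties: class order

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        nonlocal excluded
        labels = y[idx]
        counts = _class_counts(labels, classes)
        node = TreeNode(depth=depth, counts=counts, prediction=majority(labels))
        if (
            depth >= config.max_depth
            or idx.size < config.min_split
            or len(set(labels)) <= 1
        ):
            node.leaf_id = next(next_leaf)
            return node
        split = best_split(X[idx], labels)
        if split is None:
            node.leaf_id = next(next_leaf)
            return node
        f, thr, _ = split
        col = X[idx, f]
        obs = np.isfinite(col)
        go_left = obs & (col < thr)
        go_right = obs & (col >= thr)
        node.majority_side = "left" if go_left.sum() > go_right.sum() else "right"
        miss = ~obs
        if config.missing_policy == "majority" and miss.any():
            if node.majority_side == "left":
                go_left = go_left | miss
            else:
                go_right = go_right | miss
        else:
            excluded += int(miss.sum())
        node.feature, node.threshold = f, thr
        node.left = build(idx[go_left], depth + 1)
        node.right = build(idx[go_right], depth + 1)
        return node

    root = build(np.arange(X.shape[0]), 0)
    return ClassificationTree(
        root=root,
        feature_names=feature_names,
        classes=classes,
        config=config,
        n_excluded=excluded,
    )


EXCLUDED = "excluded"


def predict(tree: ClassificationTree, x) -> tuple[str, int | None]:
    """Route one feature vector down the tree; returns (class, leaf_id).

    A value equal to the threshold goes right (the ">=" branch). A missing
    split feature yields ("excluded", None) under the exclude policy, or
    follows the branch that held the training majority under "majority".
    """
    x = np.asarray(x, dtype=float)
    node = tree.root
    while not node.is_leaf:
        v = x[node.feature]
        if np.isfinite(v):
            node = node.left if v < node.threshold else node.right
        elif tree.config.missing_policy == "majority":
            node = node.left if node.majority_side == "left" else node.right
        else:
            return EXCLUDED, None
    return node.prediction, node.leaf_id


def branch_purity(n_target_in_branch: int, n_in_branch: int) -> int:
    """Whole-number percent of a branch's cases carrying the target label, truncated."""
    if n_in_branch <= 0:
        raise ValueError("branch is empty")
    if not (0 <= n_target_in_branch <= n_in_branch):
        raise ValueError("target count must be between 0 and the branch size")
    return int(percent_truncated(n_target_in_branch, n_in_branch, 0))


# ---------------------------------------------------------------------------
# records <-> feature matrix

DEFAULT_FEATURES = (
    "birth_weight_sd",
    "weight_sd",
    "ofc_sd",
    "severity_score",
    "gestalt",
)


def records_to_matrix(
    records: Sequence[PatientRecord], features: Sequence[str] = DEFAULT_FEATURES
) -> np.ndarray:
    """Feature matrix from PatientRecords; "gestalt" means the per-patient mean."""
    out = np.full((len(records), len(features)), np.nan)
    for i, rec in enumerate(records):
        for j, name in enumerate(features):
            v = rec.gestalt_mean if name == "gestalt" else getattr(rec, name)
            if v is not None:
                out[i, j] = v
    return out


# ---------------------------------------------------------------------------
# NIPBL-like filter

@dataclass
class NipblLikeFilter:
    """Two-condition rule flagging probable undetected NIPBL (mosaic) cases.

    Flag a record iff weight_sd is strictly below ``weight_below`` AND
    birth_weight_sd is at or above ``birth_weight_at_least``: severe
    postnatal growth failure without the extreme prenatal failure.
    """

    weight_below: float = -2.4
    birth_weight_at_least: float = -4.4

    def __post_init__(self) -> None:
        if not (np.isfinite(self.weight_below) and np.isfinite(self.birth_weight_at_least)):
            raise ValueError("filter thresholds must be finite")

    def matches(self, rec: PatientRecord) -> bool:
        if rec.weight_sd is None or rec.birth_weight_sd is None:
            return False
        return (
            rec.weight_sd < self.weight_below
            and rec.birth_weight_sd >= self.birth_weight_at_least
        )


@dataclass
class FilterResult:
    flagged: list[PatientRecord]
    n_total: int
    percent: int  # truncated whole-number percent of the input flagged

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)


def apply_nipbl_like_filter(
    records: Sequence[PatientRecord], filt: NipblLikeFilter | None = None
) -> FilterResult:
    """Apply the NIPBL-like rule; records missing either feature are unflagged
    but stay in the denominator."""
    if not records:
        raise ValueError("cannot filter an empty record list")
    filt = filt or NipblLikeFilter()
    flagged = [r for r in records if filt.matches(r)]
    return FilterResult(
        flagged=flagged,
        n_total=len(records),
        percent=int(percent_truncated(len(flagged), len(records), 0)),
    )
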