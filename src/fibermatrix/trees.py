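"""CART-style recursive binary partitioning (regression + classification).

Written in-house so split tie-breaking is fully deterministic: among
equally good splits the lowest feature index wins, then the lowest
threshold.  Candidate thresholds are midpoints between consecutive
distinct sorted feature values.  Regression minimises within-leaf
variance (SSE); classification minimises Gini impurity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_TOL = 1e-12


@dataclass
class TreeNode:
    n: int
    prediction: float  # mean (regression) or majority class (classification)
    impurity: float  # SSE contribution or Gini
    purity: float | None = None  # majority fraction, classification only
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self, feature_names: list[str] | None = None) -> dict:
        d: dict = {"n": self.n, "prediction": self.prediction}
        if self.purity is not None:
            d["purity"] = self.purity
        if not self.is_leaf:
            name = (
                feature_names[self.feature]
                if feature_names
                else f"x{self.feature}"
            )
            d.update(
                split_feature=name,
                split_threshold=self.threshold,
                left=self.left.to_dict(feature_names),
                right=self.right.to_dict(feature_names),
            )
        return d


@dataclass
class TreeModel:
    root: TreeNode
    kind: str  # "regression" | "classification"
    feature_names: list[str]
    max_depth: int
    min_leaf: int
    depth: int = 0
    leaf_count: int = 0
    r_squared: float | None = None
    confusion: dict | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        out = np.empty(len(X))
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.prediction
        return out

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "feature_names": self.feature_names,
            "depth": self.depth,
            "leaf_count": self.leaf_count,
            "r_squared": self.r_squared,
            "confusion": self.confusion,
            "root": self.root.to_dict(self.feature_names),
        }

    def to_dot(self) -> str:
        lines = ["digraph tree {", "  node [shape=box];"]
        counter = [0]

        def walk(node: TreeNode) -> int:
            my_id = counter[0]
            counter[0] += 1
            if node.is_leaf:
                label = f"n={node.n}\\npred={node.prediction:.4g}"
                if node.purity is not None:
                    label += f"\\npurity={node.purity:.2f}"
                lines.append(f'  n{my_id} [label="{label}"];')
            else:
                name = self.feature_names[node.feature]
                lines.append(
                    f'  n{my_id} [label="{name} <= {node.threshold:.4g}\\nn={node.n}"];'
                )
                for child in (node.left, node.right):
                    cid = walk(child)
                    lines.append(f"  n{my_id} -> n{cid};")
            return my_id

        walk(self.root)
        lines.append("}")
        return "\n".join(lines)


def _best_split_sse(
    X: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[int, float, float] | None:
    """Best (feature, threshold, gain) for regression; None if no valid split.

    Gain = parent SSE - (left SSE + right SSE), computed via cumulative
    sums over each feature's sort order.
    """
    n = len(y)
    parent_sse = float(((y - y.mean()) ** 2).sum())
    best: tuple[int, float, float] | None = None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        csum = np.cumsum(ys)
        csum2 = np.cumsum(ys**2)
        total, total2 = csum[-1], csum2[-1]
        for i in range(min_leaf - 1, n - min_leaf):
            if xs[i + 1] - xs[i] <= _TOL:
                continue
            nl = i + 1
            nr = n - nl
            sse_l = csum2[i] - csum[i] ** 2 / nl
            sse_r = (total2 - csum2[i]) - (total - csum[i]) ** 2 / nr
            gain = parent_sse - (sse_l + sse_r)
            thr = 0.5 * (xs[i] + xs[i + 1])
            if gain > _TOL and (
                best is None
                or gain > best[2] + _TOL
                or (abs(gain - best[2]) <= _TOL and (j, thr) < (best[0], best[1]))
            ):
                best = (j, thr, gain)
    return best


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p**2).sum())


def _best_split_gini(
    X: np.ndarray, y: np.ndarray, n_classes: int, min_leaf: int
) -> tuple[int, float, float] | None:
    n = len(y)
    parent = _gini(np.bincount(y, minlength=n_classes)) * n
    best: tuple[int, float, float] | None = None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), ys] = 1.0
        ccum = np.cumsum(onehot, axis=0)
        total = ccum[-1]
        for i in range(min_leaf - 1, n - min_leaf):
            if xs[i + 1] - xs[i] <= _TOL:
                continue
            nl = i + 1
            nr = n - nl
            left_counts = ccum[i]
            right_counts = total - left_counts
            child = _gini(left_counts) * nl + _gini(right_counts) * nr
            gain = parent - child
            thr = 0.5 * (xs[i] + xs[i + 1])
            if gain > _TOL and (
                best is None
                or gain > best[2] + _TOL
                or (abs(gain - best[2]) <= _TOL and (j, thr) < (best[0], best[1]))
            ):
                best = (j, thr, gain)
    return best


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    depth: int,
    max_depth: int,
    min_leaf: int,
    kind: str,
    n_classes: int,
) -> TreeNode:
    n = len(y)
    if kind == "regression":
        node = TreeNode(
            n=n,
            prediction=float(y.mean()),
            impurity=float(((y - y.mean()) ** 2).sum()),
        )
    else:
        counts = np.bincount(y, minlength=n_classes)
        maj = int(counts.argmax())
        node = TreeNode(
            n=n,
            prediction=float(maj),
            impurity=_gini(counts),
            purity=float(counts[maj] / n),
        )
    if depth >= max_depth or n < 2 * min_leaf:
        return node
    split = (
        _best_split_sse(X, y, min_leaf)
        if kind == "regression"
        else _best_split_gini(X, y, n_classes, min_leaf)
    )
    if split is None:
        return node
    j, thr, _ = split
    mask = X[:, j] <= thr
    node.feature = j
    node.threshold = thr
    node.left = _grow(
        X[mask], y[mask], depth + 1, max_depth, min_leaf, kind, n_classes
    )
    node.right = _grow(
        X[~mask], y[~mask], depth + 1, max_depth, min_leaf, kind, n_classes
    )
    return node


def _tree_stats(node: TreeNode, depth: int = 0) -> tuple[int, int]:
    if node.is_leaf:
        return depth, 1
    dl, ll = _tree_stats(node.left, depth + 1)
    dr, lr = _tree_stats(node.right, depth + 1)
    return max(dl, dr), ll + lr


def fit_regression_tree(
    X: np.ndarray,
    y: np.ndarray,
    max_depth: int = 4,
    min_leaf: int = 5,
    feature_names: list[str] | None = None,
) -> TreeModel:
    """Greedy CART regression tree; in-sample R² reported (no validation
    split).  A constant target yields a root-only tree with R² = 0."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) < 2 * min_leaf:
        raise ValueError(
            f"need at least 2*min_leaf = {2 * min_leaf} rows, got {len(y)}"
        )
    root = _grow(X, y, 0, max_depth, min_leaf, "regression", 0)
    model = TreeModel(
        root=root,
        kind="regression",
        feature_names=feature_names or [f"x{j}" for j in range(X.shape[1])],
        max_depth=max_depth,
        min_leaf=min_leaf,
    )
    model.depth, model.leaf_count = _tree_stats(root)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= _TOL:
        model.r_squared = 0.0
    else:
        resid = y - model.predict(X)
        model.r_squared = float(1.0 - (resid**2).sum() / ss_tot)
    return model


def fit_classification_tree(
    X: np.ndarray,
    y: np.ndarray,
    max_depth: int = 4,
    min_leaf: int = 5,
    feature_names: list[str] | None = None,
) -> TreeModel:
    """Greedy CART classification tree (Gini impurity) over integer class
    labels; training-set confusion counts attached."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) < 2 * min_leaf:
        raise ValueError(
            f"need at least 2*min_leaf = {2 * min_leaf} rows, got {len(y)}"
        )
    n_classes = int(y.max()) + 1 if len(y) else 1
    root = _grow(X, y, 0, max_depth, min_leaf, "classification", n_classes)
    model = TreeModel(
        root=root,
        kind="classification",
        feature_names=feature_names or [f"x{j}" for j in range(X.shape[1])],
        max_depth=max_depth,
        min_leaf=min_leaf,
    )
    model.depth, model.leaf_count = _tree_stats(root)
    pred = model.predict(X).astype(int)
    conf: dict[str, int] = {}
    for t in range(n_classes):
        for p in range(n_classes):
            conf[f"true{t}_pred{p}"] = int(((y == t) & (pred == p)).sum())
    model.confusion = conf
    return model
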