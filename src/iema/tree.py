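"""CART classification tree for cluster-predictive biomarker selection.

Greedy binary recursive partitioning on Gini impurity, splitting at
midpoints between consecutive sorted distinct expression values.  The
fit is fully deterministic and order-independent: ties between equally
good splits break by smallest gene index, then smallest threshold.
Samples with a value below the threshold go left; at-or-above goes right.
The distinct split genes, in breadth-first node order, are the selected
biomarkers.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TreeParams",
    "TreeNode",
    "TreeModel",
    "fit_cart",
    "predict_tree",
    "predict_frame",
    "accuracy",
    "extract_biomarkers",
]


@dataclass
class TreeParams:
    min_leaf: int = 5
    max_depth: int = 6
    complexity: float = 0.0  # minimum (node-weighted) Gini decrease to accept a split

    def __post_init__(self) -> None:
        if self.min_leaf < 1 or self.max_depth < 0:
            raise ValueError("min_leaf must be >= 1 and max_depth >= 0")


@dataclass
class TreeNode:
    """Internal node (gene + threshold) or leaf (label + class counts)."""

    gene: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    label: str | None = None
    class_counts: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.gene is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": True, "label": self.label, "class_counts": dict(self.class_counts)}
        return {
            "leaf": False,
            "gene": self.gene,
            "threshold": float(self.threshold),
            "class_counts": dict(self.class_counts),
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }


@dataclass
class TreeModel:
    root: TreeNode
    params: TreeParams
    classes: list

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "params": {
                "min_leaf": self.params.min_leaf,
                "max_depth": self.params.max_depth,
                "complexity": self.params.complexity,
            },
            "tree": self.root.to_dict(),
        }

    def render(self) -> str:
        """Text rendering of the tree, one node per line."""
        lines = []

        def walk(node, depth, prefix):
            pad = "  " * depth
            if node.is_leaf:
                lines.append(f"{pad}{prefix}-> {node.label} {dict(node.class_counts)}")
            else:
                lines.append(f"{pad}{prefix}{node.gene} < {node.threshold:g}?")
                walk(node.left, depth + 1, "yes: ")
                walk(node.right, depth + 1, "no:  ")

        walk(self.root, 0, "")
        return "\n".join(lines)


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p**2).sum())


def _majority(y: np.ndarray, classes: list) -> tuple[str, dict]:
    cnt = Counter(y.tolist())
    counts = {c: int(cnt.get(c, 0)) for c in classes if cnt.get(c, 0) > 0}
    # deterministic majority: max count, then class order
    label = max(counts, key=lambda c: (counts[c], -classes.index(c)))
    return label, counts


def _best_split(X: np.ndarray, y_codes: np.ndarray, n_classes: int, params: TreeParams):
    """Best (gene index, threshold) by Gini decrease; None if no valid split.

    Vectorized over thresholds per gene via sorted class-count prefixes.
    """
    n, G = X.shape
    parent_counts = np.bincount(y_codes, minlength=n_classes).astype(float)
    parent_gini = _gini(parent_counts)
    best = None  # (decrease, gene_idx, threshold)
    for g in range(G):
        x = X[:, g]
        order = np.argsort(x, kind="mergesort")
        xs = x[order]
        ys = y_codes[order]
        # prefix class counts after each position
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), ys] = 1.0
        prefix = np.cumsum(onehot, axis=0)
        # candidate split after position i (left = 0..i) where value changes
        change = np.nonzero(xs[1:] > xs[:-1])[0]
        if change.size == 0:
            continue
        nl = change + 1
        nr = n - nl
        valid = (nl >= params.min_leaf) & (nr >= params.min_leaf)
        if not valid.any():
            continue
        change = change[valid]
        nl = nl[valid]
        nr = nr[valid]
        left_counts = prefix[change]
        right_counts = parent_counts[None, :] - left_counts
        gl = 1.0 - ((left_counts / nl[:, None]) ** 2).sum(axis=1)
        gr = 1.0 - ((right_counts / nr[:, None]) ** 2).sum(axis=1)
        decrease = parent_gini - (nl * gl + nr * gr) / n
        i_best = int(np.argmax(decrease))
        d = float(decrease[i_best])
        thr = float((xs[change[i_best]] + xs[change[i_best] + 1]) / 2.0)
        # tie-break: larger decrease wins; then smaller gene index (loop order);
        # within a gene, np.argmax takes the first (smallest threshold)
        if best is None or d > best[0] + 1e-12:
            best = (d, g, thr)
    return best


def fit_cart(expr: pd.DataFrame, labels, params: TreeParams | None = None) -> TreeModel:
    """Fit a CART model predicting cluster labels from expression.

    ``expr`` is samples x genes; ``labels`` gives one class per sample.
    """
    if params is None:
        params = TreeParams()
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise ValueError("empty expression matrix")
    if isinstance(labels, (pd.Series, dict)):
        y = pd.Series(labels).reindex(expr.index).to_numpy()
    else:
        y = np.asarray(labels)
        if len(y) != expr.shape[0]:
            raise ValueError("labels length does not match sample count")
    if pd.isna(y).any():
        raise ValueError("every sample needs a label")
    X = expr.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("expression matrix contains missing values")
    classes = sorted(set(map(str, y)))
    y = np.asarray([str(v) for v in y])
    code = {c: i for i, c in enumerate(classes)}
    y_codes = np.asarray([code[v] for v in y])
    genes = list(expr.columns)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        label, counts = _majority(y[idx], classes)
        node = TreeNode(label=label, class_counts=counts)
        if depth >= params.max_depth or len(set(y_codes[idx])) == 1 or len(idx) < 2 * params.min_leaf:
            return node
        found = _best_split(X[idx], y_codes[idx], len(classes), params)
        if found is None or found[0] <= params.complexity:
            return node
        _, g, thr = found
        go_left = X[idx, g] < thr
        node.gene = genes[g]
        node.threshold = thr
        node.label = None
        node.left = build(idx[go_left], depth + 1)
        node.right = build(idx[~go_left], depth + 1)
        node.class_counts = counts
        return node

    root = build(np.arange(len(y)), 0)
    return TreeModel(root=root, params=params, classes=classes)


def predict_tree(model: TreeModel, sample_expr) -> str:
    """Route one sample (Series or mapping gene -> value) to its leaf label."""
    node = model.root
    while not node.is_leaf:
        try:
            v = sample_expr[node.gene]
        except (KeyError, IndexError):
            raise ValueError(f"sample is missing split gene {node.gene!r}") from None
        node = node.left if v < node.threshold else node.right
    return node.label


def predict_frame(model: TreeModel, expr: pd.DataFrame) -> pd.Series:
    return pd.Series([predict_tree(model, row) for _, row in expr.iterrows()], index=expr.index)


def accuracy(model: TreeModel, expr: pd.DataFrame, labels) -> float:
    pred = predict_frame(model, expr)
    if isinstance(labels, (pd.Series, dict)):
        truth = pd.Series(labels).reindex(expr.index).astype(str)
    else:
        truth = pd.Series(list(map(str, labels)), index=expr.index)
    return float((pred == truth).mean())


def extract_biomarkers(model: TreeModel) -> list:
    """Distinct split genes in breadth-first node order."""
    out = []
    seen = set()
    queue = deque([model.root])
    while queue:
        node = queue.popleft()
        if node.is_leaf:
            continue
        if node.gene not in seen:
            seen.add(node.gene)
            out.append(node.gene)
        queue.append(node.left)
        queue.append(node.right)
    return out
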