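"""Least-squares binary regression tree (CART-style), from scratch.

Growth is an exhaustive search: at every node each candidate split — every
predictor crossed with every midpoint between consecutive distinct observed
values — is scored by the summed within-child squared error, and the best
one is taken.  A nested subtree sequence is produced by weakest-link
pruning (iteratively collapsing the internal node whose removal increases
training SSE least), tree size is selected on held-out R², predictions are
terminal-node means, and variable importance accumulates per-node SSE
improvement for primary (and optionally surrogate) splitters.

Node standard deviations use the n divisor (population SD), matching how
node purity is conventionally displayed on tree diagrams.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthControl",
    "SplitRule",
    "TreeNode",
    "RegressionTree",
    "partition",
    "grow",
    "predict",
    "evaluate",
    "SizeSelection",
    "subtree_sequence",
    "importance",
]


@dataclass(frozen=True)
class GrowthControl:
    """Stopping rules for tree growth.

    A node is split only while it holds at least ``min_split_n`` cases,
    both children would hold at least ``min_leaf_n``, the node sits above
    ``max_depth``, and some split strictly reduces the training SSE.

    The defaults (10 / 2 / 4) reproduce the case study's published tree:
    there, every internal node holds at least 10 cases and every terminal
    node fewer, and the tree is four levels deep.
    """

    min_split_n: int = 10
    min_leaf_n: int = 2
    max_depth: int = 4


@dataclass(frozen=True)
class SplitRule:
    variable: str
    var_index: int
    threshold: float  # left branch: value <= threshold


@dataclass
class TreeNode:
    node_id: int
    n: int
    mean: float
    sd: float  # population SD (n divisor)
    sse: float  # training SSE at this node
    depth: int
    split: SplitRule | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    terminal_id: int | None = None

    @property
    def is_terminal(self) -> bool:
        return self.split is None

    def collapse(self) -> None:
        self.split = None
        self.left = None
        self.right = None


class RegressionTree:
    """A grown (or pruned) least-squares regression tree."""

    def __init__(self, root: TreeNode, feature_names: Sequence[str]):
        self.root = root
        self.feature_names = list(feature_names)
        self.renumber_terminals()

    # -- structure -----------------------------------------------------
    def nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(nd: TreeNode) -> None:
            out.append(nd)
            if not nd.is_terminal:
                walk(nd.left)
                walk(nd.right)

        walk(self.root)
        return out

    def leaves(self) -> list[TreeNode]:
        return [nd for nd in self.nodes() if nd.is_terminal]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def renumber_terminals(self) -> None:
        """Assign terminal ids 1..k left-to-right (in-order)."""
        counter = 0

        def walk(nd: TreeNode) -> None:
            nonlocal counter
            if nd.is_terminal:
                counter += 1
                nd.terminal_id = counter
            else:
                nd.terminal_id = None
                walk(nd.left)
                walk(nd.right)

        walk(self.root)

    def leaf_for(self, x: np.ndarray) -> TreeNode:
        nd = self.root
        while not nd.is_terminal:
            v = x[nd.split.var_index]
            if np.isnan(v):
                raise ValueError(f"missing predictor {nd.split.variable!r}")
            nd = nd.left if v <= nd.split.threshold else nd.right
        return nd

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Route rows of ``X``; return (fitted values, terminal ids)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError("predictor width mismatch")
        leaves = [self.leaf_for(row) for row in X]
        return (
            np.array([nd.mean for nd in leaves]),
            np.array([nd.terminal_id for nd in leaves]),
        )

    def to_dict(self) -> dict:
        """Nested JSON-ready structure (id, n, mean, sd, split, children)."""

        def enc(nd: TreeNode) -> dict:
            d = {
                "id": nd.node_id,
                "n": nd.n,
                "mean": round(float(nd.mean), 6),
                "sd": round(float(nd.sd), 6),
            }
            if nd.is_terminal:
                d["terminal_id"] = nd.terminal_id
            else:
                d["split"] = {"variable": nd.split.variable, "threshold": nd.split.threshold}
                d["children"] = [enc(nd.left), enc(nd.right)]
            return d

        return enc(self.root)

    def rules_for_leaf(self, terminal_id: int) -> list[tuple[str, str, float]]:
        """Path conditions (variable, '<=' or '>', threshold) to a leaf."""

        def walk(nd: TreeNode, path):
            if nd.is_terminal:
                return path if nd.terminal_id == terminal_id else None
            for child, op in ((nd.left, "<="), (nd.right, ">")):
                got = walk(child, path + [(nd.split.variable, op, nd.split.threshold)])
                if got is not None:
                    return got
            return None

        rules = walk(self.root, [])
        if rules is None:
            raise KeyError(f"no terminal node {terminal_id}")
        return rules


def partition(n: int, test_fraction: float, seed: int) -> np.ndarray:
    """Random Training/Test labels at the given fraction, reproducible by seed.

    Test size is ``round(test_fraction * n)`` without replacement.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    n_test = int(round(test_fraction * n))
    if n_test == 0 or n_test == n:
        raise ValueError("fraction leaves an empty training or test set")
    rng = np.random.default_rng(seed)
    labels = np.full(n, "Training", dtype=object)
    labels[rng.choice(n, size=n_test, replace=False)] = "Test"
    return labels


def _sse(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum()) if y.size else 0.0


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf_n: int):
    """Exhaustive candidate scan; returns (var_index, threshold, child_sse).

    Candidates are midpoints between consecutive distinct values of each
    variable.  Ties break toward the smaller variable index, then the
    smaller threshold (enforced by scan order with strict improvement).
    """
    best = None
    for j in range(X.shape[1]):
        xs = X[:, j]
        uniq = np.unique(xs)
        for a, b in zip(uniq[:-1], uniq[1:]):
            thr = (a + b) / 2.0
            mask = xs <= thr
            n_left = int(mask.sum())
            if n_left < min_leaf_n or (len(y) - n_left) < min_leaf_n:
                continue
            sse = _sse(y[mask]) + _sse(y[~mask])
            if best is None or sse < best[2] - 1e-12:
                best = (j, thr, sse)
    return best


def grow(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    control: GrowthControl | None = None,
) -> RegressionTree:
    """Grow a least-squares tree by recursive exhaustive split search."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    control = control or GrowthControl()
    feature_names = list(feature_names)
    next_id = [1]

    def build(rows: np.ndarray, depth: int) -> TreeNode:
        yy = y[rows]
        node = TreeNode(
            node_id=next_id[0],
            n=len(rows),
            mean=float(yy.mean()),
            sd=float(yy.std(ddof=0)),
            sse=_sse(yy),
            depth=depth,
        )
        next_id[0] += 1
        if len(rows) >= control.min_split_n and depth < control.max_depth:
            found = _best_split(X[rows], yy, control.min_leaf_n)
            if found is not None and node.sse - found[2] > 1e-12:
                j, thr, _ = found
                mask = X[rows, j] <= thr
                node.split = SplitRule(feature_names[j], j, float(thr))
                node.left = build(rows[mask], depth + 1)
                node.right = build(rows[~mask], depth + 1)
        return node

    return RegressionTree(build(np.arange(len(y)), 0), feature_names)


def predict(tree: RegressionTree, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Functional alias for :meth:`RegressionTree.predict`."""
    return tree.predict(X)


def evaluate(tree: RegressionTree, X: np.ndarray, y: np.ndarray) -> dict:
    """MSE, RMSE and R^2 of the tree on an evaluation set.

    R^2 is computed about the evaluation set's own mean and is NaN when
    that set has zero variance (MSE is still returned).
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty evaluation set")
    fitted, _ = tree.predict(X)
    sse = float(((y - fitted) ** 2).sum())
    sst = _sse(y)
    mse = sse / y.size
    return {
        "mse": mse,
        "rmse": float(np.sqrt(mse)),
        "r2": (1.0 - sse / sst) if sst > 0 else float("nan"),
    }


@dataclass
class SizeSelection:
    """Nested subtree sequence with per-size train/test metrics.

    ``metrics`` is indexed by terminal-node count with columns
    ``train_mse/train_rmse/train_r2_pct`` and test counterparts; R^2 is in
    percent.  ``selected_size`` is the smallest size whose test R^2 lies
    within ``band`` percentage points of the maximum test R^2;
    ``best_size`` maximizes test R^2 outright.
    """

    metrics: pd.DataFrame
    trees: dict[int, RegressionTree]
    selected_size: int
    best_size: int
    band: float = 1.0

    @property
    def selected_tree(self) -> RegressionTree:
        return self.trees[self.selected_size]


def subtree_sequence(
    tree: RegressionTree,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
    band: float = 1.0,
) -> SizeSelection:
    """Weakest-link pruning sequence from the full tree down to the root.

    At each step the internal node with two terminal children whose
    collapse increases training SSE least is collapsed, giving one subtree
    per terminal-node count.  With a test set, the selected size is the
    smallest whose test R^2 (percent) is within ``band`` of the maximum;
    without one, selection falls back to the full tree.
    """
    work = copy.deepcopy(tree)
    snapshots: dict[int, RegressionTree] = {}
    rows = []

    def record(t: RegressionTree) -> None:
        snap = copy.deepcopy(t)
        snap.renumber_terminals()
        k = snap.n_leaves
        snapshots[k] = snap
        tr = evaluate(snap, X_train, y_train)
        row = {
            "n_leaves": k,
            "train_mse": tr["mse"],
            "train_rmse": tr["rmse"],
            "train_r2_pct": 100.0 * tr["r2"],
        }
        if X_test is not None:
            te = evaluate(snap, X_test, y_test)
            row.update(test_mse=te["mse"], test_rmse=te["rmse"], test_r2_pct=100.0 * te["r2"])
        rows.append(row)

    record(work)
    while work.n_leaves > 1:
        candidates = [
            nd
            for nd in work.nodes()
            if not nd.is_terminal and nd.left.is_terminal and nd.right.is_terminal
        ]
        weakest = min(candidates, key=lambda nd: nd.sse - (nd.left.sse + nd.right.sse))
        weakest.collapse()
        record(work)

    metrics = pd.DataFrame(rows).set_index("n_leaves").sort_index()
    if X_test is not None:
        best_size = int(metrics["test_r2_pct"].idxmax())
        top = metrics["test_r2_pct"].max()
        ok = metrics.index[metrics["test_r2_pct"] >= top - band]
        selected = int(min(ok))
    else:
        best_size = selected = int(metrics.index.max())
    return SizeSelection(metrics, snapshots, selected, best_size, band)


def _route_masks(tree: RegressionTree, X: np.ndarray):
    """Yield (node, row-index array) for every node, routing X from the root."""
    out = []

    def walk(nd: TreeNode, rows: np.ndarray) -> None:
        out.append((nd, rows))
        if not nd.is_terminal:
            mask = X[rows, nd.split.var_index] <= nd.split.threshold
            walk(nd.left, rows[mask])
            walk(nd.right, rows[~mask])

    walk(tree.root, np.arange(X.shape[0]))
    return out


def importance(
    tree: RegressionTree,
    X: np.ndarray,
    y: np.ndarray,
    use_surrogates: bool = False,
) -> pd.DataFrame:
    """Relative variable importance from accumulated split improvements.

    Each internal node credits its primary splitter with the SSE reduction
    it achieves.  With ``use_surrogates``, every other variable is credited
    with the SSE reduction of its best surrogate split at that node — the
    split on it most agreeing with the primary left/right partition —
    provided the agreement beats sending all cases with the majority.
    Scores are rescaled so the leading variable reads 100%.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    scores = {name: 0.0 for name in tree.feature_names}
    for nd, rows in _route_masks(tree, X):
        if nd.is_terminal or rows.size == 0:
            continue
        yy = y[rows]
        node_sse = _sse(yy)
        primary_mask = X[rows, nd.split.var_index] <= nd.split.threshold
        improvement = node_sse - _sse(yy[primary_mask]) - _sse(yy[~primary_mask])
        scores[nd.split.variable] += max(improvement, 0.0)
        if not use_surrogates:
            continue
        n_left = int(primary_mask.sum())
        majority = max(n_left, rows.size - n_left)
        for j, name in enumerate(tree.feature_names):
            if j == nd.split.var_index:
                continue
            xs = X[rows, j]
            uniq = np.unique(xs)
            best_agree, best_mask = -1, None
            for a, b in zip(uniq[:-1], uniq[1:]):
                thr = (a + b) / 2.0
                mask = xs <= thr
                # a surrogate may mirror the primary partition directly or flipped
                agree = max(int((mask == primary_mask).sum()), int((mask != primary_mask).sum()))
                if agree > best_agree:
                    best_agree, best_mask = agree, mask
            if best_mask is not None and best_agree > majority:
                gain = node_sse - _sse(yy[best_mask]) - _sse(yy[~best_mask])
                scores[name] += max(gain, 0.0)
    out = pd.DataFrame({"score": pd.Series(scores)})
    top = out["score"].max()
    out["relative_pct"] = 100.0 * out["score"] / top if top > 0 else 0.0
    return out.sort_values("relative_pct", ascending=False)
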