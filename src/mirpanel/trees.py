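"""Recursive-partitioning models: diagnostic classification trees and
survival trees, pruned by cross-validated cost-complexity.

Classification trees split on Gini impurity and are scored by
misclassification risk; survival trees fit an exponential (constant-rate)
model per node — rate = events / total exposure — and split to maximize the
exponential log-likelihood (deviance) reduction.  Both are grown depth-first
under minimum node-size constraints, then the weakest-link cost-complexity
path is computed and the subtree minimizing k-fold cross-validated error is
returned (ties resolved toward the smaller tree).

Leaf "hazard ratios" of survival trees are event-rate ratios against the root
node; a Cox fit on leaf indicators is available as an alternative through
:func:`compare_groups`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .survival import cox_univariate, km_estimate, pairwise_logrank

logger = logging.getLogger(__name__)

CLASSIFY = "classify"
SURVIVAL = "survival"

_EPS = 1e-12


@dataclass
class TreeParams:
    """Growth and pruning defaults (rpart-style conventions)."""

    min_split: int = 20        # smallest node that may be split
    min_leaf: int = 7          # smallest allowed child
    cp: float = 0.01           # complexity threshold on the normalized risk scale
    k_folds: int = 10
    positive_label: str = "case"


@dataclass
class TreeNode:
    node_id: int
    depth: int
    n: int
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    # classification
    class_counts: dict[str, int] | None = None
    prediction: str | None = None
    prob_positive: float | None = None
    # survival
    events: float | None = None
    exposure: float | None = None
    rate: float | None = None
    rate_ratio: float | None = None   # vs root

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def internal(self) -> list["TreeNode"]:
        if self.is_leaf:
            return []
        return [self] + self.left.internal() + self.right.internal()

    def node_ids(self) -> set[int]:
        out = {self.node_id}
        if not self.is_leaf:
            out |= self.left.node_ids() | self.right.node_ids()
        return out

    def to_dict(self) -> dict:
        d: dict = {"node_id": self.node_id, "depth": self.depth, "n": self.n}
        if self.class_counts is not None:
            d.update(
                class_counts=self.class_counts,
                prediction=self.prediction,
                prob_positive=self.prob_positive,
            )
        if self.events is not None:
            d.update(
                events=self.events, exposure=self.exposure,
                rate=self.rate, rate_ratio=self.rate_ratio,
            )
        if not self.is_leaf:
            d.update(
                feature=self.feature, threshold=self.threshold,
                left=self.left.to_dict(), right=self.right.to_dict(),
            )
        return d

    def render(self, indent: int = 0) -> str:
        pad = "  " * indent
        if self.class_counts is not None:
            stats_s = f"n={self.n} counts={self.class_counts} -> {self.prediction}"
        else:
            stats_s = (
                f"n={self.n} events={self.events:.0f} rate_ratio={self.rate_ratio:.2f}"
            )
        if self.is_leaf:
            return f"{pad}leaf[{self.node_id}] {stats_s}"
        head = f"{pad}node[{self.node_id}] {self.feature} <= {self.threshold:.4g} ({stats_s})"
        return "\n".join(
            [head, self.left.render(indent + 1), self.right.render(indent + 1)]
        )


@dataclass
class Tree:
    """Fitted tree plus everything needed to re-grow it during CV."""

    task: str
    root: TreeNode
    features: list[str]
    params: TreeParams
    root_risk: float            # un-normalized resubstitution risk of the root

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(
            json.dumps({"task": self.task, "tree": self.root.to_dict()}, indent=2)
        )


@dataclass
class PruneTrace:
    """Cost-complexity path: one row per candidate subtree."""

    rows: list[dict]            # cp, size, resub_error, cv_error, cv_se
    chosen_cp: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


@dataclass
class ClassifierMetrics:
    accuracy: float
    precision: float
    recall: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int


# ---------------------------------------------------------------------------
# split search
# ---------------------------------------------------------------------------

def _gini_risk(y_pos: np.ndarray) -> float:
    """Misclassification count of a node (risk used for pruning)."""
    pos = int(y_pos.sum())
    return min(pos, len(y_pos) - pos)


def _best_split_gini(x: np.ndarray, y_pos: np.ndarray, min_leaf: int):
    """Best Gini split of one feature; returns (gain, threshold) or None.

    Gain is the decrease in summed Gini impurity n*G; candidates are
    midpoints between distinct consecutive sorted values with both children
    >= min_leaf.
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y_pos[order].astype(float)
    n = len(xs)
    cum_pos = np.cumsum(ys)
    total_pos = cum_pos[-1]
    idx = np.arange(1, n)                      # split after position i-1
    valid = (xs[1:] != xs[:-1]) & (idx >= min_leaf) & ((n - idx) >= min_leaf)
    if not valid.any():
        return None
    nl = idx[valid].astype(float)
    nr = n - nl
    pl = cum_pos[:-1][valid]
    pr = total_pos - pl
    gini_parent = 2.0 * total_pos * (n - total_pos) / n
    gini_l = 2.0 * pl * (nl - pl) / nl
    gini_r = 2.0 * pr * (nr - pr) / nr
    gains = gini_parent - gini_l - gini_r
    j = int(np.argmax(gains))
    pos = idx[valid][j]
    thr = (xs[pos - 1] + xs[pos]) / 2.0
    return float(gains[j]), float(thr)


def _exp_loglik(d: float, t: float) -> float:
    """Profile log-likelihood of an exponential node: d log(d/T) - d."""
    if d <= 0 or t <= 0:
        return 0.0
    return d * (math.log(d / t) - 1.0)


def _best_split_exp(x: np.ndarray, d: np.ndarray, t: np.ndarray, min_leaf: int):
    """Best exponential-deviance split of one feature."""
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ds = d[order].astype(float)
    ts = t[order].astype(float)
    n = len(xs)
    cd = np.cumsum(ds)
    ct = np.cumsum(ts)
    idx = np.arange(1, n)
    valid = (xs[1:] != xs[:-1]) & (idx >= min_leaf) & ((n - idx) >= min_leaf)
    if not valid.any():
        return None
    dl = cd[:-1][valid]
    tl = ct[:-1][valid]
    dr = cd[-1] - dl
    tr = ct[-1] - tl
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_l = np.where(dl > 0, dl * (np.log(dl / tl) - 1.0), 0.0)
        ll_r = np.where(dr > 0, dr * (np.log(dr / tr) - 1.0), 0.0)
    parent = _exp_loglik(cd[-1], ct[-1])
    gains = 2.0 * (ll_l + ll_r - parent)       # deviance reduction
    j = int(np.argmax(gains))
    pos = idx[valid][j]
    thr = (xs[pos - 1] + xs[pos]) / 2.0
    return float(gains[j]), float(thr)


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def _grow(
    X: pd.DataFrame,
    task: str,
    params: TreeParams,
    y_pos: np.ndarray | None = None,
    time: np.ndarray | None = None,
    event: np.ndarray | None = None,
) -> TreeNode:
    counter = [0]
    features = list(X.columns)
    Xv = X.to_numpy(dtype=float)

    if task == SURVIVAL:
        root_rate = event.sum() / time.sum() if time.sum() > 0 else 0.0

    def make_node(idx: np.ndarray, depth: int) -> TreeNode:
        counter[0] += 1
        node = TreeNode(node_id=counter[0], depth=depth, n=len(idx))
        if task == CLASSIFY:
            pos = int(y_pos[idx].sum())
            neg = len(idx) - pos
            node.class_counts = {params.positive_label: pos, "other": neg}
            # ties resolve toward the positive (case) class
            node.prediction = params.positive_label if pos >= neg else "other"
            node.prob_positive = pos / len(idx)
        else:
            d = float(event[idx].sum())
            t = float(time[idx].sum())
            node.events = d
            node.exposure = t
            node.rate = d / t if t > 0 else 0.0
            node.rate_ratio = node.rate / root_rate if root_rate > 0 else math.nan
        return node

    def split_node(node: TreeNode, idx: np.ndarray) -> None:
        if node.n < params.min_split:
            return
        if task == CLASSIFY:
            pos = int(y_pos[idx].sum())
            if pos == 0 or pos == len(idx):
                return
        else:
            if event[idx].sum() == 0:
                return
        best = None
        for f_i, f in enumerate(features):
            col = Xv[idx, f_i]
            if task == CLASSIFY:
                res = _best_split_gini(col, y_pos[idx], params.min_leaf)
            else:
                res = _best_split_exp(col, event[idx], time[idx], params.min_leaf)
            if res is None:
                continue
            gain, thr = res
            if best is None or gain > best[0] + _EPS:
                best = (gain, f_i, thr)
        if best is None or best[0] <= _EPS:
            return
        _, f_i, thr = best
        node.feature = features[f_i]
        node.threshold = thr
        left_mask = Xv[idx, f_i] <= thr
        left_idx, right_idx = idx[left_mask], idx[~left_mask]
        node.left = make_node(left_idx, node.depth + 1)
        node.right = make_node(right_idx, node.depth + 1)
        split_node(node.left, left_idx)
        split_node(node.right, right_idx)

    idx0 = np.arange(len(X))
    root = make_node(idx0, 0)
    split_node(root, idx0)
    return root


def grow_classification_tree(
    X: pd.DataFrame, labels: Sequence[str], params: TreeParams | None = None
) -> Tree:
    """Grow a binary classification tree (Gini splitting).

    ``labels`` are compared against ``params.positive_label``; all other
    labels form the negative class.
    """
    if len(X) == 0:
        raise ValueError("empty training matrix")
    params = params or TreeParams()
    y = np.asarray([l == params.positive_label for l in labels])
    if y.all() or not y.any():
        # pure input: a single leaf is still a valid (trivial) tree
        logger.warning("single class present; tree is a single leaf")
    root = _grow(X, CLASSIFY, params, y_pos=y)
    risk = _gini_risk(y)
    return Tree(task=CLASSIFY, root=root, features=list(X.columns), params=params,
                root_risk=float(max(risk, _EPS)))


def grow_survival_tree(
    X: pd.DataFrame,
    time: Sequence[float],
    event: Sequence[int],
    params: TreeParams | None = None,
) -> Tree:
    """Grow a survival tree with exponential-deviance splitting."""
    if len(X) == 0:
        raise ValueError("empty training matrix")
    params = params or TreeParams()
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("need >= 1 event")
    root = _grow(X, SURVIVAL, params, time=time, event=event)
    risk = _node_deviance(float(event.sum()), float(time.sum()),
                          event.sum() / time.sum(), event, time)
    return Tree(task=SURVIVAL, root=root, features=list(X.columns), params=params,
                root_risk=float(max(risk, _EPS)))


def _node_deviance(d, t, rate, event, time) -> float:
    """Total exponential deviance of samples under a single rate."""
    ev = np.asarray(event, dtype=float)
    tm = np.asarray(time, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(ev > 0, ev * np.log(ev / (rate * tm)), 0.0)
    return float(2.0 * np.sum(term - (ev - rate * tm)))


# ---------------------------------------------------------------------------
# routing and risk
# ---------------------------------------------------------------------------

def _route(node: TreeNode, row: np.ndarray, features_idx: Mapping[str, int]) -> TreeNode:
    while not node.is_leaf:
        v = row[features_idx[node.feature]]
        if math.isnan(v):
            # surrogate-free default branch: follow the larger child
            child = node.left if node.left.n >= node.right.n else node.right
            logger.warning("missing value for %s; routed to default branch", node.feature)
            node = child
        else:
            node = node.left if v <= node.threshold else node.right
    return node


def assign_leaves(tree: Tree, X: pd.DataFrame) -> list[TreeNode]:
    fidx = {f: i for i, f in enumerate(tree.features)}
    Xv = X[tree.features].to_numpy(dtype=float)
    return [_route(tree.root, Xv[i], fidx) for i in range(len(X))]


def assign_groups(tree: Tree, X: pd.DataFrame) -> pd.Series:
    """Deterministic leaf label per sample (``node<k>``)."""
    leaves = assign_leaves(tree, X)
    return pd.Series([f"node{l.node_id}" for l in leaves], index=X.index)


# ---------------------------------------------------------------------------
# cost-complexity pruning with cross-validation
# ---------------------------------------------------------------------------

def _subtree_risk(node: TreeNode, task: str) -> float:
    """Resubstitution risk of the subtree (sum over leaves).

    For survival trees the leaf risk is -2 x exponential profile
    log-likelihood; risk *differences* between a collapsed node and its
    subtree then equal deviance differences (the saturated term cancels).
    """
    return sum(_leaf_risk(l, task) for l in node.leaves())


def _leaf_risk(leaf: TreeNode, task: str) -> float:
    if task == CLASSIFY:
        counts = leaf.class_counts
        return float(leaf.n - max(counts.values()))
    return -2.0 * _exp_loglik(leaf.events, leaf.exposure)


def _clone(node: TreeNode) -> TreeNode:
    new = TreeNode(**{k: v for k, v in node.__dict__.items() if k not in ("left", "right")})
    if not node.is_leaf:
        new.left = _clone(node.left)
        new.right = _clone(node.right)
    return new


def _weakest_link_path(tree: Tree) -> list[tuple[float, TreeNode]]:
    """Nested subtree sequence [(alpha, subtree), ...], alpha on the
    root-risk-normalized scale, ending at the root-only tree."""
    task = tree.task
    norm = tree.root_risk
    current = _clone(tree.root)
    path = [(0.0, _clone(current))]
    while not current.is_leaf:
        best_g, best_nodes = math.inf, []
        for t in current.internal():
            r_node = _leaf_risk(t, task)
            r_sub = _subtree_risk(t, task)
            n_leaves = len(t.leaves())
            g = (r_node - r_sub) / (norm * (n_leaves - 1))
            if g < best_g - 1e-12:
                best_g, best_nodes = g, [t]
            elif abs(g - best_g) <= 1e-12:
                best_nodes.append(t)
        for t in best_nodes:
            t.left = t.right = None
            t.feature = t.threshold = None
        path.append((max(best_g, 0.0), _clone(current)))
    return path


def _prune_at(root: TreeNode, task: str, alpha: float, norm: float) -> TreeNode:
    """Weakest-link prune of a (cloned) tree at complexity alpha."""
    tree = _clone(root)
    while not tree.is_leaf:
        best_g, best_nodes = math.inf, []
        for t in tree.internal():
            g = (_leaf_risk(t, task) - _subtree_risk(t, task)) / (
                norm * (len(t.leaves()) - 1)
            )
            if g < best_g - 1e-12:
                best_g, best_nodes = g, [t]
            elif abs(g - best_g) <= 1e-12:
                best_nodes.append(t)
        if best_g > alpha + 1e-12:
            break
        for t in best_nodes:
            t.left = t.right = None
            t.feature = t.threshold = None
    return tree


def _holdout_error(
    tree_root: TreeNode,
    task: str,
    features: list[str],
    X: pd.DataFrame,
    y_pos: np.ndarray | None,
    time: np.ndarray | None,
    event: np.ndarray | None,
    root_rate: float,
    positive_label: str,
) -> float:
    fidx = {f: i for i, f in enumerate(features)}
    Xv = X[features].to_numpy(dtype=float)
    err = 0.0
    for i in range(len(X)):
        leaf = _route(tree_root, Xv[i], fidx)
        if task == CLASSIFY:
            pred_pos = leaf.prediction == positive_label
            err += float(pred_pos != bool(y_pos[i]))
        else:
            # shrunken leaf rate avoids infinite deviance for event-free leaves
            lam = (leaf.events + 0.5) / (leaf.exposure + 0.5 / root_rate)
            d, t = float(event[i]), float(time[i])
            term = d * math.log(d / (lam * t)) if d > 0 and t > 0 else 0.0
            err += 2.0 * (term - (d - lam * t))
    return err


def _folds(n: int, k: int, rng: np.random.Generator, strata: np.ndarray) -> list[np.ndarray]:
    """Seeded stratified fold assignment."""
    assignment = np.empty(n, dtype=int)
    for s in np.unique(strata):
        idx = np.nonzero(strata == s)[0]
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % k
    return [np.nonzero(assignment == f)[0] for f in range(k)]


def crossval_prune(
    tree: Tree,
    X: pd.DataFrame,
    labels: Sequence[str] | None = None,
    time: Sequence[float] | None = None,
    event: Sequence[int] | None = None,
    k: int | None = None,
    seed: int = 0,
) -> tuple[Tree, PruneTrace]:
    """Cost-complexity pruning with k-fold cross-validation.

    The candidate subtrees are the weakest-link path of the fitted tree,
    restricted to complexities >= the growth cp.  Each candidate cp is scored
    by the geometric-mean rule: fold trees are re-grown on the training
    folds, pruned at sqrt(cp_i * cp_{i+1}), and evaluated on the held-out
    fold (misclassification count for classification, exponential deviance
    for survival), summed over folds and normalized by the root risk.  The
    subtree minimizing CV error is returned; ties go to the smaller tree.
    """
    params = tree.params
    k = k or params.k_folds
    n = len(X)
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} samples")
    task = tree.task
    if task == CLASSIFY:
        y_pos = np.asarray([l == params.positive_label for l in labels])
        strata = y_pos.astype(int)
        time_a = event_a = None
    else:
        time_a = np.asarray(time, dtype=float)
        event_a = np.asarray(event, dtype=int)
        y_pos = None
        strata = event_a

    path = _weakest_link_path(tree)
    # candidate subtrees: the weakest-link path, restricted to complexities
    # at or above the growth cp (plus the full tree)
    cand: list[tuple[float, TreeNode]] = []
    seen_sizes = set()
    for i, (a, sub) in enumerate(path):
        cp_i = max(a, 0.0)
        if i > 0 and cp_i < params.cp:
            continue
        size = len(sub.leaves())
        if size in seen_sizes:
            continue
        seen_sizes.add(size)
        cand.append((cp_i, sub))
    if not cand:
        cand = [path[-1]]

    rng = np.random.default_rng(seed)
    folds = _folds(n, k, rng, strata)
    root_rate = (
        event_a.sum() / time_a.sum() if task == SURVIVAL and time_a.sum() > 0 else 0.0
    )

    # geometric-mean evaluation points
    cps = [c for c, _ in cand]
    eval_points = []
    for i in range(len(cps)):
        if i + 1 < len(cps):
            lo = max(cps[i], _EPS)
            hi = max(cps[i + 1], _EPS)
            eval_points.append(math.sqrt(lo * hi))
        else:
            eval_points.append(math.inf)

    cv_err = np.zeros(len(cand))
    fold_err = np.zeros((len(cand), k))
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        X_tr = X.iloc[train_mask]
        X_te = X.iloc[test_idx]
        if task == CLASSIFY:
            if y_pos[train_mask].all() or not y_pos[train_mask].any():
                # degenerate fold; a single-leaf tree is grown regardless
                pass
            fold_tree = _grow(X_tr, CLASSIFY, params, y_pos=y_pos[train_mask])
        else:
            if event_a[train_mask].sum() == 0:
                continue
            fold_tree = _grow(
                X_tr, SURVIVAL, params, time=time_a[train_mask], event=event_a[train_mask]
            )
        for ci, beta in enumerate(eval_points):
            pruned = (
                _prune_at(fold_tree, task, beta, tree.root_risk)
                if math.isfinite(beta)
                else _prune_to_root(fold_tree)
            )
            e = _holdout_error(
                pruned, task, tree.features, X_te,
                y_pos[test_idx] if y_pos is not None else None,
                time_a[test_idx] if time_a is not None else None,
                event_a[test_idx] if event_a is not None else None,
                root_rate, params.positive_label,
            )
            fold_err[ci, f] = e
            cv_err[ci] += e

    cv_rel = cv_err / tree.root_risk
    cv_se = fold_err.std(axis=1, ddof=1) * math.sqrt(k) / tree.root_risk if k > 1 else np.zeros(len(cand))

    # min CV error; ties -> smaller tree (later in path)
    best_i = 0
    for i in range(len(cand)):
        if cv_rel[i] < cv_rel[best_i] - 1e-12 or (
            abs(cv_rel[i] - cv_rel[best_i]) <= 1e-12
            and len(cand[i][1].leaves()) < len(cand[best_i][1].leaves())
        ):
            best_i = i

    rows = []
    for i, (cp_i, sub) in enumerate(cand):
        if task == CLASSIFY:
            resub = _subtree_risk(sub, task) / tree.root_risk
        else:
            # deviance relative to the root model (1.0 at the root tree)
            gain = _leaf_risk(sub, task) - _subtree_risk(sub, task)
            resub = (tree.root_risk - gain) / tree.root_risk
        rows.append(
            {
                "cp": cp_i,
                "size": len(sub.leaves()),
                "resub_error": resub,
                "cv_error": float(cv_rel[i]),
                "cv_se": float(cv_se[i]),
            }
        )
    trace = PruneTrace(rows=rows, chosen_cp=cand[best_i][0])
    pruned_tree = Tree(
        task=task, root=_clone(cand[best_i][1]), features=tree.features,
        params=params, root_risk=tree.root_risk,
    )
    return pruned_tree, trace


def _prune_to_root(root: TreeNode) -> TreeNode:
    node = _clone(root)
    node.left = node.right = None
    node.feature = node.threshold = None
    return node


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_classifier(
    tree: Tree, X_test: pd.DataFrame, labels_test: Sequence[str]
) -> ClassifierMetrics:
    """Accuracy / precision / recall with the positive class as positive, and
    AUC computed as the rank (Mann-Whitney) statistic of the leaf
    positive-class probabilities, ties mid-ranked.  A single-class test set
    leaves the AUC undefined (NaN)."""
    pos_label = tree.params.positive_label
    leaves = assign_leaves(tree, X_test)
    y = np.asarray([l == pos_label for l in labels_test])
    pred = np.asarray([l.prediction == pos_label for l in leaves])
    scores = np.asarray([l.prob_positive for l in leaves], dtype=float)

    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    accuracy = (tp + tn) / len(y)
    precision = tp / (tp + fp) if (tp + fp) else math.nan
    recall = tp / (tp + fn) if (tp + fn) else math.nan

    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        auc = math.nan
    else:
        from scipy.stats import rankdata

        ranks = rankdata(scores)
        auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return ClassifierMetrics(
        accuracy=accuracy, precision=precision, recall=recall, auc=float(auc),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def compare_groups(
    labels: pd.Series,
    time: Sequence[float],
    event: Sequence[int],
    use_cox: bool = False,
) -> dict:
    """Survival comparison of tree-assigned groups.

    Returns per-group KM medians, event counts and rate ratios vs the pooled
    data, plus the Bonferroni-adjusted pairwise log-rank table.  With
    ``use_cox`` each pair additionally carries a Cox HR (group_b vs group_a)
    and its 95% CI.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    lab = np.asarray(labels)
    overall_rate = event.sum() / time.sum() if time.sum() > 0 else math.nan
    groups: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    summary = []
    for g in sorted(pd.unique(lab)):
        m = lab == g
        groups[g] = (time[m], event[m])
        km = km_estimate(time[m], event[m])
        rate = event[m].sum() / time[m].sum() if time[m].sum() > 0 else math.nan
        summary.append(
            {
                "group": g, "n": int(m.sum()), "events": int(event[m].sum()),
                "median_survival": km.median,
                "rate_ratio": rate / overall_rate if overall_rate else math.nan,
            }
        )
    pairwise = pairwise_logrank(groups) if len(groups) > 1 else pd.DataFrame(
        columns=["group_a", "group_b", "chi2", "raw_p", "adjusted_p"]
    )
    if use_cox and len(groups) > 1:
        hrs, lows, highs = [], [], []
        for row in pairwise.itertuples(index=False):
            m = (lab == row.group_a) | (lab == row.group_b)
            ind = (lab[m] == row.group_b).astype(float)
            try:
                res = cox_univariate(ind, time[m], event[m], name="group")
                hrs.append(res.hr)
                lows.append(res.ci_low)
                highs.append(res.ci_high)
            except ValueError:
                hrs.append(math.nan)
                lows.append(math.nan)
                highs.append(math.nan)
        pairwise = pairwise.assign(hr=hrs, hr_ci_low=lows, hr_ci_high=highs)
    return {"groups": pd.DataFrame(summary), "pairwise": pairwise}
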