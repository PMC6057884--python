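"""Depth-limited regression trees on binned features, with surrogate splits.

Features are pre-binned (at most 64 bins per feature, quantile cuts for dense
numeric columns, category codes for categoricals); split search then reduces
to histogram scans that are vectorized across all features at once. Missing
values occupy a reserved bin and never enter the split criterion; at
prediction time they are routed by the best surrogate split (the feature /
threshold whose binary partition agrees most with the primary split on the
node's complete cases), falling back to the majority direction.

Split criterion: greedy variance reduction on the residuals. Leaf values are
either the leaf mean residual or, when per-sample curvatures are supplied, a
one-step Newton update sum(r) / sum(h) for the Cox loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_BINS = 64
MISS = MAX_BINS          # reserved bin code for missing values
_STRIDE = MAX_BINS + 1


# ----------------------------------------------------------------------
class Binner:
    """Per-feature discretization shared by all trees of an ensemble."""

    def __init__(self, max_bins: int = MAX_BINS):
        self.max_bins = max_bins
        self.kinds: list[str] = []          # "num" | "cat"
        self.cuts: list[np.ndarray | None] = []    # numeric: ascending cut points
        self.categories: list[pd.Index | None] = []
        self.n_bins: np.ndarray | None = None
        self.columns: list[str] = []

    def fit(self, X: pd.DataFrame) -> "Binner":
        self.columns = list(X.columns)
        nb = []
        for col in X.columns:
            s = X[col]
            if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
                cats = s.astype("category").cat.categories
                if len(cats) > self.max_bins:
                    raise ValueError(f"categorical column {col!r} has too many levels")
                self.kinds.append("cat")
                self.cuts.append(None)
                self.categories.append(cats)
                nb.append(max(len(cats), 1))
            else:
                v = s.to_numpy(dtype=float)
                v = v[~np.isnan(v)]
                uniq = np.unique(v)
                if len(uniq) <= 1:
                    cuts = np.empty(0)
                elif len(uniq) <= self.max_bins:
                    cuts = (uniq[:-1] + uniq[1:]) / 2.0
                else:
                    qs = np.quantile(v, np.linspace(0, 1, self.max_bins + 1)[1:-1])
                    cuts = np.unique(qs)
                self.kinds.append("num")
                self.cuts.append(cuts)
                self.categories.append(None)
                nb.append(len(cuts) + 1)
        self.n_bins = np.asarray(nb, dtype=int)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """uint8 code matrix; code MISS marks missing values."""
        missing = [c for c in self.columns if c not in X.columns]
        if missing:
            raise KeyError(f"feature schema mismatch; missing columns {missing}")
        n = len(X)
        C = np.empty((n, len(self.columns)), dtype=np.uint8)
        for j, col in enumerate(self.columns):
            s = X[col]
            if self.kinds[j] == "cat":
                codes = s.astype(pd.CategoricalDtype(self.categories[j])).cat.codes.to_numpy()
                out = np.where(codes < 0, MISS, codes)
            else:
                v = s.to_numpy(dtype=float)
                out = np.searchsorted(self.cuts[j], v, side="left")
                out = np.where(np.isnan(v), MISS, out)
            C[:, j] = out.astype(np.uint8)
        return C


# ----------------------------------------------------------------------
@dataclass
class Node:
    feature: int = -1                 # -1 marks a leaf
    code_threshold: int = -1          # numeric split: code <= threshold -> left
    left_cats: np.ndarray | None = None   # categorical split: bool mask over bins
    surrogate: tuple[int, int, bool] | None = None  # (feature, code_thr, swap)
    missing_left: bool = True         # majority-direction fallback
    left: int = -1
    right: int = -1
    value: float = 0.0
    gain: float = 0.0
    n: int = 0


@dataclass
class RegressionTree:
    nodes: list[Node] = field(default_factory=list)

    @property
    def depth(self) -> int:
        def d(i: int) -> int:
            nd = self.nodes[i]
            if nd.feature < 0:
                return 0
            return 1 + max(d(nd.left), d(nd.right))
        return d(0) if self.nodes else 0

    def predict_codes(self, C: np.ndarray) -> np.ndarray:
        """Leaf values for a pre-binned code matrix."""
        n = C.shape[0]
        out = np.empty(n)
        idx = np.arange(n)
        stack = [(0, idx)]
        while stack:
            ni, rows = stack.pop()
            nd = self.nodes[ni]
            if nd.feature < 0:
                out[rows] = nd.value
                continue
            codes = C[rows, nd.feature]
            miss = codes == MISS
            if nd.left_cats is not None:
                go_left = np.where(miss, False, nd.left_cats[np.minimum(codes, MAX_BINS - 1)])
            else:
                go_left = (codes <= nd.code_threshold) & ~miss
            if miss.any():
                route = np.full(miss.sum(), nd.missing_left)
                if nd.surrogate is not None:
                    sf, sthr, swap = nd.surrogate
                    scodes = C[rows[miss], sf]
                    sobs = scodes != MISS
                    sleft = (scodes <= sthr) != swap
                    route = np.where(sobs, sleft, nd.missing_left)
                go_left = go_left.copy()
                go_left[miss] = route
            stack.append((nd.left, rows[go_left]))
            stack.append((nd.right, rows[~go_left]))
        return out

    def leaf_rows(self, C: np.ndarray) -> np.ndarray:
        """Leaf index per row (same routing as predict_codes)."""
        n = C.shape[0]
        out = np.empty(n, dtype=int)
        stack = [(0, np.arange(n))]
        while stack:
            ni, rows = stack.pop()
            nd = self.nodes[ni]
            if nd.feature < 0:
                out[rows] = ni
                continue
            codes = C[rows, nd.feature]
            miss = codes == MISS
            if nd.left_cats is not None:
                go_left = np.where(miss, False, nd.left_cats[np.minimum(codes, MAX_BINS - 1)])
            else:
                go_left = (codes <= nd.code_threshold) & ~miss
            if miss.any():
                route = np.full(miss.sum(), nd.missing_left)
                if nd.surrogate is not None:
                    sf, sthr, swap = nd.surrogate
                    scodes = C[rows[miss], sf]
                    sobs = scodes != MISS
                    sleft = (scodes <= sthr) != swap
                    route = np.where(sobs, sleft, nd.missing_left)
                go_left = go_left.copy()
                go_left[miss] = route
            stack.append((nd.left, rows[go_left]))
            stack.append((nd.right, rows[~go_left]))
        return out


# ----------------------------------------------------------------------
def _node_histograms(C_rows: np.ndarray, w: np.ndarray, p: int):
    """Per (feature, bin) residual sums and counts for the rows of one node."""
    flat = C_rows.astype(np.int64) + np.arange(p, dtype=np.int64) * _STRIDE
    flat = flat.ravel()
    wr = np.broadcast_to(w[:, None], C_rows.shape).ravel()
    sum_r = np.bincount(flat, weights=wr, minlength=p * _STRIDE).reshape(p, _STRIDE)
    cnt = np.bincount(flat, minlength=p * _STRIDE).reshape(p, _STRIDE)
    return sum_r, cnt


def _best_split(
    sum_r: np.ndarray,
    cnt: np.ndarray,
    n_bins: np.ndarray,
    is_cat: np.ndarray,
    min_leaf: int,
    rng: np.random.Generator | None = None,
):
    """Best variance-reduction split across all features.

    Returns (gain, feature, cut_pos, order) where order is the bin ordering
    used (categorical features scan bins sorted by mean residual). Exact ties
    between features (e.g. duplicated columns) are broken uniformly at random
    when an ``rng`` is supplied, deterministically by feature index otherwise.
    """
    p = sum_r.shape[0]
    R = sum_r[:, :MAX_BINS].copy()
    N = cnt[:, :MAX_BINS].astype(float).copy()
    orders = {}
    if is_cat.any():
        for f in np.where(is_cat)[0]:
            nb = n_bins[f]
            means = np.where(N[f, :nb] > 0, R[f, :nb] / np.maximum(N[f, :nb], 1), np.inf)
            order = np.argsort(means, kind="stable")
            orders[f] = order
            R[f, :nb] = R[f, order]
            N[f, :nb] = N[f, order]
    cumR = np.cumsum(R, axis=1)
    cumN = np.cumsum(N, axis=1)
    totR = cumR[:, -1][:, None]
    totN = cumN[:, -1][:, None]
    remR = totR - cumR
    remN = totN - cumN
    with np.errstate(divide="ignore", invalid="ignore"):
        gains = (
            cumR**2 / np.maximum(cumN, 1e-300)
            + remR**2 / np.maximum(remN, 1e-300)
            - totR**2 / np.maximum(totN, 1e-300)
        )
    valid = (cumN >= min_leaf) & (remN >= min_leaf)
    # a cut after the last bin of each feature is meaningless
    pos = np.arange(MAX_BINS)[None, :]
    valid &= pos < (n_bins[:, None] - 1)
    gains = np.where(valid, gains, -np.inf)
    per_feature = gains.max(axis=1)
    best = per_feature.max()
    if not np.isfinite(best):
        return -np.inf, -1, -1, None
    tol = 1e-9 * max(1.0, abs(best))
    candidates = np.where(per_feature >= best - tol)[0]
    if rng is not None and len(candidates) > 1:
        f = int(candidates[rng.integers(len(candidates))])
    else:
        f = int(candidates[0])
    b = int(np.argmax(gains[f]))
    return float(gains[f, b]), f, b, orders.get(f)


def _best_surrogate(
    C_rows: np.ndarray,
    primary_left: np.ndarray,
    primary_obs: np.ndarray,
    feature: int,
    n_bins: np.ndarray,
    p: int,
):
    """Surrogate split (feature, code threshold, swap) maximizing routing
    agreement with the primary split on rows observed in both; None when no
    candidate beats the majority-direction baseline."""
    obs_rows = C_rows[primary_obs]
    left = primary_left[primary_obs].astype(float)
    if obs_rows.shape[0] == 0:
        return None, True
    sum_l, cnt = _node_histograms(obs_rows, left, p)
    # exclude the missing bin of each candidate from totals
    L = sum_l[:, :MAX_BINS]
    Ncnt = cnt[:, :MAX_BINS].astype(float)
    cumL = np.cumsum(L, axis=1)
    cumN = np.cumsum(Ncnt, axis=1)
    totL = cumL[:, -1][:, None]
    totN = cumN[:, -1][:, None]
    agree = cumL + (totN - cumN) - (totL - cumL)        # left-left + right-right
    agree_swap = totN - agree
    best = np.maximum(agree, agree_swap)
    pos = np.arange(MAX_BINS)[None, :]
    # compare agreement *rates*: a candidate is only judged on the rows where
    # it is itself observed, which may be far fewer than the node's rows
    valid = (pos < (n_bins[:, None] - 1)) & (totN >= 2)
    rate = np.where(valid, best / np.maximum(totN, 1), -np.inf)
    rate[feature, :] = -np.inf
    n_left = left.sum()
    majority_left = bool(n_left >= len(left) - n_left)
    baseline_rate = max(n_left, len(left) - n_left) / max(len(left), 1)
    f, b = np.unravel_index(np.argmax(rate), rate.shape)
    if rate[f, b] <= baseline_rate:
        return None, majority_left
    swap = bool(agree_swap[f, b] > agree[f, b])
    return (int(f), int(b), swap), majority_left


def grow_tree(
    C: np.ndarray,
    residuals: np.ndarray,
    binner: Binner,
    rows: np.ndarray | None = None,
    hessian: np.ndarray | None = None,
    max_depth: int = 3,
    min_leaf: int = 10,
    rng: np.random.Generator | None = None,
) -> RegressionTree:
    """Grow a depth-limited tree on pre-binned codes (see module docstring)."""
    r = np.asarray(residuals, dtype=float)
    n, p = C.shape
    if rows is None:
        rows = np.arange(n)
    is_cat = np.array([k == "cat" for k in binner.kinds])
    n_bins = binner.n_bins
    tree = RegressionTree()

    def leaf_value(rr: np.ndarray) -> float:
        if len(rr) == 0:
            return 0.0
        if hessian is None:
            return float(r[rr].mean())
        denom = hessian[rr].sum()
        if denom < 1e-12:
            return 0.0
        return float(r[rr].sum() / denom)

    def build(rr: np.ndarray, depth: int) -> int:
        ni = len(tree.nodes)
        tree.nodes.append(Node(n=len(rr)))
        node = tree.nodes[ni]
        if depth >= max_depth or len(rr) < 2 * min_leaf or np.ptp(r[rr]) == 0:
            node.value = leaf_value(rr)
            return ni
        sum_r, cnt = _node_histograms(C[rr], r[rr], p)
        gain, f, b, order = _best_split(sum_r, cnt, n_bins, is_cat, min_leaf, rng=rng)
        if not np.isfinite(gain) or gain <= 1e-12:
            node.value = leaf_value(rr)
            return ni
        codes = C[rr, f]
        miss = codes == MISS
        if order is not None:  # categorical: left set = first b+1 bins in residual order
            left_cats = np.zeros(MAX_BINS, dtype=bool)
            left_cats[order[: b + 1]] = True
            go_left = np.where(miss, False, left_cats[np.minimum(codes, MAX_BINS - 1)])
            node.left_cats = left_cats
        else:
            go_left = (codes <= b) & ~miss
            node.code_threshold = b
        node.feature = f
        node.gain = gain
        if miss.any():
            node.surrogate, node.missing_left = _best_surrogate(
                C[rr], go_left, ~miss, f, n_bins, p
            )
            route = np.full(miss.sum(), node.missing_left)
            if node.surrogate is not None:
                sf, sthr, swap = node.surrogate
                scodes = C[rr[miss], sf]
                sobs = scodes != MISS
                sleft = (scodes <= sthr) != swap
                route = np.where(sobs, sleft, node.missing_left)
            go_left = go_left.copy()
            go_left[miss] = route
        left_rows = rr[go_left]
        right_rows = rr[~go_left]
        if len(left_rows) == 0 or len(right_rows) == 0:
            node.feature = -1
            node.value = leaf_value(rr)
            return ni
        node.left = build(left_rows, depth + 1)
        node.right = build(right_rows, depth + 1)
        return ni

    build(np.asarray(rows), 0)
    return tree


def fit_regression_tree(
    X: pd.DataFrame,
    residuals: np.ndarray,
    max_depth: int = 3,
    min_leaf: int = 10,
    hessian: np.ndarray | None = None,
) -> tuple[RegressionTree, Binner]:
    """Fit a single tree to residuals (standalone interface).

    Without ``hessian`` leaves carry the mean residual; with it, the one-step
    Newton update used inside the Cox boosting loop. All-constant residuals
    yield a single-leaf tree.
    """
    binner = Binner().fit(X)
    C = binner.transform(X)
    tree = grow_tree(
        C, residuals, binner, hessian=hessian, max_depth=max_depth, min_leaf=min_leaf
    )
    return tree, binner
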