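"""Cox-loss gradient boosting with inner-CV selection of the step count.

Each boosting step fits a depth-limited regression tree to the current
working residuals of the Breslow partial log-likelihood (optionally on a
bagged row subsample) and adds shrinkage-scaled one-step-Newton leaf values
to the log-hazard score. The number of boosting steps is the minimizer of the
mean inner cross-validated negative partial log-likelihood; per-feature
importance accumulates the split variance reductions (relative influence,
normalized to sum 100).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .loss import cox_hessian_diag, cox_negative_gradient, cox_partial_loglik
from .tree import MISS, Binner, Node, RegressionTree, grow_tree

log = logging.getLogger(__name__)


@dataclass
class BoostedCoxEnsemble:
    binner: Binner
    trees: list[RegressionTree] = field(default_factory=list)
    nu: float = 0.05
    n_trees: int = 0
    importance_ledger: dict[str, float] = field(default_factory=dict)
    training_log: pd.DataFrame | None = None
    cv_curve: np.ndarray | None = None

    @property
    def feature_names(self) -> list[str]:
        return self.binner.columns

    # ---------------------------------------------------------------- predict
    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Additive log-hazard score over the selected trees."""
        C = self.binner.transform(X)
        scores = np.zeros(len(X))
        for tree in self.trees[: self.n_trees]:
            scores += self.nu * tree.predict_codes(C)
        return scores

    def importance(self, normalize: bool = True) -> dict[str, float]:
        imp = {c: self.importance_ledger.get(c, 0.0) for c in self.feature_names}
        if normalize:
            total = sum(imp.values())
            if total > 0:
                imp = {c: 100.0 * v / total for c, v in imp.items()}
        return imp

    # ---------------------------------------------------------------- I/O
    def to_json(self, path) -> None:
        def node_dict(nd: Node) -> dict:
            return {
                "feature": nd.feature,
                "code_threshold": nd.code_threshold,
                "left_cats": None if nd.left_cats is None else nd.left_cats.astype(int).tolist(),
                "surrogate": list(nd.surrogate) if nd.surrogate else None,
                "missing_left": bool(nd.missing_left),
                "left": nd.left,
                "right": nd.right,
                "value": nd.value,
                "gain": nd.gain,
                "n": nd.n,
            }
        payload = {
            "nu": self.nu,
            "n_trees": self.n_trees,
            "importance": self.importance_ledger,
            "binner": {
                "columns": self.binner.columns,
                "kinds": self.binner.kinds,
                "cuts": [None if c is None else list(map(float, c)) for c in self.binner.cuts],
                "categories": [None if c is None else list(map(str, c)) for c in self.binner.categories],
                "n_bins": self.binner.n_bins.tolist(),
            },
            "trees": [[node_dict(nd) for nd in t.nodes] for t in self.trees[: self.n_trees]],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "BoostedCoxEnsemble":
        with open(path) as fh:
            payload = json.load(fh)
        b = Binner()
        b.columns = payload["binner"]["columns"]
        b.kinds = payload["binner"]["kinds"]
        b.cuts = [None if c is None else np.asarray(c) for c in payload["binner"]["cuts"]]
        b.categories = [None if c is None else pd.Index(c) for c in payload["binner"]["categories"]]
        b.n_bins = np.asarray(payload["binner"]["n_bins"])
        trees = []
        for tnodes in payload["trees"]:
            t = RegressionTree()
            for nd in tnodes:
                t.nodes.append(
                    Node(
                        feature=nd["feature"],
                        code_threshold=nd["code_threshold"],
                        left_cats=None if nd["left_cats"] is None else np.asarray(nd["left_cats"], dtype=bool),
                        surrogate=None if nd["surrogate"] is None else tuple(nd["surrogate"]),
                        missing_left=nd["missing_left"],
                        left=nd["left"],
                        right=nd["right"],
                        value=nd["value"],
                        gain=nd["gain"],
                        n=nd["n"],
                    )
                )
            trees.append(t)
        ens = cls(binner=b, trees=trees, nu=payload["nu"], n_trees=payload["n_trees"])
        ens.importance_ledger = dict(payload["importance"])
        return ens


# ----------------------------------------------------------------------
def _boost(
    C: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    binner: Binner,
    nu: float,
    n_steps: int,
    bag_fraction: float,
    max_depth: int,
    min_leaf: int,
    rng: np.random.Generator,
    C_valid: np.ndarray | None = None,
    t_valid: np.ndarray | None = None,
    d_valid: np.ndarray | None = None,
):
    """Core boosting loop; returns trees, per-step train loss, per-step
    validation loss (when a validation set is given) and the importance ledger."""
    n = C.shape[0]
    f = np.zeros(n)
    f_val = np.zeros(C_valid.shape[0]) if C_valid is not None else None
    trees: list[RegressionTree] = []
    train_loss = np.empty(n_steps)
    val_loss = np.empty(n_steps) if C_valid is not None else None
    ledger: dict[int, float] = {}
    for m in range(n_steps):
        r = cox_negative_gradient(f, times, events)
        h = cox_hessian_diag(f, times, events)
        if bag_fraction < 1.0:
            k = max(int(round(bag_fraction * n)), 2 * min_leaf)
            rows = rng.choice(n, size=min(k, n), replace=False)
            rows.sort()
        else:
            rows = np.arange(n)
        tree = grow_tree(
            C, r, binner, rows=rows, hessian=h, max_depth=max_depth,
            min_leaf=min_leaf, rng=rng,
        )
        # leaf values were fitted on the bag; apply to all rows
        f += nu * tree.predict_codes(C)
        for nd in tree.nodes:
            if nd.feature >= 0:
                ledger[nd.feature] = ledger.get(nd.feature, 0.0) + nd.gain
        trees.append(tree)
        train_loss[m] = -cox_partial_loglik(f, times, events)
        if C_valid is not None:
            f_val += nu * tree.predict_codes(C_valid)
            val_loss[m] = -cox_partial_loglik(f_val, t_valid, d_valid)
    return trees, train_loss, val_loss, ledger


def fit_gbm(
    X: pd.DataFrame,
    times,
    events,
    nu: float = 0.05,
    n_max: int = 2000,
    bag_fraction: float = 0.5,
    inner_folds: int = 10,
    max_depth: int = 3,
    min_leaf: int = 10,
    seed: int = 0,
) -> BoostedCoxEnsemble:
    """Fit a boosted Cox ensemble; the step count minimizes inner-CV loss.

    Inner folds are stratified by event status (each needs >= 2 events). When
    the CV minimum sits at ``n_max`` (no interior minimum), a warning is
    issued and ``n_max`` steps are kept. ``inner_folds <= 1`` skips selection
    and keeps ``n_max`` steps. Training is deterministic given ``seed``.
    """
    from ..evaluation.cv import stratified_folds  # local import to avoid a cycle

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    binner = Binner().fit(X)
    C = binner.transform(X)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 211]))

    cv_curve = None
    n_trees = n_max
    if inner_folds > 1:
        if events.sum() < 2 * inner_folds:
            raise ValueError("need at least 2 events per inner fold")
        folds = stratified_folds(events, inner_folds, rng)
        losses = np.zeros((inner_folds, n_max))
        for fidx in range(inner_folds):
            va = folds == fidx
            tr = ~va
            fold_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 37, fidx]))
            _, _, vl, _ = _boost(
                C[tr], times[tr], events[tr], binner, nu, n_max,
                bag_fraction, max_depth, min_leaf, fold_rng,
                C_valid=C[va], t_valid=times[va], d_valid=events[va],
            )
            losses[fidx] = vl
        cv_curve = losses.mean(axis=0)
        n_trees = int(np.argmin(cv_curve)) + 1
        if n_trees == n_max:
            warnings.warn("inner-CV loss still decreasing at n_max; keeping n_max trees")

    final_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 59]))
    trees, train_loss, _, ledger = _boost(
        C, times, events, binner, nu, n_trees,
        bag_fraction, max_depth, min_leaf, final_rng,
    )
    ens = BoostedCoxEnsemble(binner=binner, trees=trees, nu=nu, n_trees=n_trees)
    ens.importance_ledger = {
        binner.columns[f]: g for f, g in sorted(ledger.items())
    }
    ens.cv_curve = cv_curve
    ens.training_log = pd.DataFrame(
        {
            "step": np.arange(1, n_trees + 1),
            "train_loss": train_loss,
            "cv_loss": cv_curve[:n_trees] if cv_curve is not None else np.nan,
        }
    )
    return ens


def predict_risk(ensemble: BoostedCoxEnsemble, X: pd.DataFrame) -> np.ndarray:
    """Per-patient log-hazard score (additive over trees; empty ensemble -> 0)."""
    return ensemble.predict(X)


def variable_importance(
    ensemble: BoostedCoxEnsemble, normalize: bool = True
) -> dict[str, float]:
    """Relative influence: cumulative loss reduction per feature, summing to 100."""
    return ensemble.importance(normalize=normalize)
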