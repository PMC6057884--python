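"""Cross-validated comparison of structure-learning algorithms.

Each learner is fitted on k-1 folds (structure plus CPTs estimated by
maximum likelihood with add-one smoothing, so unseen test configurations
keep finite probability) and scored by the mean per-record log-likelihood of
the held-out fold. Learners are ranked by descending mean held-out
log-likelihood (equivalently ascending negated expected log-likelihood).
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
import networkx as nx

from .discretize import DiscreteDataset


Learner = Callable[[DiscreteDataset, int], nx.DiGraph]


def _fit_cpts(
    dag: nx.DiGraph, data: DiscreteDataset, alpha: float = 1.0
) -> dict[str, np.ndarray]:
    card = data.cardinalities()
    cpts = {}
    for v in data.data.columns:
        parents = sorted(dag.predecessors(v))
        r = card[v]
        q = int(np.prod([card[p] for p in parents])) if parents else 1
        idx = np.zeros(len(data.data), dtype=np.int64)
        for p in parents:
            idx = idx * card[p] + data.data[p].to_numpy()
        joint = idx * r + data.data[v].to_numpy()
        counts = np.bincount(joint, minlength=q * r).reshape(q, r).astype(float)
        counts += alpha
        cpts[v] = counts / counts.sum(axis=1, keepdims=True)
    return cpts


def _loglik(
    dag: nx.DiGraph, cpts: dict[str, np.ndarray], data: DiscreteDataset
) -> float:
    """Mean per-record log-likelihood of ``data`` under the fitted BN."""
    card = data.cardinalities()
    total = np.zeros(len(data.data))
    for v in data.data.columns:
        parents = sorted(dag.predecessors(v))
        idx = np.zeros(len(data.data), dtype=np.int64)
        for p in parents:
            idx = idx * card[p] + data.data[p].to_numpy()
        total += np.log(cpts[v][idx, data.data[v].to_numpy()])
    return float(total.mean())


def cv_select_learner(
    data: DiscreteDataset,
    learners: dict[str, Learner],
    k: int = 10,
    seed: int = 0,
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Rank learners by k-fold held-out log-likelihood (descending).

    ``learners`` maps name -> callable(data, seed) -> DAG. Returns a frame
    (learner, mean_loglik, sd_loglik) sorted best-first; ties keep input
    order. ``k`` may equal n (leave-one-out).
    """
    n = len(data.data)
    if k > n:
        raise ValueError("k cannot exceed the number of records")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 613]))
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[perm] = np.arange(n) % k
    rows = []
    for name, learner in learners.items():
        scores = []
        for f in range(k):
            tr = folds != f
            te = folds == f
            train = DiscreteDataset(
                data.data.loc[tr], data.levels, data.roles, data.bin_edges
            )
            test = DiscreteDataset(
                data.data.loc[te], data.levels, data.roles, data.bin_edges
            )
            dag = learner(train, int(seed) + f)
            cpts = _fit_cpts(dag, train, alpha=alpha)
            scores.append(_loglik(dag, cpts, test))
        rows.append((name, float(np.mean(scores)), float(np.std(scores))))
    df = pd.DataFrame(rows, columns=["learner", "mean_loglik", "sd_loglik"])
    return df.sort_values("mean_loglik", ascending=False, kind="stable").reset_index(drop=True)
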