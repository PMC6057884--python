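"""Decomposable BIC scoring of discrete Bayesian networks.

score(G) = sum over nodes v of family_score(v, pa(v)) with

    family_score = loglik(v | pa(v)) - (penalty / 2) * log N * (r_v - 1) * q_v

where r_v is the cardinality of v, q_v the number of parent configurations,
and the log-likelihood is the multinomial MLE plug-in (zero counts contribute
zero). Higher is better.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .discretize import DiscreteDataset


class ScoreCache:
    """Memoized family scores over one dataset (column codes pre-extracted)."""

    def __init__(self, dataset: DiscreteDataset, penalty: float = 1.0):
        self.columns = list(dataset.data.columns)
        self.codes = {c: dataset.data[c].to_numpy(dtype=np.int64) for c in self.columns}
        self.card = dataset.cardinalities()
        self.n = len(dataset.data)
        self.penalty = penalty
        self._memo: dict[tuple[str, tuple[str, ...]], float] = {}

    def family(self, child: str, parents: tuple[str, ...]) -> float:
        key = (child, tuple(sorted(parents)))
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        r = self.card[child]
        q = 1
        idx = np.zeros(self.n, dtype=np.int64)
        for p_name in key[1]:
            idx = idx * self.card[p_name] + self.codes[p_name]
            q *= self.card[p_name]
        joint = idx * r + self.codes[child]
        counts = np.bincount(joint, minlength=q * r).reshape(q, r)
        row_tot = np.broadcast_to(counts.sum(axis=1, keepdims=True), counts.shape)
        pos = counts > 0
        ll = float(
            (counts[pos] * (np.log(counts[pos]) - np.log(row_tot[pos]))).sum()
        )
        pen = 0.5 * self.penalty * np.log(self.n) * (r - 1) * q
        val = ll - pen
        self._memo[key] = val
        return val


def family_score(
    dataset: DiscreteDataset, child: str, parents, penalty: float = 1.0
) -> float:
    """BIC family score for one (child, parents) pair."""
    return ScoreCache(dataset, penalty=penalty).family(child, tuple(parents))


def bic_score(dag: nx.DiGraph, dataset: DiscreteDataset, penalty: float = 1.0) -> float:
    """Total BIC of a DAG over the dataset (decomposable; higher is better)."""
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("graph must be acyclic")
    cache = ScoreCache(dataset, penalty=penalty)
    return sum(
        cache.family(v, tuple(dag.predecessors(v))) for v in dataset.data.columns
    )
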