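"""Discrete Bayesian-network ground truth: random DAGs, CPTs and ancestral sampling.

A discrete BN over graph G factorizes as p(x) = prod_v p(x_v | x_pa(v));
``sample_discrete_bn`` draws rows by ancestral sampling in topological order,
so empirical conditional frequencies converge to the CPT entries as n grows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

_TOL = 1e-9


def random_dag(
    n_nodes: int,
    max_in_degree: int = 2,
    edge_prob: float = 0.35,
    seed: int | np.random.Generator = 0,
    node_names: list[str] | None = None,
) -> nx.DiGraph:
    """Random DAG over a random topological order with bounded in-degree."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = node_names or [f"V{i}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for pos, j in enumerate(order):
        earlier = order[:pos].copy()
        rng.shuffle(earlier)
        n_par = 0
        for i in earlier:
            if n_par >= max_in_degree:
                break
            if rng.random() < edge_prob:
                g.add_edge(names[i], names[j])
                n_par += 1
    return g


def random_cpts(
    dag: nx.DiGraph,
    n_levels: int = 3,
    strength: float = 0.85,
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Strong CPTs: each parent configuration concentrates mass ``strength``
    on one (configuration-dependent) level, the rest spread uniformly."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cpts: dict[str, np.ndarray] = {}
    for v in dag.nodes:
        q = n_levels ** len(list(dag.predecessors(v)))
        table = np.full((q, n_levels), (1.0 - strength) / (n_levels - 1))
        peaks = rng.integers(0, n_levels, size=q)
        table[np.arange(q), peaks] = strength
        cpts[v] = table
    return cpts


def sample_discrete_bn(
    dag: nx.DiGraph,
    cpts: dict[str, np.ndarray],
    n: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Ancestral sampling of ``n`` rows from a discrete BN.

    ``cpts[v]`` has shape (prod of parent cardinalities, n_levels_v); parent
    configurations are indexed with the first parent (sorted order) as the
    most significant digit. Every CPT row must sum to 1 within 1e-9.
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("graph must be acyclic")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    levels = {v: cpts[v].shape[1] for v in dag.nodes}
    for v, t in cpts.items():
        if np.abs(t.sum(axis=1) - 1.0).max() > _TOL:
            raise ValueError(f"CPT rows of {v!r} do not sum to 1")
    data: dict[str, np.ndarray] = {}
    for v in nx.topological_sort(dag):
        parents = sorted(dag.predecessors(v))
        t = cpts[v]
        if parents:
            idx = np.zeros(n, dtype=int)
            for p_name in parents:
                idx = idx * levels[p_name] + data[p_name]
        else:
            idx = np.zeros(n, dtype=int)
        probs = t[idx]                     # (n, n_levels)
        u = rng.random(n)
        data[v] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    cols = list(dag.nodes)
    return pd.DataFrame({c: data[c] for c in cols})
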