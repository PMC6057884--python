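"""Bootstrap edge confidence and the stable-edge subgraph.

Patient records are resampled with replacement B times; a structure is
learned on each replicate and the relative frequency of every directed edge
recorded. Edges appearing in strictly more than the threshold fraction of
reconstructions form the stable subgraph (frequencies attached as edge
labels). Undirected (either-orientation) frequencies are reported as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .discretize import DiscreteDataset
from .select import Learner


@dataclass
class EdgeConfidenceGraph:
    frequencies: dict[tuple[str, str], float]      # directed edge -> frequency
    undirected: dict[frozenset, float] = field(default_factory=dict)
    n_bootstrap: int = 0
    nodes: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tfrequency\n")
            for (u, v), f in sorted(self.frequencies.items(), key=lambda kv: -kv[1]):
                fh.write(f"{u}\t{v}\t{f:.6g}\n")


def bootstrap_edge_confidence(
    data: DiscreteDataset,
    learner: Learner,
    B: int = 1000,
    seed: int = 0,
) -> EdgeConfidenceGraph:
    """Relative frequency of each directed edge over ``B`` bootstrap structures."""
    n = len(data.data)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 811]))
    dir_counts: dict[tuple[str, str], int] = {}
    und_counts: dict[frozenset, int] = {}
    for b in range(B):
        rows = rng.integers(0, n, size=n)
        boot = DiscreteDataset(
            data.data.iloc[rows].reset_index(drop=True),
            data.levels,
            data.roles,
            data.bin_edges,
        )
        dag = learner(boot, int(rng.integers(2**31)))
        for e in dag.edges:
            dir_counts[e] = dir_counts.get(e, 0) + 1
            key = frozenset(e)
            und_counts[key] = und_counts.get(key, 0) + 1
    return EdgeConfidenceGraph(
        frequencies={e: c / B for e, c in dir_counts.items()},
        undirected={k: c / B for k, c in und_counts.items()},
        n_bootstrap=B,
        nodes=list(data.data.columns),
    )


def stable_edges(
    conf_graph: EdgeConfidenceGraph, threshold: float = 0.5
) -> nx.DiGraph:
    """Directed graph of edges with frequency strictly above ``threshold``."""
    g = nx.DiGraph()
    g.add_nodes_from(conf_graph.nodes)
    for (u, v), f in conf_graph.frequencies.items():
        if f > threshold:
            g.add_edge(u, v, frequency=f)
    return g
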