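"""Mapping network edges onto literature-style cause-effect mechanism graphs.

Pathway-pathway edges from the stable network are validated by gene-set
overlap: a one-sided hypergeometric tail probability per edge, with
Benjamini-Yekutieli FDR control across edges. Pathways are related to
mechanism subgraphs (typed cause-effect graphs of genes, variants and
biological processes) the same way, and the mechanism context of an edge is
extracted as the union of shortest paths between the two mapped gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats import hypergeom

from .evaluation.stratify import by_fdr

log = logging.getLogger(__name__)

NODE_TYPES = ("gene", "process", "variant")
RELATIONS = ("increases", "decreases", "association")


# ---------------------------------------------------------------------- types
@dataclass
class GeneSet:
    """Named set of (uppercased) gene symbols."""

    identifier: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(g.upper() for g in self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.identifier!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


def read_cause_effect_tsv(path) -> nx.DiGraph:
    """Read a typed edge list (source, relation, target, source_type, target_type)."""
    df = pd.read_csv(path, sep="\t")
    g = nx.DiGraph()
    for row in df.itertuples(index=False):
        g.add_node(row.source, type=row.source_type)
        g.add_node(row.target, type=row.target_type)
        g.add_edge(row.source, row.target, relation=row.relation)
    return g


def write_cause_effect_tsv(graph: nx.DiGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\trelation\ttarget\tsource_type\ttarget_type\n")
        for u, v, d in graph.edges(data=True):
            fh.write(
                f"{u}\t{d.get('relation', 'association')}\t{v}\t"
                f"{graph.nodes[u].get('type', 'gene')}\t{graph.nodes[v].get('type', 'gene')}\n"
            )


@dataclass
class MechanismMapping:
    pathway: str
    best_subgraph: str | None
    overlaps: pd.DataFrame          # subgraph, k, size_a, size_b, p, q, significant
    significant: list[str] = field(default_factory=list)


# ---------------------------------------------------------------- statistics
def hypergeom_overlap_test(
    setA: set[str] | frozenset[str],
    setB: set[str] | frozenset[str],
    universe: set[str] | frozenset[str],
) -> float:
    """One-sided enrichment p-value P(X >= k), X ~ Hypergeom(N=|U|, K=|A|, n=|B|).

    Both sets must be subsets of the universe; swapping which set plays the
    draw leaves the tail probability unchanged.
    """
    A, B, U = set(setA), set(setB), set(universe)
    if not A or not B:
        raise ValueError("gene sets must be nonempty")
    if not A <= U or not B <= U:
        raise ValueError("both sets must be contained in the universe")
    k = len(A & B)
    return float(hypergeom.sf(k - 1, len(U), len(A), len(B)))


def validate_pathway_edges(
    stable_edges: list[tuple[str, str]],
    pathway_gene_sets: dict[str, set[str] | list[str]],
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Gene-overlap significance of pathway-pathway edges, with BY FDR.

    Edges with an endpoint lacking a gene set are skipped with a log entry.
    Returns a frame (source, target, k, p, q, significant) where significant
    means q < alpha; the summary fraction is len(sig)/len(tested).
    """
    sets = {k: frozenset(str(g).upper() for g in v) for k, v in pathway_gene_sets.items()}
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    else:
        universe = frozenset(str(g).upper() for g in universe)
    rows = []
    for u, v in stable_edges:
        if u not in sets or v not in sets:
            log.info("edge (%s, %s) skipped: endpoint without a gene set", u, v)
            continue
        p = hypergeom_overlap_test(sets[u], sets[v], universe)
        rows.append((u, v, len(sets[u] & sets[v]), p))
    df = pd.DataFrame(rows, columns=["source", "target", "k", "p"])
    df["q"] = by_fdr(df["p"].to_numpy()) if len(df) else []
    df["significant"] = df["q"] < alpha
    return df


def map_pathways_to_mechanism_sets(
    pathway_gene_sets: dict[str, set[str] | list[str]],
    mechanism_subgraph_gene_sets: dict[str, set[str] | list[str]],
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> list[MechanismMapping]:
    """Relate each pathway to the mechanism subgraphs it overlaps.

    One hypergeometric test per (pathway, subgraph) pair; BY adjustment over
    the full matrix of tests. Per pathway, subgraphs with q < alpha are
    retained; the best is the smallest p (ties: larger overlap, then name).
    """
    pws = {k: frozenset(str(g).upper() for g in v) for k, v in pathway_gene_sets.items()}
    mechs = {k: frozenset(str(g).upper() for g in v) for k, v in mechanism_subgraph_gene_sets.items()}
    if universe is None:
        universe = frozenset().union(*pws.values(), *mechs.values())
    else:
        universe = frozenset(str(g).upper() for g in universe)
    rows = []
    for pw, A in pws.items():
        for mg, B in mechs.items():
            k = len(A & B)
            p = hypergeom_overlap_test(A, B, universe)
            rows.append((pw, mg, k, len(A), len(B), p))
    df = pd.DataFrame(rows, columns=["pathway", "subgraph", "k", "size_a", "size_b", "p"])
    df["q"] = by_fdr(df["p"].to_numpy()) if len(df) else []
    df["significant"] = df["q"] < alpha
    out = []
    for pw in pws:
        sub = df[df["pathway"] == pw].copy()
        sub = sub.sort_values(["p", "k", "subgraph"], ascending=[True, False, True], kind="stable")
        sig = sub[sub["significant"]]["subgraph"].tolist()
        best = None
        if len(sig):
            best = sig[0]
        elif len(sub) and sub.iloc[0]["k"] > 0:
            best = str(sub.iloc[0]["subgraph"])
        out.append(
            MechanismMapping(pathway=pw, best_subgraph=best, overlaps=sub.reset_index(drop=True), significant=sig)
        )
    return out


# ---------------------------------------------------------------- path union
def _bfs_shortest_path(
    adj: dict[str, list[str]], a: str, b: str
) -> list[str] | None:
    """One hop-count shortest path with deterministic lexicographic tie-break:
    neighbors are scanned in sorted order and the first discovered parent kept."""
    if a == b:
        return [a]
    parent: dict[str, str] = {a: a}
    frontier = [a]
    while frontier:
        nxt = []
        for u in frontier:
            for w in sorted(adj.get(u, ())):
                if w not in parent:
                    parent[w] = u
                    if w == b:
                        path = [b]
                        while path[-1] != a:
                            path.append(parent[path[-1]])
                        return path[::-1]
                    nxt.append(w)
        frontier = nxt
    return None


def shortest_path_union(
    graph: nx.DiGraph,
    A_nodes: set[str] | list[str],
    B_nodes: set[str] | list[str],
    directed: bool = True,
    all_shortest: bool = False,
) -> nx.DiGraph:
    """Union of shortest paths from every a in A to every b in B.

    Hop-count (unweighted) paths on the directed graph; with
    ``directed=False`` (or as fallback semantics chosen by the caller) paths
    run on the underlying undirected graph but the returned subgraph keeps the
    original edge orientations. ``all_shortest=True`` includes every shortest
    path per pair instead of the single deterministic one. Unreachable pairs
    are logged and skipped. A and B must be nonempty and present in the graph.
    """
    A = sorted(set(A_nodes))
    B = sorted(set(B_nodes))
    if not A or not B:
        raise ValueError("A and B must be nonempty")
    missing = [x for x in A + B if x not in graph]
    if missing:
        raise KeyError(f"nodes absent from graph: {missing}")
    work = graph if directed else graph.to_undirected(as_view=True)
    adj = {u: list(work.neighbors(u)) for u in work.nodes}
    keep_nodes: set[str] = set()
    keep_edges: set[tuple[str, str]] = set()

    def add_path(path: list[str]) -> None:
        keep_nodes.update(path)
        for u, v in zip(path, path[1:]):
            if graph.has_edge(u, v):
                keep_edges.add((u, v))
            else:
                keep_edges.add((v, u))

    for a in A:
        for b in B:
            if all_shortest:
                try:
                    for path in nx.all_shortest_paths(work, a, b):
                        add_path(path)
                except nx.NetworkXNoPath:
                    log.info("no path %s -> %s", a, b)
            else:
                path = _bfs_shortest_path(adj, a, b)
                if path is None:
                    log.info("no path %s -> %s", a, b)
                else:
                    add_path(path)
    sub = nx.DiGraph()
    for u in keep_nodes:
        sub.add_node(u, **graph.nodes[u])
    for u, v in keep_edges:
        sub.add_edge(u, v, **graph.edges[u, v])
    return sub
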