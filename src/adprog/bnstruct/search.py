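"""Score-based structure search: greedy hill climbing and tabu search.

Both walk the space of DAGs with add / delete / reverse moves, never
violating acyclicity or the edge blacklist, scoring candidates by the
decomposable BIC (only the affected families are rescored, with memoization).
Hill climbing restarts from random constraint-respecting graphs; tabu search
permits non-improving moves while keeping a list of recently undone moves
tabu, returning the best structure visited.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import networkx as nx

from .constraints import ConstraintSet
from .discretize import DiscreteDataset
from .score import ScoreCache


def _would_create_cycle(g: nx.DiGraph, u: str, v: str) -> bool:
    # adding u -> v creates a cycle iff v already reaches u
    return g.has_node(v) and g.has_node(u) and nx.has_path(g, v, u)


def _reverse_creates_cycle(g: nx.DiGraph, u: str, v: str) -> bool:
    # reversing u -> v is illegal iff u still reaches v without the edge (u, v)
    stack = [u]
    seen = {u}
    while stack:
        x = stack.pop()
        for y in g.successors(x):
            if x == u and y == v:
                continue
            if y == v:
                return True
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return False


def _candidate_moves(g: nx.DiGraph, nodes: list[str], constraints: ConstraintSet):
    """Yield (kind, u, v) for all admissible add/delete/reverse moves."""
    edges = set(g.edges)
    for u in nodes:
        for v in nodes:
            if u == v:
                continue
            if (u, v) in edges:
                if (u, v) not in constraints.required:
                    yield ("del", u, v)
                    if constraints.allows(v, u) and not _reverse_creates_cycle(g, u, v):
                        yield ("rev", u, v)
            else:
                if constraints.allows(u, v) and not _would_create_cycle(g, u, v):
                    yield ("add", u, v)


def _move_delta(
    g: nx.DiGraph, cache: ScoreCache, kind: str, u: str, v: str
) -> float:
    pa_v = tuple(g.predecessors(v))
    if kind == "add":
        return cache.family(v, pa_v + (u,)) - cache.family(v, pa_v)
    if kind == "del":
        new_pa = tuple(x for x in pa_v if x != u)
        return cache.family(v, new_pa) - cache.family(v, pa_v)
    # reverse u -> v: remove from v's family, add to u's
    pa_u = tuple(g.predecessors(u))
    new_pa_v = tuple(x for x in pa_v if x != u)
    return (
        cache.family(v, new_pa_v)
        - cache.family(v, pa_v)
        + cache.family(u, pa_u + (v,))
        - cache.family(u, pa_u)
    )


def _apply(g: nx.DiGraph, kind: str, u: str, v: str) -> None:
    if kind == "add":
        g.add_edge(u, v)
    elif kind == "del":
        g.remove_edge(u, v)
    else:
        g.remove_edge(u, v)
        g.add_edge(v, u)


def _empty_graph(nodes: list[str], constraints: ConstraintSet) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for u, v in constraints.required:
        g.add_edge(u, v)
    return g


def _random_start(
    nodes: list[str], constraints: ConstraintSet, rng: np.random.Generator
) -> nx.DiGraph:
    g = _empty_graph(nodes, constraints)
    n_try = max(1, len(nodes))
    for _ in range(n_try):
        u, v = (nodes[i] for i in rng.choice(len(nodes), size=2, replace=False))
        if constraints.allows(u, v) and not g.has_edge(u, v) and not _would_create_cycle(g, u, v):
            g.add_edge(u, v)
    return g


def _greedy_climb(
    g: nx.DiGraph,
    nodes: list[str],
    cache: ScoreCache,
    constraints: ConstraintSet,
) -> float:
    """Greedy ascent in place; returns the total improvement."""
    total = 0.0
    while True:
        best_delta = 1e-10
        best_move = None
        for move in _candidate_moves(g, nodes, constraints):
            delta = _move_delta(g, cache, *move)
            if delta > best_delta:
                best_delta = delta
                best_move = move
        if best_move is None:
            return total
        _apply(g, *best_move)
        total += best_delta


def hill_climbing(
    data: DiscreteDataset,
    constraints: ConstraintSet | None = None,
    restarts: int = 50,
    seed: int = 0,
    penalty: float = 1.0,
) -> nx.DiGraph:
    """Greedy hill climbing with random restarts; returns the best local optimum.

    The first climb starts from the empty graph (plus required arcs), the
    remaining ``restarts`` from random admissible graphs. Deterministic given
    ``seed``.
    """
    constraints = constraints or ConstraintSet()
    nodes = list(data.data.columns)
    cache = ScoreCache(data, penalty=penalty)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 409]))

    def total_score(g: nx.DiGraph) -> float:
        return sum(cache.family(v, tuple(g.predecessors(v))) for v in nodes)

    best_g = _empty_graph(nodes, constraints)
    _greedy_climb(best_g, nodes, cache, constraints)
    best_s = total_score(best_g)
    for _ in range(restarts):
        g = _random_start(nodes, constraints, rng)
        _greedy_climb(g, nodes, cache, constraints)
        s = total_score(g)
        if s > best_s + 1e-12:
            best_s, best_g = s, g
    return best_g


def tabu_search(
    data: DiscreteDataset,
    constraints: ConstraintSet | None = None,
    tabu_len: int = 10,
    max_iter: int = 1000,
    max_stagnant: int = 15,
    seed: int = 0,
    penalty: float = 1.0,
) -> nx.DiGraph:
    """Tabu search over DAG space; returns the best structure visited.

    At each iteration the best admissible non-tabu move is taken even when it
    worsens the score; the inverse move is then tabu for ``tabu_len``
    iterations. Search stops after ``max_iter`` iterations or ``max_stagnant``
    consecutive iterations without improving the incumbent. Deterministic
    given ``seed`` (the seed only disambiguates nothing here -- the walk is
    fully deterministic -- but is kept for interface symmetry).
    """
    constraints = constraints or ConstraintSet()
    nodes = list(data.data.columns)
    cache = ScoreCache(data, penalty=penalty)

    g = _empty_graph(nodes, constraints)
    _greedy_climb(g, nodes, cache, constraints)

    def total_score(gr: nx.DiGraph) -> float:
        return sum(cache.family(v, tuple(gr.predecessors(v))) for v in nodes)

    best_g = g.copy()
    best_s = current_s = total_score(g)
    tabu: deque[tuple[str, str, str]] = deque(maxlen=tabu_len)
    inverse = {"add": "del", "del": "add", "rev": "rev"}
    stagnant = 0
    for _ in range(max_iter):
        best_move = None
        best_delta = -np.inf
        for move in _candidate_moves(g, nodes, constraints):
            if move in tabu:
                continue
            delta = _move_delta(g, cache, *move)
            if delta > best_delta:
                best_delta = delta
                best_move = move
        if best_move is None:
            break
        _apply(g, *best_move)
        current_s += best_delta
        kind, u, v = best_move
        if kind == "rev":
            tabu.append(("rev", v, u))
        else:
            tabu.append((inverse[kind], u, v))
        if current_s > best_s + 1e-12:
            best_s = current_s
            best_g = g.copy()
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= max_stagnant:
                break
    return best_g
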