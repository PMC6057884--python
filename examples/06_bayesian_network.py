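"""Constrained Bayesian-network structure learning with bootstrap confidence.

Samples a discrete dataset from a known 10-node DAG, learns structures with
tabu search under the role-based edge blacklist, compares learners by
cross-validated held-out log-likelihood, and reports which edges survive a
bootstrap at the >50% stability threshold.
"""

import networkx as nx
import numpy as np

from adprog.bnstruct import (
    DiscreteDataset, bootstrap_edge_confidence, cv_select_learner,
    hill_climbing, stable_edges, tabu_search,
)
from adprog.synthcohort import random_cpts, random_dag, sample_discrete_bn

dag = random_dag(10, max_in_degree=2, seed=5)
cpts = random_cpts(dag, n_levels=3, seed=5)
df = sample_discrete_bn(dag, cpts, 2000, seed=5)
data = DiscreteDataset(df, {c: ["0", "1", "2"] for c in df.columns},
                       {c: "genomic" for c in df.columns})
print(f"ground truth: {dag.number_of_edges()} edges over {len(dag)} nodes")

ranking = cv_select_learner(
    data,
    {"tabu": lambda d, s: tabu_search(d, seed=s),
     "hill_climbing": lambda d, s: hill_climbing(d, restarts=5, seed=s)},
    k=5, seed=0,
)
print("\nlearner ranking by held-out log-likelihood (higher is better):")
print(ranking.round(4).to_string(index=False))

conf = bootstrap_edge_confidence(data, lambda d, s: tabu_search(d, seed=s),
                                 B=100, seed=0)
stable = stable_edges(conf, threshold=0.5)
true_sk = {frozenset(e) for e in dag.edges}
got_sk = {frozenset(e) for e in stable.edges}
tp = len(true_sk & got_sk)
print(f"\nstable edges (>50% of 100 bootstrap reconstructions): {len(got_sk)}")
print(f"of which in the true skeleton: {tp} "
      f"(precision {tp/max(len(got_sk),1):.2f}, recall {tp/len(true_sk):.2f})")
print("-> bootstrap frequency is a robustness measure: edges driven by real")
print("   conditional dependence persist across data perturbations.")
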