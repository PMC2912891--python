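"""Shared test helpers: independent oracles kept deliberately simple."""

from __future__ import annotations

import itertools

import numpy as np

from phyloga import SimulationSpec, SubstitutionModel, simulate_alignment
from phyloga.alignment import STATE_ORDER
from phyloga.models import TransitionCalculator, site_rate_mixture
from phyloga.trees import Tree


def path_distance_matrix(tree: Tree) -> tuple[np.ndarray, list[str]]:
    """Additive (path-length) distances between all leaf pairs."""
    taxa = sorted(tree.taxa)
    n = len(taxa)
    D = np.zeros((n, n))
    for i, a in enumerate(taxa):
        start = tree.leaf_by_label(a)
        dist = {start: 0.0}
        stack = [start]
        while stack:
            node = stack.pop()
            for nb, length in tree.adj[node].items():
                if nb not in dist:
                    dist[nb] = dist[node] + length
                    stack.append(nb)
        for j, b in enumerate(taxa):
            D[i, j] = dist[tree.leaf_by_label(b)]
    return D, taxa


def brute_force_lnl(tree: Tree, alignment, model: SubstitutionModel) -> float:
    """Exhaustive sum over all internal-state assignments — the independent
    likelihood oracle (usable up to ~6 taxa)."""
    calc = TransitionCalculator(model)
    mixture = site_rate_mixture(model)
    internals = sorted(tree.internal_nodes())
    root = internals[0] if internals else tree.leaf_by_label(min(tree.taxa))
    # Directed edge list away from the root.
    edges = []
    stack = [(root, None)]
    while stack:
        node, parent = stack.pop()
        for nb in sorted(tree.adj[node]):
            if nb != parent:
                edges.append((node, nb, tree.adj[node][nb]))
                stack.append((nb, node))
    leaf_states = {
        node: np.array([STATE_ORDER.index(c) for c in alignment.sequences[label]])
        for node, label in tree.labels.items()
    }
    n_sites = alignment.n_sites
    site_likelihood = np.zeros(n_sites)
    for rate, weight in mixture:
        P = {(u, v): calc.probabilities(length * rate) for u, v, length in edges}
        for assign in itertools.product(range(4), repeat=len(internals)):
            state = dict(zip(internals, assign))
            if root in tree.labels:
                prob = np.asarray(model.frequencies)[leaf_states[root]].copy()
            else:
                prob = np.full(n_sites, model.frequencies[state[root]])
            for u, v, _ in edges:
                su = state[u] if u in state else leaf_states[u]
                sv = state[v] if v in state else leaf_states[v]
                prob = prob * P[(u, v)][su, sv]
            site_likelihood += weight * prob
            if root in tree.labels:
                break  # a leaf root has no internal assignment freedom at itself
    return float(np.log(site_likelihood).sum())


def quick_alignment(tree: Tree, model: SubstitutionModel, n_sites: int, seed: int):
    return simulate_alignment(SimulationSpec(tree, [model], n_sites=n_sites, seed=seed))


def random_binary_tree(taxa, seed, mean=0.1):
    from phyloga import random_tree

    return random_tree(list(taxa), np.random.default_rng(seed), branch_length_mean=mean)
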