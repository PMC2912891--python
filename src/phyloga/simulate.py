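"""Sequence evolution simulator.

Alignments are generated by drawing root states from the stationary
frequencies and evolving them down a given tree with P(t * rate) per
branch, where the per-site rate comes from the model's Pinv/Gamma mixture
(invariant sites never change) and each partition's branch lengths are
scaled by its relative rate.  Same spec + seed always reproduces the same
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, CharSet, PartitionScheme, STATE_ORDER
from .models import SubstitutionModel, TransitionCalculator, site_rate_mixture
from .trees import Tree, TreeError

__all__ = ["SimulationSpec", "simulate_alignment"]


@dataclass
class SimulationSpec:
    """Everything needed to simulate one alignment.

    For partitioned simulations supply one model per partition and a
    :class:`PartitionScheme` whose charsets cover 1..n_sites; otherwise a
    single model and the total site count."""

    tree: Tree
    models: list[SubstitutionModel]
    n_sites: int = 1000
    partitions: PartitionScheme | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.models, SubstitutionModel):
            self.models = [self.models]
        if self.partitions is None:
            cs = CharSet("all", frozenset(range(1, self.n_sites + 1)))
            self.partitions = PartitionScheme([cs])
        sizes = sum(self.partitions.sizes)
        if sizes != self.n_sites:
            raise TreeError(
                f"partitions cover {sizes} sites but n_sites={self.n_sites}")
        if len(self.models) != len(self.partitions.partitions):
            raise TreeError("need one model per partition")


def simulate_alignment(spec: SimulationSpec,
                       rng: np.random.Generator | None = None) -> Alignment:
    """Evolve sequences along ``spec.tree``; returns a Nexus-writable alignment."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    tree = spec.tree
    taxa = sorted(tree.taxa)
    if len(taxa) < 2:
        raise TreeError("simulation needs at least two taxa")

    columns = np.empty((len(taxa), spec.n_sites), dtype=np.int8)
    taxon_row = {t: i for i, t in enumerate(taxa)}

    for model, charset, rel_rate in zip(spec.models, spec.partitions.partitions,
                                        spec.partitions.relative_rates):
        sites = sorted(charset.sites)
        n = len(sites)
        calc = TransitionCalculator(model)
        mixture = site_rate_mixture(model)
        weights = np.array([w for _, w in mixture])
        rates = np.array([r for r, _ in mixture])
        site_rates = rates[rng.choice(len(rates), size=n, p=weights)] * rel_rate

        root = next(iter(tree.internal_nodes()), None)
        if root is None:
            root = tree.leaf_by_label(taxa[0])
        states = {root: rng.choice(4, size=n, p=model.frequencies)}
        # Iterative preorder walk from the root.
        stack = [(root, None)]
        while stack:
            node, parent = stack.pop()
            for child in sorted(tree.adj[node]):
                if child == parent:
                    continue
                states[child] = _evolve(states[node], tree.adj[node][child],
                                        site_rates, calc, rng)
                stack.append((child, node))
        for node, label in tree.labels.items():
            columns[taxon_row[label], [s - 1 for s in sites]] = states[node]

    sequences = {
        taxon: "".join(STATE_ORDER[s] for s in columns[i])
        for i, taxon in enumerate(taxa)
    }
    return Alignment(taxa, sequences)


def _evolve(parent_states: np.ndarray, branch_length: float,
            site_rates: np.ndarray, calc: TransitionCalculator,
            rng: np.random.Generator) -> np.ndarray:
    """Draw child states site by site; rate-0 (invariant) sites are copied."""
    out = parent_states.copy()
    variable = site_rates > 0
    if branch_length == 0 or not variable.any():
        return out
    unique_rates = np.unique(site_rates[variable])
    for rate in unique_rates:
        mask = site_rates == rate
        P = calc.probabilities(branch_length * rate)
        cum = P.cumsum(axis=1)
        draws = rng.random(int(mask.sum()))
        parents = parent_states[mask]
        out[mask] = (draws[:, None] > cum[parents]).sum(axis=1)
    return out
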