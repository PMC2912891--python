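"""Convergence statistics and stopping rules.

The mean relative error (MRE) compares two consensus trees through their
bipartition support values:

    MRE(Ti, Tj) = (1/nPartition) * sum_p |phi_i,p - phi_j,p| / max(phi_i,p, phi_j,p)

where the sum runs over the bipartitions observed in Ti or Tj (identical
bipartitions counted once), and a bipartition present in only one tree
contributes 1.  Consensus trees entering the MRE retain *all* observed
bipartitions with their support values, not only the majority ones.

Two stopping automata use the statistic: an intra-replicate rule on
consensus trees sampled every n > 1 generations, and an inter-replicate
rule on running consensuses across completed replicates.  Both keep a
reference consensus and a counter: a value below the threshold increments
the counter; a value at or above it moves the reference to the newest
sample and resets the counter; the run stops once the counter reaches the
required consecutive count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trees import ConsensusTree, Tree, TreeError, majority_consensus

__all__ = [
    "mre",
    "MreStopper",
    "likelihood_stability_stop",
    "ReplicateSet",
    "run_replicates",
]


def _support_map(tree) -> dict[frozenset[str], float]:
    if isinstance(tree, ConsensusTree):
        return tree.split_support
    if isinstance(tree, dict):
        return tree
    raise TreeError("mre expects ConsensusTree objects or split->support maps")


def mre(ti, tj) -> float:
    """Mean relative error between two consensus trees (in [0, 1])."""
    if isinstance(ti, ConsensusTree) and isinstance(tj, ConsensusTree):
        if ti.taxa != tj.taxa:
            raise TreeError("consensus trees have different taxon sets")
    si, sj = _support_map(ti), _support_map(tj)
    observed = set(si) | set(sj)
    if not observed:
        return 0.0
    total = 0.0
    for split in observed:
        phi_i = si.get(split, 0.0)
        phi_j = sj.get(split, 0.0)
        total += abs(phi_i - phi_j) / max(phi_i, phi_j)
    return total / len(observed)


@dataclass
class MreStopper:
    """Reference-advance/counter automaton shared by both MRE stopping rules.

    ``observe`` consumes the next consensus sample and returns True when the
    counter has reached ``required`` consecutive below-threshold values.
    """

    threshold: float = 0.05
    required: int = 10
    reference: object = None
    reference_index: int = -1
    counter: int = 0
    history: list[tuple[int, int, float, int]] = field(default_factory=list)

    def observe(self, sample, index: int | None = None) -> bool:
        if index is None:
            index = len(self.history) + 1
        if self.reference is None:
            self.reference = sample
            self.reference_index = index
            return False
        value = mre(self.reference, sample)
        if value < self.threshold:
            self.counter += 1
        else:
            self.reference = sample
            self.reference_index = index
            self.counter = 0
        self.history.append((index, self.reference_index, value, self.counter))
        return self.counter >= self.required


def likelihood_stability_stop(trace, window: int, epsilon: float) -> bool:
    """Stop when best-lnL improvement over the last ``window`` entries is
    below ``epsilon`` (strict: an improvement of exactly ``epsilon``
    continues)."""
    if window < 2:
        raise TreeError("stability window must be at least 2")
    if len(trace) < window:
        return False
    return (trace[-1] - trace[-window]) < epsilon


# ------------------------------------------------------------- replicates


@dataclass
class ReplicateSet:
    """Results of repeated independent searches.

    Each replicate contributes its single best tree; the running consensus
    over replicates 1..i feeds the inter-replicate MRE rule, and the final
    majority-rule consensus carries per-branch support equal to the fraction
    of replicates displaying the branch.
    """

    trees: list[Tree] = field(default_factory=list)
    lnls: list[float] = field(default_factory=list)
    stopper: MreStopper | None = None
    stop_reason: str = ""

    @property
    def n_replicates(self) -> int:
        return len(self.trees)

    def running_consensus(self) -> ConsensusTree:
        return majority_consensus(self.trees)

    def final_consensus(self) -> ConsensusTree:
        return majority_consensus(self.trees)


def run_replicates(alignment, settings, progress=None) -> ReplicateSet:
    """Run independent search replicates with deterministic per-replicate
    seeds derived from the master seed.

    With ``min_replicates > 0`` the replicate count is chosen automatically
    by the inter-replicate MRE rule (bounded by ``max_replicates``);
    otherwise exactly ``settings.replicates`` replicates run.  Completion
    order cannot affect the result: replicate r always uses the RNG stream
    seeded by (master seed, r).
    """
    from .search import run_search  # deferred: search imports this module

    auto = settings.min_replicates > 0
    max_reps = settings.max_replicates if auto else settings.replicates
    if max_reps < 1:
        raise TreeError("replicate count must be at least 1")
    repset = ReplicateSet(stopper=MreStopper(
        threshold=settings.inter_mre_threshold,
        required=settings.inter_mre_consecutive,
    ))
    for r in range(max_reps):
        seed = np.random.SeedSequence([settings.seed, r])
        result = run_search(alignment, settings, seed_sequence=seed)
        repset.trees.append(result.best.tree)
        repset.lnls.append(result.best.lnl)
        if progress is not None:
            progress(r, result)
        if auto:
            done = repset.stopper.observe(repset.running_consensus(), index=r + 1)
            if done and repset.n_replicates >= settings.min_replicates:
                repset.stop_reason = "inter-replicate MRE convergence"
                return repset
    repset.stop_reason = "replicate cap reached" if auto else "fixed replicate count"
    return repset
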