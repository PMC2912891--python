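"""Topology and parameter operators, their selection and frequency adaptation.

Five topology operators (NNI, SPR, TBR, TXS, STS) and six parameter
operators (all branch lengths, internal branch lengths, rate-matrix
parameters, Gamma shape, Pinv, among-partition rates).  Edits carry full
before/after snapshots, so applying then undoing restores the exact prior
state.  Proposal magnitudes are multiplicative for positive parameters:
new = old * e^u with u ~ Uniform(-lambda, lambda).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import SubstitutionModel
from .trees import Tree, bipartitions, canonical_split

__all__ = [
    "OperatorError",
    "TopologyEdit",
    "ParameterEdit",
    "OperatorSet",
    "propose_topology",
    "propose_parameter",
    "apply_edit",
    "undo_edit",
    "nni_neighborhood",
    "spr_neighborhood",
    "tbr_neighborhood",
    "TOPOLOGY_KINDS",
    "PARAMETER_TARGETS",
    "PROPOSAL_SCALES",
]

TOPOLOGY_KINDS = ("NNI", "SPR", "TBR", "TXS", "STS")
PARAMETER_TARGETS = (
    "branch_lengths",
    "internal_branch_lengths",
    "rate_matrix",
    "gamma_shape",
    "pinv",
    "partition_rates",
)

# Default proposal magnitudes (lambda of the log-uniform window; Pinv uses an
# additive window reflected into [0, 0.99]).
PROPOSAL_SCALES = {
    "branch_lengths": 0.5,
    "internal_branch_lengths": 0.5,
    "rate_matrix": 0.5,
    "gamma_shape": 0.5,
    "pinv": 0.1,
    "partition_rates": 0.3,
}

_STS_RESAMPLE_LIMIT = 50


class OperatorError(ValueError):
    pass


@dataclass
class TopologyEdit:
    """A topology move with its undo snapshot.

    ``affected`` holds the splits destroyed by the move (present before,
    absent after) — the branches consensus pruning inspects."""

    kind: str
    old_tree: Tree
    new_tree: Tree | None
    affected: frozenset[frozenset[str]] = frozenset()
    no_op: bool = False


@dataclass
class ParameterEdit:
    """A parameter move with before/after snapshots of what it touches."""

    target: str
    old_tree: Tree | None = None
    new_tree: Tree | None = None
    old_models: list[SubstitutionModel] | None = None
    new_models: list[SubstitutionModel] | None = None
    old_rates: list[float] | None = None
    new_rates: list[float] | None = None
    no_op: bool = False


# ------------------------------------------------------------ topology moves


def _sorted_edges(tree: Tree, internal_only: bool = False):
    source = tree.internal_edges() if internal_only else tree.edges()
    return sorted((u, v) for u, v, _ in source)


def _pick(seq, rng: np.random.Generator):
    return seq[int(rng.integers(len(seq)))]


def _edge_allowed(tree: Tree, u: int, v: int, edge_filter) -> bool:
    if edge_filter is None:
        return True
    side = tree.side_taxa(u, v)
    if len(side) < 2 or len(side) > len(tree.taxa) - 2:
        return True  # trivial splits are never constrained
    return edge_filter(canonical_split(side, tree.taxa))


def _nni_apply(tree: Tree, u: int, v: int, cross: int) -> Tree:
    """Swap one subtree across internal edge u-v; ``cross`` in {0, 1} picks
    which neighbor of v trades places with u's first spare neighbor."""
    out = tree.copy()
    a = sorted(nb for nb in out.adj[u] if nb != v)[0]
    c = sorted(nb for nb in out.adj[v] if nb != u)[cross]
    la = out.disconnect(u, a)
    lc = out.disconnect(v, c)
    out.connect(u, c, lc)
    out.connect(v, a, la)
    return out


def _propose_nni(tree: Tree, rng, edge_filter) -> Tree | None:
    edges = [e for e in _sorted_edges(tree, internal_only=True)
             if _edge_allowed(tree, *e, edge_filter)]
    if not edges:
        return None
    u, v = _pick(edges, rng)
    return _nni_apply(tree, u, v, int(rng.integers(2)))


def _spr_prune_edges(tree: Tree):
    """Directed (p, s) edges where the s-side subtree can be pruned:
    p must be internal."""
    out = []
    for u, v, _ in tree.edges():
        if u not in tree.labels:
            out.append((u, v))
        if v not in tree.labels:
            out.append((v, u))
    return sorted(out)


def _spr_apply(tree: Tree, p: int, s: int, target: tuple[int, int]) -> Tree:
    out = tree.copy()
    pendant = out.disconnect(p, s)
    x, y = sorted(out.adj[p])
    out.smooth(p)
    tx, ty = target
    # The smoothed node p is gone; the target edge survives by construction.
    mid = out.insert_on_edge(tx, ty)
    out.connect(mid, s, pendant)
    return out


def _spr_targets(tree: Tree, p: int, s: int):
    """Edges available for regrafting after pruning (p, s): every edge of
    the remaining fragment except the one created by smoothing p."""
    remaining = set(tree.adj) - tree.side_nodes(p, s)
    x, y = sorted(nb for nb in tree.adj[p] if nb != s)
    merged = (min(x, y), max(x, y))
    targets = []
    for u, v, _ in tree.edges():
        if u in remaining and v in remaining and p not in (u, v):
            targets.append((u, v))
    return sorted(t for t in targets if t != merged)


def _propose_spr(tree: Tree, rng, edge_filter) -> Tree | None:
    prune_edges = _spr_prune_edges(tree)
    if not prune_edges:
        return None
    p, s = _pick(prune_edges, rng)
    targets = [t for t in _spr_targets(tree, p, s)
               if _edge_allowed(tree, *t, edge_filter)]
    if not targets:
        return None
    target = _pick(targets, rng)
    return _spr_apply(tree, p, s, target)


def _tbr_attachments(tree: Tree, side: set[int], endpoint: int):
    """Reconnection points of one fragment after bisection at ``endpoint``.

    A point is either an edge of the smoothed fragment, encoded (a, b), or
    a bare node (n, n) when the fragment is a single leaf."""
    if side == {endpoint}:
        return [(endpoint, endpoint)]
    edges = [(a, b) for a, b, _ in tree.edges()
             if a in side and b in side and endpoint not in (a, b)]
    if endpoint not in tree.labels:
        nbs = sorted(nb for nb in tree.adj[endpoint] if nb in side)
        if len(nbs) == 2:  # endpoint smooths away, its edges merge
            edges.append((min(nbs), max(nbs)))
    else:
        edges = [(endpoint, endpoint)] if not edges else edges
    return sorted(edges)


def _tbr_apply(tree: Tree, u: int, v: int,
               e1: tuple[int, int], e2: tuple[int, int]) -> Tree:
    """Bisect at edge u-v and reconnect the two fragments at attachment
    points e1 (u side) and e2 (v side); the removed length is reused for
    the new bridging edge."""
    out = tree.copy()
    luv = out.disconnect(u, v)
    for node in (u, v):
        if node not in out.labels and out.degree(node) == 2:
            out.smooth(node)
    points = []
    for a, b in (e1, e2):
        points.append(a if a == b else out.insert_on_edge(a, b))
    out.connect(points[0], points[1], luv)
    return out


def _propose_tbr(tree: Tree, rng, edge_filter) -> Tree | None:
    edges = [e for e in _sorted_edges(tree)
             if _edge_allowed(tree, *e, edge_filter)]
    if not edges:
        return None
    u, v = _pick(edges, rng)
    side_v = tree.side_nodes(u, v)
    side_u = set(tree.adj) - side_v
    frag_u = _tbr_attachments(tree, side_u, u)
    frag_v = _tbr_attachments(tree, side_v, v)
    if not frag_u or not frag_v:
        return None
    e1 = _pick(frag_u, rng)
    e2 = _pick(frag_v, rng)
    return _tbr_apply(tree, u, v, e1, e2)


def _propose_txs(tree: Tree, rng, edge_filter) -> Tree | None:
    leaves = sorted(tree.leaves(), key=lambda n: tree.labels[n])
    if len(leaves) < 2:
        return None
    i = int(rng.integers(len(leaves)))
    j = int(rng.integers(len(leaves) - 1))
    if j >= i:
        j += 1
    a, b = leaves[i], leaves[j]
    out = tree.copy()
    out.labels[a], out.labels[b] = out.labels[b], out.labels[a]
    return out


def _propose_sts(tree: Tree, rng, edge_filter) -> Tree | None:
    """Exchange two node-disjoint subtrees (attachment lengths travel with
    their subtrees); resampled a bounded number of times before no-op."""
    directed = _spr_prune_edges(tree)
    if len(directed) < 2:
        return None
    for _ in range(_STS_RESAMPLE_LIMIT):
        (p1, s1) = _pick(directed, rng)
        (p2, s2) = _pick(directed, rng)
        if {p1, s1} == {p2, s2}:
            continue
        side1 = tree.side_nodes(p1, s1)
        side2 = tree.side_nodes(p2, s2)
        if side1 & side2:
            continue
        out = tree.copy()
        l1 = out.disconnect(p1, s1)
        l2 = out.disconnect(p2, s2)
        out.connect(p1, s2, l2)
        out.connect(p2, s1, l1)
        return out
    return None


_TOPOLOGY_PROPOSERS = {
    "NNI": _propose_nni,
    "SPR": _propose_spr,
    "TBR": _propose_tbr,
    "TXS": _propose_txs,
    "STS": _propose_sts,
}


def propose_topology(
    tree: Tree,
    kind: str,
    rng: np.random.Generator,
    edge_filter=None,
) -> TopologyEdit:
    """Propose one topology move of the given kind.

    ``edge_filter`` (split -> bool) restricts candidate internal branches —
    the supervised consensus-pruning mode.  An exhausted candidate pool
    yields a no-op edit, not an error.
    """
    if kind not in _TOPOLOGY_PROPOSERS:
        raise OperatorError(f"unknown topology operator {kind!r}")
    new_tree = _TOPOLOGY_PROPOSERS[kind](tree, rng, edge_filter)
    if new_tree is None:
        return TopologyEdit(kind, tree, None, no_op=True)
    affected = frozenset(bipartitions(tree) - bipartitions(new_tree))
    return TopologyEdit(kind, tree, new_tree, affected=affected)


def nni_neighborhood(tree: Tree) -> set[frozenset[frozenset[str]]]:
    """All topologies one NNI away (as bipartition sets)."""
    out = set()
    for u, v in _sorted_edges(tree, internal_only=True):
        for cross in (0, 1):
            out.add(bipartitions(_nni_apply(tree, u, v, cross)))
    out.discard(bipartitions(tree))
    return out


def spr_neighborhood(tree: Tree) -> set[frozenset[frozenset[str]]]:
    out = set()
    for p, s in _spr_prune_edges(tree):
        for target in _spr_targets(tree, p, s):
            out.add(bipartitions(_spr_apply(tree, p, s, target)))
    out.discard(bipartitions(tree))
    return out


def tbr_neighborhood(tree: Tree) -> set[frozenset[frozenset[str]]]:
    out = set()
    for u, v in _sorted_edges(tree):
        side_v = tree.side_nodes(u, v)
        side_u = set(tree.adj) - side_v
        for e1 in _tbr_attachments(tree, side_u, u):
            for e2 in _tbr_attachments(tree, side_v, v):
                out.add(bipartitions(_tbr_apply(tree, u, v, e1, e2)))
    out.discard(bipartitions(tree))
    return out


# ----------------------------------------------------------- parameter moves


def propose_parameter(
    tree: Tree,
    models: list[SubstitutionModel],
    partition_rates: list[float],
    partition_sizes: list[int],
    target: str,
    rng: np.random.Generator,
    scale: float | None = None,
) -> ParameterEdit:
    """Propose one parameter perturbation.

    Positive parameters receive multiplicative log-uniform proposals; Pinv
    uses an additive proposal reflected into [0, 0.99]; partition rates are
    renormalized to size-weighted mean 1 after the move.
    """
    if target not in PARAMETER_TARGETS:
        raise OperatorError(f"unknown parameter operator {target!r}")
    lam = PROPOSAL_SCALES[target] if scale is None else scale

    if target in ("branch_lengths", "internal_branch_lengths"):
        edges = _sorted_edges(tree, internal_only=target == "internal_branch_lengths")
        if not edges:
            return ParameterEdit(target, no_op=True)
        u, v = _pick(edges, rng)
        out = tree.copy()
        factor = float(np.exp(rng.uniform(-lam, lam)))
        out.set_length(u, v, max(tree.adj[u][v], 1e-9) * factor)
        return ParameterEdit(target, old_tree=tree, new_tree=out)

    if target == "rate_matrix":
        k = int(rng.integers(len(models)))
        model = models[k]
        factor = float(np.exp(rng.uniform(-lam, lam)))
        if model.family == "JC":
            raise OperatorError("JC has no free rate-matrix parameters")
        if model.family in ("K2P", "HKY85"):
            new = model.with_updates(kappa=model.kappa * factor)
        elif model.family == "TN93":
            which = _pick(["kappa1", "kappa2"], rng)
            new = model.with_updates(**{which: getattr(model, which) * factor})
        else:
            idx = int(rng.integers(5))  # GT stays the reference
            ex = model.exchangeabilities.copy()
            ex[idx] *= factor
            new = model.with_updates(exchangeabilities=ex)
        new_models = list(models)
        new_models[k] = new
        return ParameterEdit(target, old_models=list(models), new_models=new_models)

    if target == "gamma_shape":
        k = int(rng.integers(len(models)))
        model = models[k]
        if not model.has_gamma:
            raise OperatorError("Gamma rates are not enabled")
        new_models = list(models)
        factor = float(np.exp(rng.uniform(-lam, lam)))
        new_models[k] = model.with_updates(alpha=model.alpha * factor)
        return ParameterEdit(target, old_models=list(models), new_models=new_models)

    if target == "pinv":
        k = int(rng.integers(len(models)))
        model = models[k]
        if model.pinv == 0.0:
            raise OperatorError("Pinv is not enabled")
        value = model.pinv + float(rng.uniform(-lam, lam))
        value = _reflect(value, 0.0, 0.99)
        new_models = list(models)
        new_models[k] = model.with_updates(pinv=value)
        return ParameterEdit(target, old_models=list(models), new_models=new_models)

    # partition_rates
    if len(partition_rates) < 2:
        raise OperatorError("among-partition rates need at least two partitions")
    k = int(rng.integers(len(partition_rates)))
    rates = np.asarray(partition_rates, dtype=float)
    rates[k] *= float(np.exp(rng.uniform(-lam, lam)))
    weights = np.asarray(partition_sizes, dtype=float)
    rates /= float((rates * weights).sum() / weights.sum())
    return ParameterEdit(target, old_rates=list(partition_rates),
                         new_rates=[float(r) for r in rates])


def _reflect(value: float, lo: float, hi: float) -> float:
    span = hi - lo
    value = (value - lo) % (2.0 * span)
    return lo + (value if value <= span else 2.0 * span - value)


# ------------------------------------------------------------- apply / undo


def apply_edit(current: Tree, edit: TopologyEdit | ParameterEdit) -> Tree:
    """Return the edited tree; raises if ``edit`` was not proposed for
    ``current`` (stale edit)."""
    source = edit.old_tree
    if source is not None and source is not current:
        raise OperatorError("stale edit: proposed for a different tree")
    if edit.no_op or edit.new_tree is None:
        return current
    return edit.new_tree


def undo_edit(current: Tree, edit: TopologyEdit | ParameterEdit) -> Tree:
    """Restore the pre-edit tree; apply-then-undo is the identity."""
    if edit.no_op or edit.new_tree is None:
        return current
    if edit.new_tree is not current:
        raise OperatorError("stale edit: current tree is not this edit's result")
    return edit.old_tree


# ------------------------------------------------------- operator selection


@dataclass
class OperatorSet:
    """Enabled operators with their frequencies and adaptation state.

    Modes: ``fixed`` (draw by frequency), ``ordered`` (round-robin),
    ``random`` (uniform), ``dynamic`` (draw by frequency, periodically
    re-weighted in proportion to each operator's realized likelihood gain,
    never below the configured minima).
    """

    operators: list[str]
    frequencies: list[float] = field(default_factory=list)
    minima: list[float] | float = 0.0
    mode: str = "fixed"
    adapt_interval: int = 100

    def __post_init__(self) -> None:
        if not self.operators:
            raise OperatorError("no operators enabled")
        known = set(TOPOLOGY_KINDS) | set(PARAMETER_TARGETS)
        for op in self.operators:
            if op not in known:
                raise OperatorError(f"unknown operator {op!r}")
        n = len(self.operators)
        if not self.frequencies:
            self.frequencies = [1.0 / n] * n
        if len(self.frequencies) != n:
            raise OperatorError("frequencies must match operators")
        total = sum(self.frequencies)
        if total <= 0:
            raise OperatorError("frequencies must sum to a positive value")
        self.frequencies = [f / total for f in self.frequencies]
        if isinstance(self.minima, (int, float)):
            self.minima = [float(self.minima)] * n
        if sum(self.minima) > 1.0 + 1e-9:
            raise OperatorError("minimum frequencies exceed 1")
        self.gains: dict[str, float] = {op: 0.0 for op in self.operators}
        self._cursor = 0
        self._steps_since_adapt = 0

    def choose(self, rng: np.random.Generator) -> str:
        if self.mode == "ordered":
            op = self.operators[self._cursor % len(self.operators)]
            self._cursor += 1
            return op
        if self.mode == "random":
            return self.operators[int(rng.integers(len(self.operators)))]
        u = float(rng.random())
        acc = 0.0
        for op, freq in zip(self.operators, self.frequencies):
            acc += freq
            if u < acc:
                return op
        return self.operators[-1]

    def record_gain(self, op: str, gain: float) -> None:
        """Credit an operator with the realized lnL improvement of an
        accepted step (rejected proposals contribute nothing)."""
        if gain > 0:
            self.gains[op] += gain
        self._steps_since_adapt += 1
        if self.mode == "dynamic" and self._steps_since_adapt >= self.adapt_interval:
            self.adapt_frequencies()

    def adapt_frequencies(self) -> None:
        """freq_i = min_i + (1 - sum(min)) * gain_i / sum(gains); gains reset.
        All-zero gains leave frequencies unchanged."""
        gains = np.array([max(self.gains[op], 0.0) for op in self.operators])
        if gains.sum() > 0:
            spare = 1.0 - sum(self.minima)
            raw = gains / gains.sum()
            self.frequencies = [m + spare * r for m, r in zip(self.minima, raw)]
        self.gains = {op: 0.0 for op in self.operators}
        self._steps_since_adapt = 0

    @property
    def topology_operators(self) -> list[str]:
        return [op for op in self.operators if op in TOPOLOGY_KINDS]
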