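"""Partitioned maximum-likelihood evaluation by the pruning algorithm.

Likelihoods are computed per partition over compressed site patterns, with
per-node log-scaling against underflow.  Among-partition relative rates and
per-category Gamma rates enter as multipliers on branch lengths.  A cache
object supports recomputing only the root-ward path after branch-length
edits; topology edits rebuild the cache (operators produce snapshot-based
edits, so node identity is not stable across them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import Alignment, PartitionScheme, SitePatternTable, compress_patterns
from .models import SubstitutionModel, TransitionCalculator, site_rate_mixture
from .trees import Tree, TreeError

logger = logging.getLogger(__name__)

__all__ = [
    "LikelihoodValue",
    "LikelihoodEngine",
    "LikelihoodCache",
    "optimize_parameters",
    "BRANCH_LENGTH_BOUNDS",
]

BRANCH_LENGTH_BOUNDS = (1e-8, 10.0)
_TINY = 1e-300


@dataclass
class LikelihoodValue:
    """Total log-likelihood and its per-partition decomposition."""

    total: float
    per_partition: list[float]

    def __float__(self) -> float:
        return self.total


def _mask_to_partials(masks: np.ndarray) -> np.ndarray:
    """(n_pat,) IUPAC masks -> (n_pat, 4) conditional leaf likelihoods."""
    bits = np.array([1, 2, 4, 8], dtype=np.uint8)
    return ((masks[:, None] & bits[None, :]) > 0).astype(float)


class _RootedIndex:
    """Postorder array view of a tree below a virtual root."""

    __slots__ = ("root", "order", "parent", "children", "blen")

    def __init__(self, tree: Tree, root: int | None = None):
        if root is None:
            internals = tree.internal_nodes()
            if internals:
                anchor = tree.leaf_by_label(min(tree.taxa))
                root = next(iter(tree.adj[anchor]))
            else:  # two-taxon tree: root on a leaf
                root = tree.leaf_by_label(min(tree.taxa))
        self.root = root
        self.parent: dict[int, int | None] = {root: None}
        self.children: dict[int, list[int]] = {}
        self.blen: dict[int, float] = {}
        order: list[int] = []
        stack = [root]
        while stack:
            node = stack.pop()
            order.append(node)
            kids = [nb for nb in tree.adj[node] if nb != self.parent[node]]
            self.children[node] = kids
            for kid in kids:
                self.parent[kid] = node
                self.blen[kid] = tree.adj[node][kid]
                stack.append(kid)
        self.order = order[::-1]  # postorder: children before parents

    def path_to_root(self, node: int) -> list[int]:
        path = []
        cursor: int | None = node
        while cursor is not None:
            path.append(cursor)
            cursor = self.parent[cursor]
        return path


class LikelihoodEngine:
    """Evaluates trees against one alignment under a partitioned model set.

    Parameters
    ----------
    alignment:
        The sequence data; leaves of evaluated trees must match its taxa.
    models:
        One :class:`SubstitutionModel` per partition (or a single model for
        the trivial scheme).
    partitions:
        Optional :class:`PartitionScheme`; defaults to a single partition
        covering all sites.  Its ``relative_rates`` hold the
        among-partition rates (size-weighted mean 1).
    """

    def __init__(
        self,
        alignment: Alignment,
        models: SubstitutionModel | list[SubstitutionModel],
        partitions: PartitionScheme | None = None,
    ):
        if alignment.n_sites == 0:
            raise TreeError("alignment has no sites")
        self.alignment = alignment
        self.partitions = partitions or PartitionScheme.single(alignment)
        if isinstance(models, SubstitutionModel):
            models = [models] * len(self.partitions.partitions)
        if len(models) != len(self.partitions.partitions):
            raise TreeError("need one model per partition")
        self.models: list[SubstitutionModel] = list(models)
        self.tables: list[SitePatternTable] = [
            compress_patterns(alignment, cs) for cs in self.partitions.partitions
        ]
        # Per partition, per taxon label: (n_pat, 4) leaf conditionals.
        self.leaf_partials: list[dict[str, np.ndarray]] = []
        for table in self.tables:
            self.leaf_partials.append(
                {taxon: _mask_to_partials(table.patterns[i])
                 for i, taxon in enumerate(table.taxa)}
            )

    @property
    def partition_rates(self) -> list[float]:
        return self.partitions.relative_rates

    def set_partition_rates(self, rates) -> None:
        self.partitions.relative_rates = list(self.partitions.normalized_rates(rates))

    def log_likelihood(self, tree: Tree, root: int | None = None) -> LikelihoodValue:
        """lnL of ``tree``; equals the cache-based computation exactly."""
        return LikelihoodCache(self, tree, root=root).value()


class _PartitionState:
    """Cached pruning state (partials + scale contributions) for one partition."""

    __slots__ = ("calc", "mixture", "rates", "weights", "partials", "scalelog")

    def __init__(self, engine: LikelihoodEngine, k: int, rate: float):
        model = engine.models[k]
        self.calc = TransitionCalculator(model)
        mixture = site_rate_mixture(model)
        self.rates = np.array([r * rate for r, _ in mixture])
        self.mixture = np.array([w for _, w in mixture])
        self.weights = engine.tables[k].weights
        self.partials: dict[int, np.ndarray] = {}
        self.scalelog: dict[int, np.ndarray] = {}


class LikelihoodCache:
    """Partial-likelihood vectors for one (tree, engine) pair.

    ``invalidate_and_update`` recomputes only nodes on the root-ward path of
    edited branches; the result always equals a from-scratch computation.
    """

    def __init__(self, engine: LikelihoodEngine, tree: Tree, root: int | None = None):
        if tree.taxa != frozenset(engine.alignment.taxa):
            raise TreeError("tree leaves do not match alignment taxa")
        for _, _, length in tree.edges():
            if length < 0:
                raise TreeError("negative branch length")
        self.engine = engine
        self.tree = tree
        self.index = _RootedIndex(tree, root=root)
        self.states = [
            _PartitionState(engine, k, rate)
            for k, rate in enumerate(engine.partition_rates)
        ]
        for node in self.index.order:
            self._compute_node(node)

    # ------------------------------------------------------------- internals

    def _compute_node(self, node: int) -> None:
        idx = self.index
        is_leaf = node in self.tree.labels
        for k, st in enumerate(self.states):
            n_pat = self.engine.tables[k].n_patterns
            n_cat = len(st.rates)
            if is_leaf:
                base = self.engine.leaf_partials[k][self.tree.labels[node]]
                partial = np.broadcast_to(base, (n_cat, n_pat, 4)).copy()
            else:
                partial = np.ones((n_cat, n_pat, 4))
            for child in idx.children[node]:
                P = st.calc.probability_stack(st.rates * idx.blen[child])
                partial *= np.einsum("cij,cpj->cpi", P, st.partials[child])
            factor = partial.max(axis=(0, 2))  # shared across categories
            safe = np.where(factor > 0, factor, 1.0)
            partial /= safe[None, :, None]
            st.partials[node] = partial
            st.scalelog[node] = np.log(np.maximum(factor, _TINY))

    # ------------------------------------------------------------- queries

    def value(self) -> LikelihoodValue:
        per_partition = []
        root = self.index.root
        for k, st in enumerate(self.states):
            pi = self.engine.models[k].frequencies
            site = np.einsum("c,cpi,i->p", st.mixture, st.partials[root], pi)
            total_scale = sum(st.scalelog.values())
            lnl = float(np.dot(st.weights, np.log(np.maximum(site, _TINY)) + total_scale))
            per_partition.append(lnl)
        return LikelihoodValue(float(sum(per_partition)), per_partition)

    def invalidate_and_update(self, edited_branches) -> LikelihoodValue:
        """Recompute after in-place branch-length edits on ``self.tree``.

        ``edited_branches`` is an iterable of (u, v) node pairs.  Only the
        parents of edited branches and their ancestors are recomputed."""
        idx = self.index
        dirty: set[int] = set()
        for u, v in edited_branches:
            child = v if idx.parent.get(v) == u else u
            if idx.parent.get(child) != (u if child == v else v):
                raise TreeError(f"({u}, {v}) is not a parent-child edge of this cache")
            idx.blen[child] = self.tree.adj[u][v]
            parent = idx.parent[child]
            if parent is not None:
                dirty.update(idx.path_to_root(parent))
        for node in idx.order:
            if node in dirty:
                self._compute_node(node)
        return self.value()


# --------------------------------------------------------------- optimizer


def _brent(objective, bounds, tol=1e-6):
    res = minimize_scalar(objective, bounds=bounds, method="bounded",
                          options={"xatol": tol})
    return float(res.x), float(res.fun)


def optimize_parameters(
    tree: Tree,
    engine: LikelihoodEngine,
    targets: tuple[str, ...] = ("branch_lengths",),
    max_cycles: int = 3,
    tol: float = 1e-4,
) -> LikelihoodValue:
    """Coordinate-wise numerical optimization; lnL never decreases.

    ``targets`` is a subset of {branch_lengths, rate_matrix, gamma_shape,
    pinv, partition_rates}.  Branch lengths use bounded Brent search per
    branch on [1e-8, 10]; model parameters use log-scale Brent; partition
    rates are renormalized inside the objective so the size-weighted mean
    stays 1.  The tree and the engine's models are updated in place.
    """
    best = engine.log_likelihood(tree).total
    for _ in range(max_cycles):
        start = best
        if "branch_lengths" in targets or "internal_branch_lengths" in targets:
            best = _optimize_branch_lengths(
                tree, engine, internal_only="branch_lengths" not in targets)
        if "rate_matrix" in targets:
            best = _optimize_rate_matrix(tree, engine)
        if "gamma_shape" in targets:
            best = _optimize_scalar_param(tree, engine, "alpha", (0.02, 100.0))
        if "pinv" in targets:
            best = _optimize_pinv(tree, engine)
        if "partition_rates" in targets and len(engine.models) > 1:
            best = _optimize_partition_rates(tree, engine)
        if best - start < tol:
            break
    return engine.log_likelihood(tree)


def _optimize_branch_lengths(tree: Tree, engine: LikelihoodEngine,
                             internal_only: bool = False) -> float:
    cache = LikelihoodCache(engine, tree)
    edges = sorted(
        (u, v) for u, v, _ in
        (tree.internal_edges() if internal_only else tree.edges())
    )
    best = cache.value().total
    for u, v in edges:
        current = tree.adj[u][v]

        def objective(x):
            tree.set_length(u, v, x)
            return -cache.invalidate_and_update([(u, v)]).total

        x, fun = _brent(objective, BRANCH_LENGTH_BOUNDS)
        if -fun >= best:
            best = -fun
            tree.set_length(u, v, x)
        else:  # numerical edge case: keep the previous length
            tree.set_length(u, v, current)
        cache.invalidate_and_update([(u, v)])
    return best


def _optimize_rate_matrix(tree: Tree, engine: LikelihoodEngine) -> float:
    best = engine.log_likelihood(tree).total
    for k, model in enumerate(engine.models):
        if model.family == "JC":
            continue
        if model.family in ("K2P", "HKY85"):
            params = ["kappa"]
        elif model.family == "TN93":
            params = ["kappa1", "kappa2"]
        else:  # GTR: five free exchangeabilities, GT fixed at 1
            params = [0, 1, 2, 3, 4]
        for param in params:
            best = _optimize_one_model_param(tree, engine, k, param, best)
    return best


def _optimize_one_model_param(tree, engine, k, param, best) -> float:
    model = engine.models[k]

    def set_value(value):
        if isinstance(param, str):
            engine.models[k] = engine.models[k].with_updates(**{param: value})
        else:
            ex = engine.models[k].exchangeabilities.copy()
            ex[param] = value
            engine.models[k] = engine.models[k].with_updates(exchangeabilities=ex)

    def objective(log_value):
        set_value(float(np.exp(log_value)))
        return -engine.log_likelihood(tree).total

    current = model.kappa if param == "kappa" else (
        model.kappa1 if param == "kappa1" else
        model.kappa2 if param == "kappa2" else model.exchangeabilities[param])
    x, fun = _brent(objective, (np.log(0.02), np.log(50.0)))
    if -fun >= best:
        set_value(float(np.exp(x)))
        return -fun
    set_value(current)
    return best


def _optimize_scalar_param(tree, engine, name: str, bounds) -> float:
    best = engine.log_likelihood(tree).total
    for k, model in enumerate(engine.models):
        if name == "alpha" and not model.has_gamma:
            continue
        current = getattr(model, name)

        def objective(log_value):
            engine.models[k] = engine.models[k].with_updates(**{name: float(np.exp(log_value))})
            return -engine.log_likelihood(tree).total

        x, fun = _brent(objective, (np.log(bounds[0]), np.log(bounds[1])))
        if -fun >= best:
            engine.models[k] = engine.models[k].with_updates(**{name: float(np.exp(x))})
            best = -fun
        else:
            engine.models[k] = engine.models[k].with_updates(**{name: current})
    return best


def _optimize_pinv(tree, engine) -> float:
    best = engine.log_likelihood(tree).total
    for k, model in enumerate(engine.models):
        if model.pinv == 0.0:
            continue  # Pinv disabled for this partition
        current = model.pinv

        def objective(p):
            engine.models[k] = engine.models[k].with_updates(pinv=float(p))
            return -engine.log_likelihood(tree).total

        x, fun = _brent(objective, (0.0, 0.95))
        if -fun >= best:
            engine.models[k] = engine.models[k].with_updates(pinv=float(x))
            best = -fun
        else:
            engine.models[k] = engine.models[k].with_updates(pinv=current)
    return best


def _optimize_partition_rates(tree, engine) -> float:
    best = engine.log_likelihood(tree).total
    n = len(engine.models)
    for k in range(n):
        saved = list(engine.partition_rates)

        def objective(log_r):
            rates = list(saved)
            rates[k] = float(np.exp(log_r))
            engine.set_partition_rates(rates)  # renormalizes: weighted mean 1
            return -engine.log_likelihood(tree).total

        x, fun = _brent(objective, (np.log(0.05), np.log(20.0)))
        if -fun >= best:
            rates = list(saved)
            rates[k] = float(np.exp(x))
            engine.set_partition_rates(rates)
            best = -fun
        else:
            engine.set_partition_rates(saved)
    return best
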