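"""Unrooted phylogenetic trees: data model, Newick I/O, bipartition algebra,
consensus building, distance matrices, and starting-tree generators.

A tree is stored as an adjacency map over integer node ids.  Leaves have
degree 1 and carry taxon labels; internal nodes of a binary unrooted tree
have degree 3.  A bipartition (split) is represented canonically as the
frozenset of taxon labels on the side *not* containing the alphabetically
smallest taxon, so a split and its complement compare equal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from collections import Counter

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Tree",
    "TreeError",
    "ConsensusTree",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "split_to_edge",
    "robinson_foulds",
    "majority_consensus",
    "random_tree",
    "nj_tree",
    "lnj_tree",
    "model_distance_matrix",
    "reroot",
    "tree_signature",
]


class TreeError(ValueError):
    pass


class Tree:
    """Adjacency-based unrooted tree with branch lengths.

    ``root`` is an optional display-level rooting (a node id); it never
    affects bipartitions or likelihood.
    """

    __slots__ = ("adj", "labels", "_next_id", "root")

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}
        self.labels: dict[int, str] = {}
        self._next_id = 0
        self.root: int | None = None

    # ---------------------------------------------------------- construction

    def new_node(self, label: str | None = None) -> int:
        node = self._next_id
        self._next_id += 1
        self.adj[node] = {}
        if label is not None:
            self.labels[node] = label
        return node

    def connect(self, u: int, v: int, length: float) -> None:
        if length < 0:
            raise TreeError(f"negative branch length {length}")
        self.adj[u][v] = length
        self.adj[v][u] = length

    def disconnect(self, u: int, v: int) -> float:
        length = self.adj[u].pop(v)
        self.adj[v].pop(u)
        return length

    def set_length(self, u: int, v: int, length: float) -> None:
        if v not in self.adj[u]:
            raise TreeError(f"no edge {u}-{v}")
        if length < 0:
            raise TreeError(f"negative branch length {length}")
        self.adj[u][v] = length
        self.adj[v][u] = length

    def length(self, u: int, v: int) -> float:
        return self.adj[u][v]

    def remove_node(self, node: int) -> None:
        for nb in list(self.adj[node]):
            self.disconnect(node, nb)
        del self.adj[node]
        self.labels.pop(node, None)
        if self.root == node:
            self.root = None

    def smooth(self, node: int) -> None:
        """Remove a degree-2 unlabeled node, merging its two edges."""
        if node in self.labels or self.degree(node) != 2:
            raise TreeError(f"cannot smooth node {node}")
        (a, la), (b, lb) = self.adj[node].items()
        self.remove_node(node)
        self.connect(a, b, la + lb)

    def insert_on_edge(self, u: int, v: int, dist_from_u: float | None = None) -> int:
        """Subdivide edge u-v with a new node; returns the new node id."""
        length = self.disconnect(u, v)
        if dist_from_u is None:
            dist_from_u = length / 2.0
        node = self.new_node()
        self.connect(u, node, dist_from_u)
        self.connect(node, v, max(length - dist_from_u, 0.0))
        return node

    # ---------------------------------------------------------- inspection

    def degree(self, node: int) -> int:
        return len(self.adj[node])

    @property
    def nodes(self) -> list[int]:
        return list(self.adj)

    def leaves(self) -> list[int]:
        return [n for n in self.adj if n in self.labels]

    def internal_nodes(self) -> list[int]:
        return [n for n in self.adj if n not in self.labels]

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.labels.values())

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def edges(self):
        """Yield (u, v, length) with u < v."""
        for u, nbs in self.adj.items():
            for v, length in nbs.items():
                if u < v:
                    yield u, v, length

    def n_edges(self) -> int:
        return sum(1 for _ in self.edges())

    def internal_edges(self):
        for u, v, length in self.edges():
            if u not in self.labels and v not in self.labels:
                yield u, v, length

    def leaf_by_label(self, label: str) -> int:
        for node, lab in self.labels.items():
            if lab == label:
                return node
        raise TreeError(f"no leaf labelled {label!r}")

    def validate_binary(self) -> None:
        n = self.n_leaves
        for node in self.adj:
            expected = 1 if node in self.labels else 3
            if self.degree(node) != expected:
                if self.root == node and self.degree(node) == 2:
                    continue
                raise TreeError(f"node {node} has degree {self.degree(node)}, expected {expected}")
        if self.n_edges() != 2 * n - 3 + (1 if self.root is not None and self.degree(self.root) == 2 else 0):
            raise TreeError("edge count does not match an unrooted binary tree")

    def copy(self) -> "Tree":
        dup = Tree()
        dup.adj = {u: dict(nbs) for u, nbs in self.adj.items()}
        dup.labels = dict(self.labels)
        dup._next_id = self._next_id
        dup.root = self.root
        return dup

    # ---------------------------------------------------------- traversal

    def side_nodes(self, u: int, v: int) -> set[int]:
        """All nodes on the v side of edge u-v (v included)."""
        if v not in self.adj[u]:
            raise TreeError(f"no edge {u}-{v}")
        seen = {u, v}
        stack = [v]
        while stack:
            node = stack.pop()
            for nb in self.adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        seen.discard(u)
        return seen

    def side_taxa(self, u: int, v: int) -> frozenset[str]:
        return frozenset(self.labels[n] for n in self.side_nodes(u, v) if n in self.labels)


# -------------------------------------------------------------- bipartitions


def canonical_split(side: frozenset[str], taxa: frozenset[str]) -> frozenset[str]:
    """Canonical form: the side not containing the smallest taxon."""
    anchor = min(taxa)
    return taxa - side if anchor in side else frozenset(side)


def bipartitions(tree: Tree) -> frozenset[frozenset[str]]:
    """Nontrivial splits induced by the internal branches."""
    taxa = tree.taxa
    splits = set()
    for u, v, _ in tree.internal_edges():
        side = tree.side_taxa(u, v)
        if 2 <= len(side) <= len(taxa) - 2:
            splits.add(canonical_split(side, taxa))
    return frozenset(splits)


def split_to_edge(tree: Tree) -> dict[frozenset[str], tuple[int, int]]:
    """Map each nontrivial split to an internal edge (u, v) realizing it,
    oriented so the v side is the canonical split side."""
    taxa = tree.taxa
    mapping: dict[frozenset[str], tuple[int, int]] = {}
    for u, v, _ in tree.internal_edges():
        side = tree.side_taxa(u, v)
        if 2 <= len(side) <= len(taxa) - 2:
            split = canonical_split(side, taxa)
            mapping[split] = (u, v) if side == split else (v, u)
    return mapping


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    if t1.taxa != t2.taxa:
        raise TreeError("trees have different taxon sets")
    return len(bipartitions(t1) ^ bipartitions(t2))


def tree_signature(tree: Tree, digits: int = 12) -> tuple:
    """Canonical (topology + branch lengths) fingerprint, id-independent.

    Every edge is keyed by the canonical taxon-side of its split (trivial
    pendant edges included, keyed by the single taxon)."""
    taxa = tree.taxa
    entries = []
    for u, v, length in tree.edges():
        side = tree.side_taxa(u, v)
        key = tuple(sorted(canonical_split(side, taxa))) if len(side) not in (0, len(taxa)) else tuple(sorted(side))
        entries.append((key, round(length, digits)))
    return tuple(sorted(entries))


# -------------------------------------------------------------- Newick I/O


def parse_newick(text: str) -> Tree:
    """Parse one Newick string into an unrooted :class:`Tree`.

    A rooted input (binary root) is unrooted by suppressing the degree-2
    root.  Internal-node labels (e.g. support values) are ignored.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise TreeError("Newick string must end with ';'")
    tree = Tree()
    pos = 0
    s = text[:-1]

    def parse_clade() -> tuple[int, float]:
        nonlocal pos
        if pos >= len(s):
            raise TreeError("unexpected end of Newick string")
        if s[pos] == "(":
            pos += 1
            node = tree.new_node()
            while True:
                child, clen = parse_clade()
                tree.connect(node, child, clen)
                if pos >= len(s):
                    raise TreeError("unbalanced parentheses in Newick string")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise TreeError(f"unexpected character {s[pos]!r} at position {pos}")
            _read_label()  # internal label / support: discarded
        else:
            label = _read_label()
            if not label:
                raise TreeError(f"expected taxon label at position {pos}")
            node = tree.new_node(label)
        length = 0.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",():":
                pos += 1
            length = float(s[start:pos])
        return node, length

    def _read_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            end = s.index("'", pos + 1)
            label = s[pos + 1:end]
            pos = end + 1
            return label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        return s[start:pos].strip()

    root, root_len = parse_clade()
    if pos != len(s):
        raise TreeError(f"trailing characters in Newick string at position {pos}")
    if root_len:
        raise TreeError("branch length on the root is not meaningful")
    if len(set(tree.labels.values())) != len(tree.labels):
        raise TreeError("duplicate taxon labels in Newick string")
    # Unroot: suppress a degree-2 root.
    if root not in tree.labels and tree.degree(root) == 2:
        tree.smooth(root)
    return tree


def _fmt_len(length: float) -> str:
    # repr gives the shortest digit string that round-trips the float exactly
    return repr(float(length))


def write_newick(tree: Tree, support: dict[frozenset[str], float] | None = None) -> str:
    """Serialize a tree to Newick (one line, with branch lengths).

    ``support`` maps canonical splits to values written as internal-node
    labels, the convention used for consensus output.
    """
    if tree.n_leaves < 2:
        raise TreeError("cannot serialize a tree with fewer than 2 leaves")
    taxa = tree.taxa
    if tree.root is not None and tree.root in tree.adj:
        start = tree.root
    else:
        anchor_leaf = tree.leaf_by_label(min(taxa))
        start = next(iter(tree.adj[anchor_leaf]))

    def render(node: int, parent: int | None) -> str:
        children = [nb for nb in tree.adj[node] if nb != parent]
        if not children:
            label = tree.labels[node]
            if any(c.isspace() for c in label):
                label = f"'{label}'"
            out = label
        else:
            inner = ",".join(
                render(child, node) + f":{_fmt_len(tree.adj[node][child])}"
                for child in children
            )
            out = f"({inner})"
            if support is not None and parent is not None:
                side = tree.side_taxa(parent, node)
                if 2 <= len(side) <= len(taxa) - 2:
                    key = canonical_split(side, taxa)
                    if key in support:
                        out += f"{support[key]:.4g}"
        return out

    return render(start, None) + ";"


# -------------------------------------------------------------- consensus


@dataclass
class ConsensusTree:
    """Majority-rule consensus with branch support values.

    ``support`` covers the splits retained in the topology; ``split_support``
    records Φ for *every* split observed in the inputs (needed by the MRE
    convergence statistic, which sums over observed bipartitions).
    """

    tree: Tree
    support: dict[frozenset[str], float]
    split_support: dict[frozenset[str], float]
    n_inputs: int = 0

    @property
    def taxa(self) -> frozenset[str]:
        return self.tree.taxa


def _compatible(a: frozenset[str], b: frozenset[str], taxa: frozenset[str]) -> bool:
    return (
        not (a & b)
        or a <= b
        or b <= a
        or a | b == taxa
    )


def majority_consensus(trees: list[Tree], include_all: bool = False) -> ConsensusTree:
    """Majority-rule consensus; Φ values are occurrence fractions.

    Branch lengths are averaged over the trees containing the branch
    (pendant lengths over all trees).  With ``include_all``, sub-majority
    splits compatible with the growing set are greedily added in decreasing
    support order (ties broken deterministically).
    """
    if not trees:
        raise TreeError("consensus of an empty tree list")
    taxa = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != taxa:
            raise TreeError("trees have different taxon sets")
    n = len(trees)

    counts: Counter = Counter()
    length_sums: dict[frozenset[str], float] = {}
    pendant_sums = {taxon: 0.0 for taxon in taxa}
    for t in trees:
        mapping = split_to_edge(t)
        for split, (u, v) in mapping.items():
            counts[split] += 1
            length_sums[split] = length_sums.get(split, 0.0) + t.length(u, v)
        for leaf in t.leaves():
            pendant_sums[t.labels[leaf]] += t.length(leaf, next(iter(t.adj[leaf])))

    split_support = {s: c / n for s, c in counts.items()}
    ordered = sorted(
        split_support,
        key=lambda s: (-split_support[s], len(s), tuple(sorted(s))),
    )
    retained: list[frozenset[str]] = []
    for split in ordered:
        if split_support[split] > 0.5:
            retained.append(split)
        elif include_all and all(_compatible(split, r, taxa) for r in retained):
            retained.append(split)

    avg_lengths = {s: length_sums[s] / counts[s] for s in retained}
    avg_pendant = {taxon: total / n for taxon, total in pendant_sums.items()}
    tree = _tree_from_splits(taxa, retained, avg_lengths, avg_pendant)
    support = {s: split_support[s] for s in retained}
    return ConsensusTree(tree, support, split_support, n_inputs=n)


def _tree_from_splits(
    taxa: frozenset[str],
    splits: list[frozenset[str]],
    lengths: dict[frozenset[str], float],
    pendant: dict[str, float],
) -> Tree:
    """Build the (possibly multifurcating) tree displaying a compatible split set."""
    anchor = min(taxa)
    # Canonical splits never contain the anchor: each is a clade of the
    # tree rooted on the anchor's pendant edge.
    clades = sorted(set(splits), key=len, reverse=True)
    tree = Tree()
    root = tree.new_node()
    clade_node: dict[frozenset[str], int] = {}

    def parent_of(item: frozenset[str] | str) -> int:
        members = item if isinstance(item, frozenset) else frozenset([item])
        best: frozenset[str] | None = None
        for clade in clades:
            if members < clade or (isinstance(item, str) and members <= clade):
                if best is None or len(clade) < len(best):
                    best = clade
        return clade_node[best] if best is not None else root

    for clade in clades:
        node = tree.new_node()
        clade_node[clade] = node
    for clade in clades:
        tree.connect(parent_of(clade), clade_node[clade], lengths.get(clade, 0.0))
    for taxon in sorted(taxa):
        leaf = tree.new_node(taxon)
        target = root if taxon == anchor else parent_of(taxon)
        tree.connect(target, leaf, pendant.get(taxon, 0.0))
    if tree.degree(root) == 2:
        tree.smooth(root)
    return tree


# -------------------------------------------------------------- generators


def random_tree(
    taxa: list[str],
    rng: np.random.Generator,
    branch_length_mean: float = 0.1,
) -> Tree:
    """Uniform random unrooted binary topology via sequential leaf insertion,
    with i.i.d. exponential branch lengths (mean ``branch_length_mean``)."""
    if len(taxa) < 4:
        raise TreeError("need at least 4 taxa")
    if len(set(taxa)) != len(taxa):
        raise TreeError("duplicate taxon labels")
    tree = Tree()
    center = tree.new_node()
    for label in taxa[:3]:
        tree.connect(center, tree.new_node(label), 1.0)
    for label in taxa[3:]:
        edges = sorted((u, v) for u, v, _ in tree.edges())
        u, v = edges[int(rng.integers(len(edges)))]
        mid = tree.insert_on_edge(u, v)
        tree.connect(mid, tree.new_node(label), 1.0)
    for u, v, _ in list(tree.edges()):
        tree.set_length(u, v, float(rng.exponential(branch_length_mean)))
    return tree


def _check_distance_matrix(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise TreeError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise TreeError("distance matrix must be symmetric")
    if np.any(np.diag(dist) != 0):
        raise TreeError("distance matrix must have a zero diagonal")
    return dist


def _agglomerate(dist: np.ndarray, labels: list[str], pick) -> Tree:
    """Shared NJ/LNJ agglomeration.  ``pick(ranked_pairs, m)`` chooses the
    joined pair from candidate pairs ranked by the Saitou–Nei criterion
    (ties broken by lowest (row, column) index)."""
    dist = _check_distance_matrix(dist)
    m = len(labels)
    if m < 4:
        raise TreeError("need at least 4 taxa")
    tree = Tree()
    active = [tree.new_node(lab) for lab in labels]
    D = dist.copy()

    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=1)
        ranked = sorted(
            ((float((m - 2) * D[i, j] - r[i] - r[j]), i, j)
             for i in range(m) for j in range(i + 1, m)),
        )
        _, i, j = ranked[pick(ranked, m)]
        vi = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = D[i, j] - vi
        vi, vj = _clamp_pair(vi, vj)
        node = tree.new_node()
        tree.connect(node, active[i], vi)
        tree.connect(node, active[j], vj)
        new_row = np.array([
            (D[i, k] + D[j, k] - D[i, j]) / 2.0 for k in range(m) if k not in (i, j)
        ])
        keep = [k for k in range(m) if k not in (i, j)]
        D = D[np.ix_(keep, keep)]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row
        D[:-1, -1] = new_row
        active = [active[k] for k in keep] + [node]

    # Resolve the final three clusters around a central node.
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    center = tree.new_node()
    v0 = (d01 + d02 - d12) / 2.0
    v1 = (d01 + d12 - d02) / 2.0
    v2 = (d02 + d12 - d01) / 2.0
    for node, v in zip(active, (v0, v1, v2)):
        tree.connect(center, node, max(v, 0.0))
    return tree


def _clamp_pair(vi: float, vj: float) -> tuple[float, float]:
    """Clamp negative NJ length estimates to 0, moving the deficit to the
    sister branch so the path length is preserved where possible."""
    if vi < 0:
        logger.debug("negative NJ branch length %.4g clamped", vi)
        vj = max(vj + vi, 0.0)
        vi = 0.0
    if vj < 0:
        logger.debug("negative NJ branch length %.4g clamped", vj)
        vi = max(vi + vj, 0.0)
        vj = 0.0
    return vi, vj


def nj_tree(dist: np.ndarray, labels: list[str]) -> Tree:
    """Saitou–Nei neighbor joining; exact on additive matrices."""
    return _agglomerate(dist, labels, lambda ranked, m: 0)


def lnj_tree(
    dist: np.ndarray,
    labels: list[str],
    p: float,
    rng: np.random.Generator,
) -> Tree:
    """Loose neighbor joining: at each agglomeration step the joined pair is
    drawn uniformly from the ``ceil(m(m-1)p/2)`` best candidate pairs under
    the NJ criterion (minimum list size 1), where m is the current cluster
    count.  ``p = 0`` reproduces :func:`nj_tree` exactly; ``p = 1`` draws
    from all pairs."""
    if not 0.0 <= p <= 1.0:
        raise TreeError("p must lie in [0, 1]")

    def pick(ranked, m):
        size = max(1, math.ceil(m * (m - 1) * p / 2.0))
        size = min(size, len(ranked))
        return int(rng.integers(size))

    return _agglomerate(dist, labels, pick)


# ---------------------------------------------------------- model distances


def model_distance_matrix(alignment, model, cap: float = 10.0) -> np.ndarray:
    """Pairwise maximum-likelihood distances under ``model``.

    Each pair's distance maximizes the pairwise likelihood numerically
    (including any Pinv/Γ rate mixture).  Columns where either sequence has
    an ambiguity code or a gap are skipped for that pair.  Saturated pairs
    are capped at ``cap`` and logged.  Under JC the numerical optimum
    coincides with the closed form −(3/4)·ln(1 − (4/3)·p̂).
    """
    from scipy.optimize import minimize_scalar
    from .alignment import STATE_ORDER
    from .models import TransitionCalculator, site_rate_mixture

    calc = TransitionCalculator(model)
    mixture = site_rate_mixture(model)
    pi = model.frequencies
    ntax = alignment.n_tax
    D = np.zeros((ntax, ntax))
    state_idx = {c: i for i, c in enumerate(STATE_ORDER)}

    for a in range(ntax):
        for b in range(a + 1, ntax):
            sa = alignment.sequences[alignment.taxa[a]]
            sb = alignment.sequences[alignment.taxa[b]]
            counts = np.zeros((4, 4))
            for ca, cb in zip(sa, sb):
                ia, ib = state_idx.get(ca), state_idx.get(cb)
                if ia is not None and ib is not None:
                    counts[ia, ib] += 1
            if counts.sum() == 0 or counts.sum() == np.trace(counts):
                D[a, b] = D[b, a] = 0.0
                continue

            def neg_lnl(d):
                P = np.zeros((4, 4))
                for rate, weight in mixture:
                    P += weight * calc.probabilities(d * rate)
                with np.errstate(divide="ignore"):
                    logs = np.log(np.maximum(pi[:, None] * P, 1e-300))
                return -float((counts * logs).sum())

            res = minimize_scalar(neg_lnl, bounds=(1e-9, cap), method="bounded",
                                  options={"xatol": 1e-8})
            d = float(res.x)
            if d > cap * 0.999:
                logger.warning("saturated pair (%s, %s): distance capped at %g",
                               alignment.taxa[a], alignment.taxa[b], cap)
                d = cap
            D[a, b] = D[b, a] = d
    return D


# -------------------------------------------------------------- rerooting


def reroot(tree: Tree, edge: tuple[int, int]) -> Tree:
    """Return a copy rooted on ``edge`` (display-level only).

    The bipartition set is unchanged: the inserted degree-2 root realizes
    the same split as the original edge."""
    u, v = edge
    if v not in tree.adj.get(u, {}):
        raise TreeError(f"no edge {u}-{v} in tree")
    out = tree.copy()
    out.root = out.insert_on_edge(u, v)
    return out
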