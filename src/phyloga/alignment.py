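"""Nucleotide alignments, character sets, partitions, and site-pattern compression.

Sequences are strings over the IUPAC nucleotide alphabet plus the gap symbol
``-``.  Ambiguity codes and gaps are treated as partial-information states in
likelihood computation: a gap (or ``?``/``N``) carries no information and is
equivalent to "any base".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IUPAC_MASKS",
    "STATE_ORDER",
    "Alignment",
    "CharSet",
    "PartitionScheme",
    "SitePatternTable",
    "compress_patterns",
]

# Bit masks over the state order (A, C, G, T).
STATE_ORDER = "ACGT"
_A, _C, _G, _T = 1, 2, 4, 8
IUPAC_MASKS: dict[str, int] = {
    "A": _A, "C": _C, "G": _G, "T": _T, "U": _T,
    "R": _A | _G, "Y": _C | _T, "S": _C | _G, "W": _A | _T,
    "K": _G | _T, "M": _A | _C,
    "B": _C | _G | _T, "D": _A | _G | _T, "H": _A | _C | _T, "V": _A | _C | _G,
    "N": 15, "X": 15, "?": 15, "-": 15,
}


class AlignmentError(ValueError):
    """Raised for invalid alignments, charsets, or partitions."""


@dataclass
class Alignment:
    """A taxa-by-sites nucleotide alignment.

    Parameters
    ----------
    taxa:
        Ordered, unique taxon labels.
    sequences:
        Mapping taxon label -> sequence string; all equal length.
    """

    taxa: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dupes = {t for t in self.taxa if self.taxa.count(t) > 1}
            raise AlignmentError(f"duplicate taxon labels: {sorted(dupes)}")
        if set(self.taxa) != set(self.sequences):
            raise AlignmentError("taxa list and sequence keys differ")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise AlignmentError(f"sequences of unequal length: {sorted(lengths)}")
        for taxon in self.taxa:
            seq = self.sequences[taxon].upper()
            bad = set(seq) - set(IUPAC_MASKS)
            if bad:
                raise AlignmentError(f"invalid symbols in sequence {taxon!r}: {sorted(bad)}")
            self.sequences[taxon] = seq

    @property
    def n_tax(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def column(self, site: int) -> str:
        """Return the alignment column at 1-based position ``site``."""
        return "".join(self.sequences[t][site - 1] for t in self.taxa)

    def encoded(self) -> np.ndarray:
        """(n_tax, n_sites) array of IUPAC bit masks, taxa in ``self.taxa`` order."""
        out = np.empty((self.n_tax, self.n_sites), dtype=np.uint8)
        for i, taxon in enumerate(self.taxa):
            out[i] = [IUPAC_MASKS[c] for c in self.sequences[taxon]]
        return out

    def base_frequencies(self, sites: "CharSet | None" = None) -> np.ndarray:
        """Empirical A,C,G,T frequencies (unambiguous symbols only).

        Fully or partially ambiguous symbols are ignored; falls back to
        uniform frequencies if no unambiguous base is present.
        """
        counts = np.zeros(4)
        positions = sorted(sites.sites) if sites is not None else range(1, self.n_sites + 1)
        for taxon in self.taxa:
            seq = self.sequences[taxon]
            for pos in positions:
                idx = STATE_ORDER.find(seq[pos - 1])
                if idx >= 0:
                    counts[idx] += 1
        if counts.sum() == 0:
            return np.full(4, 0.25)
        return counts / counts.sum()


@dataclass(frozen=True)
class CharSet:
    """A named set of 1-based alignment positions."""

    name: str
    sites: frozenset[int]

    def __post_init__(self) -> None:
        if not self.sites:
            raise AlignmentError(f"charset {self.name!r} is empty")
        if min(self.sites) < 1:
            raise AlignmentError(f"charset {self.name!r} has positions < 1")

    def validate_against(self, alignment: Alignment) -> None:
        if max(self.sites) > alignment.n_sites:
            raise AlignmentError(
                f"charset {self.name!r} references site {max(self.sites)} "
                f"but alignment has {alignment.n_sites} sites"
            )

    @property
    def size(self) -> int:
        return len(self.sites)

    @staticmethod
    def from_spec(name: str, spec: str, n_sites: int | None = None) -> "CharSet":
        """Parse a Nexus-style site list: ``1-4 9 12-20\\3 30-.``"""
        sites: set[int] = set()
        for token in spec.replace(",", " ").split():
            step = 1
            if "\\" in token:
                token, step_s = token.split("\\", 1)
                step = int(step_s)
            if "-" in token:
                lo_s, hi_s = token.split("-", 1)
                lo = int(lo_s)
                if hi_s in (".", ""):
                    if n_sites is None:
                        raise AlignmentError("open-ended range needs a known alignment length")
                    hi = n_sites
                else:
                    hi = int(hi_s)
                sites.update(range(lo, hi + 1, step))
            else:
                sites.add(int(token))
        return CharSet(name, frozenset(sites))


@dataclass
class PartitionScheme:
    """Disjoint charsets analysed on a shared topology, with relative rates.

    The per-partition relative rates scale branch lengths for that partition;
    they are constrained so their site-count-weighted average equals 1, which
    keeps overall branch lengths interpretable as expected substitutions/site.
    """

    partitions: list[CharSet]
    relative_rates: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.partitions:
            raise AlignmentError("partition scheme needs at least one partition")
        seen: set[int] = set()
        for cs in self.partitions:
            if seen & cs.sites:
                raise AlignmentError(f"partition {cs.name!r} overlaps a previous partition")
            seen |= cs.sites
        if not self.relative_rates:
            self.relative_rates = [1.0] * len(self.partitions)
        if len(self.relative_rates) != len(self.partitions):
            raise AlignmentError("one relative rate required per partition")
        if any(r <= 0 for r in self.relative_rates):
            raise AlignmentError("relative rates must be positive")
        self.relative_rates = list(self.normalized_rates(self.relative_rates))

    @property
    def sizes(self) -> list[int]:
        return [cs.size for cs in self.partitions]

    def normalized_rates(self, rates) -> np.ndarray:
        """Rescale ``rates`` so the size-weighted mean equals 1."""
        rates = np.asarray(rates, dtype=float)
        weights = np.asarray(self.sizes, dtype=float)
        mean = float((rates * weights).sum() / weights.sum())
        return rates / mean

    def check_weighted_mean(self, tol: float = 1e-9) -> None:
        weights = np.asarray(self.sizes, dtype=float)
        mean = float((np.asarray(self.relative_rates) * weights).sum() / weights.sum())
        if abs(mean - 1.0) > tol:
            raise AlignmentError(f"weighted mean of partition rates is {mean}, not 1")

    @staticmethod
    def single(alignment: Alignment) -> "PartitionScheme":
        """The trivial one-partition scheme covering every site."""
        cs = CharSet("all", frozenset(range(1, alignment.n_sites + 1)))
        return PartitionScheme([cs])


@dataclass
class SitePatternTable:
    """Unique site columns of one partition, with multiplicities.

    ``patterns`` is an (n_tax, n_patterns) array of IUPAC bit masks; column
    order follows first occurrence in the partition's sorted site list.
    """

    patterns: np.ndarray
    weights: np.ndarray
    site_to_pattern: dict[int, int]   # 1-based site -> pattern column
    taxa: list[str]

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    def expand_columns(self) -> np.ndarray:
        """Reconstruct the (n_tax, n_sites) mask matrix in site order."""
        sites = sorted(self.site_to_pattern)
        idx = [self.site_to_pattern[s] for s in sites]
        return self.patterns[:, idx]


def compress_patterns(alignment: Alignment, partition: CharSet | None = None) -> SitePatternTable:
    """Collapse identical columns of one partition into weighted patterns."""
    if partition is None:
        partition = CharSet("all", frozenset(range(1, alignment.n_sites + 1)))
    partition.validate_against(alignment)
    encoded = alignment.encoded()
    sites = sorted(partition.sites)
    index: dict[bytes, int] = {}
    cols: list[np.ndarray] = []
    weights: list[int] = []
    site_to_pattern: dict[int, int] = {}
    for site in sites:
        col = encoded[:, site - 1]
        key = col.tobytes()
        if key not in index:
            index[key] = len(cols)
            cols.append(col)
            weights.append(0)
        weights[index[key]] += 1
        site_to_pattern[site] = index[key]
    patterns = np.stack(cols, axis=1)
    return SitePatternTable(patterns, np.asarray(weights), site_to_pattern, list(alignment.taxa))
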