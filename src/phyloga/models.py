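"""Nucleotide substitution models and rate heterogeneity.

Five time-reversible models are supported — JC, K2P, HKY85, TN93, GTR —
optionally combined with a proportion of invariant sites (Pinv) and/or a
discrete Gamma distribution of among-site rates.  Every rate matrix Q is
scaled to an expected substitution rate of 1, so branch lengths are
expected substitutions per site.

State order is A, C, G, T throughout.  Transitions are A<->G and C<->T.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special, stats

__all__ = [
    "SubstitutionModel",
    "ModelError",
    "build_Q",
    "TransitionCalculator",
    "discretize_gamma",
    "site_rate_mixture",
    "aic",
    "bic",
    "likelihood_ratio_test",
    "free_parameter_count",
    "NESTED_PATH",
]

FAMILIES = ("JC", "K2P", "HKY85", "TN93", "GTR")
# Exchangeability order for GTR: (AC, AG, AT, CG, CT, GT); GT is the
# reference rate fixed to 1.
EXCHANGE_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


class ModelError(ValueError):
    pass


@dataclass
class SubstitutionModel:
    """A reversible nucleotide model plus optional rate heterogeneity.

    Parameters
    ----------
    family:
        One of JC, K2P, HKY85, TN93, GTR.
    frequencies:
        Stationary base frequencies (A, C, G, T); forced uniform for JC/K2P.
    kappa:
        Transition/transversion rate ratio (K2P, HKY85).
    kappa1, kappa2:
        Purine (A<->G) and pyrimidine (C<->T) transition ratios (TN93).
    exchangeabilities:
        The six GTR rates in order (AC, AG, AT, CG, CT, GT); GT acts as the
        reference and is rescaled to 1.
    pinv:
        Proportion of invariant sites in [0, 1).
    alpha:
        Gamma shape; ``None`` disables Gamma rates.
    n_categories:
        Number of discrete Gamma categories (k).
    """

    family: str = "JC"
    frequencies: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    kappa: float = 2.0
    kappa1: float = 2.0
    kappa2: float = 2.0
    exchangeabilities: np.ndarray = field(default_factory=lambda: np.ones(6))
    pinv: float = 0.0
    alpha: float | None = None
    n_categories: int = 4

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ModelError(f"unknown model family {self.family!r}")
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.family in ("JC", "K2P"):
            self.frequencies = np.full(4, 0.25)
        if self.frequencies.shape != (4,):
            raise ModelError("frequencies must be a 4-vector")
        if abs(self.frequencies.sum() - 1.0) > 1e-6:
            raise ModelError(f"frequencies sum to {self.frequencies.sum()}, not 1")
        if np.any(self.frequencies <= 0):
            raise ModelError("frequencies must be positive")
        self.frequencies = self.frequencies / self.frequencies.sum()
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        if self.exchangeabilities.shape != (6,):
            raise ModelError("exchangeabilities must be a 6-vector")
        if np.any(self.exchangeabilities <= 0):
            raise ModelError("exchangeabilities must be positive")
        # GT is the reference rate.
        self.exchangeabilities = self.exchangeabilities / self.exchangeabilities[5]
        for name in ("kappa", "kappa1", "kappa2"):
            if getattr(self, name) <= 0:
                raise ModelError(f"{name} must be positive")
        if not 0.0 <= self.pinv < 1.0:
            raise ModelError("pinv must lie in [0, 1)")
        if self.alpha is not None and self.alpha <= 0:
            raise ModelError("alpha must be positive")
        if self.n_categories < 1:
            raise ModelError("need at least one rate category")

    @property
    def has_gamma(self) -> bool:
        return self.alpha is not None

    def with_updates(self, **kwargs) -> "SubstitutionModel":
        return replace(self, **kwargs)

    def effective_exchangeabilities(self) -> np.ndarray:
        """The 6 exchange rates implied by the family's parameterization."""
        if self.family == "JC":
            return np.ones(6)
        if self.family in ("K2P", "HKY85"):
            k = self.kappa
            return np.array([1.0, k, 1.0, 1.0, k, 1.0])
        if self.family == "TN93":
            return np.array([1.0, self.kappa1, 1.0, 1.0, self.kappa2, 1.0])
        return self.exchangeabilities.copy()


def build_Q(model: SubstitutionModel) -> np.ndarray:
    """The reversible rate matrix, scaled to unit expected rate.

    Q_ij = s_ij * pi_j for i != j; rows sum to zero; detailed balance
    pi_i Q_ij = pi_j Q_ji holds by construction.
    """
    s = model.effective_exchangeabilities()
    pi = model.frequencies
    Q = np.zeros((4, 4))
    for rate, (i, j) in zip(s, EXCHANGE_PAIRS):
        Q[i, j] = rate * pi[j]
        Q[j, i] = rate * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(Q)))
    if mu <= 0:
        raise ModelError("degenerate rate matrix")
    return Q / mu


class TransitionCalculator:
    """Eigendecomposition-backed P(t) = exp(Qt) for one model.

    Q is symmetrized through diag(sqrt(pi)) so the decomposition is of a
    real symmetric matrix (guaranteed real eigenvalues, stable)."""

    def __init__(self, model: SubstitutionModel):
        self.model = model
        self.Q = build_Q(model)
        pi = model.frequencies
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
        B = (B + B.T) / 2.0  # symmetrize numerically
        eigvals, U = np.linalg.eigh(B)
        self._eigvals = eigvals
        self._left = U / sqrt_pi[:, None]          # diag(1/sqrt(pi)) @ U
        self._right = (U * sqrt_pi[:, None]).T     # U.T @ diag(sqrt(pi))

    def probabilities(self, t: float) -> np.ndarray:
        """The 4x4 stochastic matrix P(t); requires t >= 0."""
        if t < 0:
            raise ModelError(f"negative evolutionary time {t}")
        P = (self._left * np.exp(self._eigvals * t)) @ self._right
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def probability_stack(self, times: np.ndarray) -> np.ndarray:
        """P(t) for a vector of times; returns shape (len(times), 4, 4)."""
        times = np.asarray(times, dtype=float)
        if np.any(times < 0):
            raise ModelError("negative evolutionary time")
        expo = np.exp(np.outer(times, self._eigvals))          # (n, 4)
        P = np.einsum("ik,nk,kj->nij", self._left, expo, self._right)
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


def discretize_gamma(alpha: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability slices of Gamma(alpha, alpha).

    The category rates are the conditional means of each slice (the
    mean-of-bins construction), so they average exactly to 1.
    """
    if alpha <= 0:
        raise ModelError("alpha must be positive")
    if k < 1:
        raise ModelError("need at least one category")
    if k == 1:
        return np.ones(1)
    # Slice boundaries in rate space (rate parameterization: scale = 1/alpha).
    bounds = stats.gamma.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    # Mean over [a, b) of Gamma(alpha, alpha) = k * (F_{alpha+1}(b) - F_{alpha+1}(a))
    # where F is the CDF of Gamma(alpha+1, alpha) (since the distribution mean is 1).
    upper = special.gammainc(alpha + 1.0, alpha * bounds[1:])
    lower = special.gammainc(alpha + 1.0, alpha * bounds[:-1])
    rates = k * (upper - lower)
    rates = np.maximum(rates, 1e-12)
    return rates / rates.mean()


def site_rate_mixture(model: SubstitutionModel) -> list[tuple[float, float]]:
    """The per-site (rate, weight) mixture implied by Pinv and/or Gamma.

    Variable-site rates are scaled by 1/(1 - Pinv) so the expected rate is
    exactly 1, keeping branch lengths in substitutions/site.
    """
    pinv = model.pinv
    if model.has_gamma:
        rates = discretize_gamma(model.alpha, model.n_categories)
    else:
        rates = np.ones(1)
    k = len(rates)
    mixture: list[tuple[float, float]] = []
    if pinv > 0:
        mixture.append((0.0, pinv))
    scale = 1.0 / (1.0 - pinv)
    mixture.extend((float(r * scale), (1.0 - pinv) / k) for r in rates)
    return mixture


# ------------------------------------------------------------ model choice


def aic(lnl: float, n_params: int) -> float:
    """Akaike information criterion: -2 lnL + 2K."""
    return -2.0 * lnl + 2.0 * n_params


def bic(lnl: float, n_params: int, n_sites: int) -> float:
    """Bayesian information criterion: -2 lnL + K ln(n)."""
    if n_sites < 1:
        raise ModelError("BIC needs a positive sample size")
    return -2.0 * lnl + n_params * np.log(n_sites)


# Model descriptions are (family, pinv?, gamma?).  The LRT walks the
# exchangeability ladder first, then tests +Gamma, then +Pinv.
NESTED_PATH = ("JC", "K2P", "HKY85", "TN93", "GTR")


def _nesting_rank(family: str) -> int:
    return NESTED_PATH.index(family)


def is_nested(simple: "ModelSpec", complex_: "ModelSpec") -> bool:
    fam_ok = _nesting_rank(simple.family) <= _nesting_rank(complex_.family)
    het_ok = (simple.pinv <= complex_.pinv) and (simple.gamma <= complex_.gamma)
    return fam_ok and het_ok and (simple != complex_)


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: family plus heterogeneity flags."""

    family: str
    pinv: bool = False
    gamma: bool = False

    @property
    def name(self) -> str:
        suffix = ("+I" if self.pinv else "") + ("+G" if self.gamma else "")
        return self.family + suffix


def free_parameter_count(spec: ModelSpec, n_taxa: int, n_partitions: int = 1) -> int:
    """K for AIC/BIC: branch lengths plus free model parameters.

    Per partition: base frequencies (3, except JC/K2P which fix them
    uniform), exchange parameters (K2P/HKY85: 1; TN93: 2; GTR: 5), +1 for
    Pinv, +1 for the Gamma shape.  Among-partition relative rates add
    n_partitions - 1.  Branch lengths add 2*n_taxa - 3 (shared topology).
    """
    per_partition = {"JC": 0, "K2P": 1, "HKY85": 4, "TN93": 5, "GTR": 8}[spec.family]
    per_partition += int(spec.pinv) + int(spec.gamma)
    return (2 * n_taxa - 3) + n_partitions * per_partition + (n_partitions - 1)


def likelihood_ratio_test(
    lnl_simple: float,
    lnl_complex: float,
    df_delta: int,
    alpha: float = 0.05,
) -> bool:
    """True when the complex model is preferred at level ``alpha``.

    The statistic 2(lnL1 - lnL0) is compared with the chi-square upper
    quantile on ``df_delta`` degrees of freedom.
    """
    if df_delta < 1:
        raise ModelError("models must differ in at least one parameter")
    if lnl_complex < lnl_simple - 1e-6:
        raise ModelError(
            f"complex model lnL {lnl_complex} below simple model lnL {lnl_simple}: "
            "models are not nested or optimization failed"
        )
    statistic = max(2.0 * (lnl_complex - lnl_simple), 0.0)
    critical = stats.chi2.ppf(1.0 - alpha, df=df_delta)
    return bool(statistic > critical)
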