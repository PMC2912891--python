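"""Model parameter estimation on a fixed tree and model selection.

Candidate models are scored on the neighbor-joining topology with branch
lengths and free model parameters numerically optimized, following the
usual practice of selecting a substitution model on a fixed reasonable
tree before the full search.  Selection supports the likelihood ratio
test (nested path JC -> K2P -> HKY85 -> TN93 -> GTR, then +Gamma, then
+Pinv), AIC, and BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, CharSet
from .likelihood import LikelihoodEngine, optimize_parameters
from .models import (
    ModelError,
    ModelSpec,
    SubstitutionModel,
    aic,
    bic,
    free_parameter_count,
    is_nested,
    likelihood_ratio_test,
)
from .trees import Tree, model_distance_matrix, nj_tree

__all__ = [
    "estimate_initial_parameters",
    "fit_on_tree",
    "ModelFit",
    "ModelSelectionResult",
    "select_model",
    "DEFAULT_CANDIDATES",
]

DEFAULT_CANDIDATES = tuple(
    ModelSpec(family, pinv, gamma)
    for family in ("JC", "K2P", "HKY85", "TN93", "GTR")
    for pinv in (False, True)
    for gamma in (False, True)
)


def _empirical_kappa(alignment: Alignment) -> float:
    """Moment-style starting value for the ts/tv rate ratio from pairwise
    mismatch counts (2 * transitions / transversions; 1 under equal rates)."""
    transitions = {frozenset("AG"), frozenset("CT")}
    ts = tv = 0
    taxa = alignment.taxa
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            for a, b in zip(alignment.sequences[taxa[i]], alignment.sequences[taxa[j]]):
                if a != b and a in "ACGT" and b in "ACGT":
                    if frozenset((a, b)) in transitions:
                        ts += 1
                    else:
                        tv += 1
    if tv == 0:
        return 4.0
    return float(np.clip(2.0 * ts / tv, 0.2, 40.0))


def _instantiate(spec: ModelSpec, alignment: Alignment,
                 partition: CharSet | None = None) -> SubstitutionModel:
    kappa = _empirical_kappa(alignment)
    exch = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
    return SubstitutionModel(
        family=spec.family,
        frequencies=alignment.base_frequencies(partition),
        kappa=kappa,
        kappa1=kappa,
        kappa2=kappa,
        exchangeabilities=exch,
        pinv=0.1 if spec.pinv else 0.0,
        alpha=0.5 if spec.gamma else None,
    )


def _fit_targets(spec: ModelSpec) -> tuple[str, ...]:
    targets = ["branch_lengths"]
    if spec.family != "JC":
        targets.append("rate_matrix")
    if spec.gamma:
        targets.append("gamma_shape")
    if spec.pinv:
        targets.append("pinv")
    return tuple(targets)


@dataclass
class ModelFit:
    spec: ModelSpec
    model: SubstitutionModel
    lnl: float
    n_params: int
    aic: float
    bic: float
    tree: Tree


def fit_on_tree(alignment: Alignment, spec: ModelSpec, tree: Tree,
                max_cycles: int = 2) -> ModelFit:
    """Optimize one candidate model (and branch lengths) on a fixed topology."""
    model = _instantiate(spec, alignment)
    engine = LikelihoodEngine(alignment, model)
    work = tree.copy()
    value = optimize_parameters(work, engine, targets=_fit_targets(spec),
                                max_cycles=max_cycles)
    k = free_parameter_count(spec, alignment.n_tax)
    return ModelFit(spec, engine.models[0], value.total, k,
                    aic(value.total, k), bic(value.total, k, alignment.n_sites),
                    work)


def estimate_initial_parameters(alignment: Alignment,
                                spec: ModelSpec | None = None,
                                partition: CharSet | None = None) -> SubstitutionModel:
    """Estimate starting model parameters from the NJ tree.

    Base frequencies come from the empirical counts; rate parameters,
    Gamma shape and Pinv are optimized numerically on the JC-distance NJ
    topology."""
    if spec is None:
        spec = ModelSpec("HKY85")
    if partition is not None:
        sub = Alignment(alignment.taxa, {
            t: "".join(alignment.sequences[t][s - 1] for s in sorted(partition.sites))
            for t in alignment.taxa})
        alignment = sub
    start = SubstitutionModel(family="JC")
    dist = model_distance_matrix(alignment, start)
    tree = nj_tree(dist, list(alignment.taxa))
    try:
        return fit_on_tree(alignment, spec, tree).model
    except Exception:  # optimizer failure: fall back to defaults
        return _instantiate(spec, alignment, partition=None)


@dataclass
class ModelSelectionResult:
    """Per-candidate scores and the winner under the chosen criterion."""

    criterion: str
    fits: list[ModelFit]
    chosen: ModelFit
    lrt_path: list[tuple[str, str, bool]] = field(default_factory=list)

    def table(self) -> str:
        """Tab-separated report: model, lnL, K, AIC, BIC, selected flag."""
        lines = ["model\tlnL\tK\tAIC\tBIC\tselected"]
        for fit in self.fits:
            flag = "*" if fit.spec == self.chosen.spec else ""
            lines.append(f"{fit.spec.name}\t{fit.lnl:.4f}\t{fit.n_params}"
                         f"\t{fit.aic:.4f}\t{fit.bic:.4f}\t{flag}")
        return "\n".join(lines)


def select_model(alignment: Alignment,
                 candidates=DEFAULT_CANDIDATES,
                 criterion: str = "BIC",
                 tree: Tree | None = None,
                 alpha: float = 0.05) -> ModelSelectionResult:
    """Choose the best-fitting candidate on a fixed NJ tree.

    AIC/BIC pick the minimum score (ties broken toward fewer parameters);
    the LRT climbs the nested path, keeping the simpler model unless the
    complex one is significantly better at level ``alpha``."""
    criterion = criterion.upper()
    if criterion not in ("LRT", "AIC", "BIC"):
        raise ModelError(f"unknown criterion {criterion!r}")
    candidates = list(candidates)
    if not candidates:
        raise ModelError("no candidate models")
    if tree is None:
        dist = model_distance_matrix(alignment, SubstitutionModel(family="JC"))
        tree = nj_tree(dist, list(alignment.taxa))
    fits = [fit_on_tree(alignment, spec, tree) for spec in candidates]

    if len(fits) == 1:
        return ModelSelectionResult(criterion, fits, fits[0])

    if criterion in ("AIC", "BIC"):
        key = (lambda f: (f.aic, f.n_params)) if criterion == "AIC" else \
              (lambda f: (f.bic, f.n_params))
        chosen = min(fits, key=key)
        return ModelSelectionResult(criterion, fits, chosen)

    # LRT: walk from the simplest candidate towards more complex nested ones.
    order = sorted(fits, key=lambda f: f.n_params)
    current = order[0]
    path: list[tuple[str, str, bool]] = []
    for fit in order[1:]:
        if not is_nested(current.spec, fit.spec):
            continue
        df = fit.n_params - current.n_params
        prefer = likelihood_ratio_test(current.lnl, max(fit.lnl, current.lnl),
                                       df, alpha=alpha)
        path.append((current.spec.name, fit.spec.name, prefer))
        if prefer:
            current = fit
    return ModelSelectionResult(criterion, fits, current, lrt_path=path)
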