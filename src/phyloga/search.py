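"""The four search heuristics: hill climbing, simulated annealing, a
classical genetic algorithm, and the metapopulation genetic algorithm
(metaGA) with consensus pruning.

All heuristics share the starting-tree generators, the operator set, the
likelihood engine, and the stopping rules.  Runs are deterministic given
the master seed: every population draws from its own RNG stream seeded by
(master seed, population index), so the declared worker count (a
performance knob) can never change results.
"""

from __future__ import annotations

import time
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, PartitionScheme
from .convergence import MreStopper, likelihood_stability_stop
from .likelihood import LikelihoodEngine, optimize_parameters
from .models import SubstitutionModel
from .operators import (
    OperatorError,
    OperatorSet,
    TopologyEdit,
    propose_parameter,
    propose_topology,
)
from .settings import PARAMETER_OPERATORS, TOPOLOGY_OPERATORS, RunSettings
from .trees import (
    ConsensusTree,
    Tree,
    TreeError,
    bipartitions,
    lnj_tree,
    majority_consensus,
    model_distance_matrix,
    nj_tree,
    parse_newick,
    random_tree,
)

__all__ = [
    "Individual",
    "SearchResult",
    "CoolingSchedule",
    "ConsensusPruningState",
    "sa_accept",
    "hill_climb",
    "simulated_annealing",
    "select_parents",
    "recombine",
    "genetic_algorithm",
    "cp_update",
    "cp_filter",
    "hybridize",
    "metaga_search",
    "run_search",
    "build_model",
    "build_operator_set",
    "make_starting_trees",
]


@dataclass
class Individual:
    """One candidate solution: a tree plus its full parameter state."""

    tree: Tree
    models: list[SubstitutionModel]
    partition_rates: list[float]
    lnl: float = float("-inf")

    def evaluated(self, engine: LikelihoodEngine) -> "Individual":
        return Individual(self.tree, self.models, self.partition_rates,
                          _evaluate(engine, self))


def _evaluate(engine: LikelihoodEngine, ind: Individual) -> float:
    engine.models = list(ind.models)
    engine.set_partition_rates(ind.partition_rates)
    return engine.log_likelihood(ind.tree).total


@dataclass
class SearchResult:
    best: Individual
    trace: list[tuple]
    stop_reason: str
    population_best: list[Individual] = field(default_factory=list)
    consensus_series: list[tuple[int, ConsensusTree]] = field(default_factory=list)
    generations: int = 0


# ------------------------------------------------------------ construction


def build_model(alignment: Alignment, settings: RunSettings,
                partition: "CharSet | None" = None) -> SubstitutionModel:
    """Initial model per settings: empirical base frequencies, default
    rate parameters (refined during the search and by final optimization)."""
    freqs = alignment.base_frequencies(partition)
    return SubstitutionModel(
        family=settings.model,
        frequencies=freqs,
        pinv=0.1 if settings.use_pinv else 0.0,
        alpha=0.5 if settings.use_gamma else None,
        n_categories=settings.gamma_categories,
    )


def build_operator_set(settings: RunSettings, models: list[SubstitutionModel],
                       n_partitions: int) -> OperatorSet:
    """Filter the configured operators down to those the model supports."""
    ops = []
    for op in settings.enabled_operators:
        if op == "rate_matrix" and all(m.family == "JC" for m in models):
            continue
        if op == "gamma_shape" and not any(m.has_gamma for m in models):
            continue
        if op == "pinv" and not any(m.pinv > 0 for m in models):
            continue
        if op == "partition_rates" and n_partitions < 2:
            continue
        ops.append(op)
    if not ops:
        raise OperatorError("no usable operators for this model configuration")
    freqs = list(settings.operator_frequencies) if settings.operator_frequencies else []
    if freqs and len(freqs) != len(ops):
        freqs = []  # frequencies referred to dropped operators; fall back to equal
    mode = {"fixed": "fixed", "ordered": "ordered",
            "random": "random", "dynamic": "dynamic"}[settings.operator_mode]
    return OperatorSet(ops, frequencies=freqs,
                       minima=settings.operator_min_frequency if mode == "dynamic" else 0.0,
                       mode=mode, adapt_interval=settings.adapt_interval)


def make_starting_trees(alignment: Alignment, settings: RunSettings,
                        model: SubstitutionModel, rng: np.random.Generator,
                        count: int) -> list[Tree]:
    """Starting trees per configuration: NJ (deterministic), LNJ(p),
    random, or a user tree file (one Newick per line, cycled)."""
    taxa = list(alignment.taxa)
    kind = settings.starting_tree
    if kind == "user":
        with open(settings.user_tree_file, encoding="utf-8") as fh:
            trees = [parse_newick(line) for line in fh if line.strip()]
        if not trees:
            raise TreeError("user tree file contains no trees")
        return [trees[i % len(trees)].copy() for i in range(count)]
    if kind == "random":
        return [random_tree(taxa, rng, settings.random_branch_length_mean)
                for _ in range(count)]
    dist = model_distance_matrix(alignment, model)
    if kind == "nj":
        base = nj_tree(dist, taxa)
        return [base.copy() for _ in range(count)]
    return [lnj_tree(dist, taxa, settings.lnj_p, rng) for _ in range(count)]


def _initial_population(alignment, settings, rng, count) -> tuple[list[Individual], LikelihoodEngine]:
    model = build_model(alignment, settings)
    engine = LikelihoodEngine(alignment, model)
    trees = make_starting_trees(alignment, settings, model, rng, count)
    rates = list(engine.partition_rates)
    population = [Individual(t, [model], rates).evaluated(engine) for t in trees]
    return population, engine


# --------------------------------------------------------------- proposals


def _propose_mutation(ind: Individual, engine: LikelihoodEngine,
                      opset: OperatorSet, rng: np.random.Generator,
                      cp: "ConsensusPruningState | None" = None
                      ) -> tuple[str, Individual | None]:
    """Draw one operator and apply it; returns (operator, candidate) where
    candidate is None for a no-op or a consensus-pruning veto."""
    op = opset.choose(rng)
    if op in TOPOLOGY_OPERATORS:
        edge_filter = cp.edge_filter(rng) if cp is not None and cp.handling == "supervised" else None
        edit = propose_topology(ind.tree, op, rng, edge_filter=edge_filter)
        if edit.no_op:
            return op, None
        if cp is not None and not cp_filter(edit, cp, rng):
            return op, None
        cand = Individual(edit.new_tree, ind.models, ind.partition_rates)
        return op, cand.evaluated(engine)
    sizes = engine.partitions.sizes
    try:
        edit = propose_parameter(ind.tree, ind.models, ind.partition_rates,
                                 sizes, op, rng)
    except OperatorError:
        return op, None
    if edit.no_op:
        return op, None
    cand = Individual(
        edit.new_tree if edit.new_tree is not None else ind.tree,
        edit.new_models if edit.new_models is not None else ind.models,
        edit.new_rates if edit.new_rates is not None else ind.partition_rates,
    )
    return op, cand.evaluated(engine)


# ------------------------------------------------------- hill climbing / SA


def sa_accept(delta_lnl: float, temperature: float,
              rng: np.random.Generator, max_accept_prob: float = 1.0) -> bool:
    """Boltzmann acceptance: improvements always accepted; a deterioration
    is accepted with min(max_accept_prob, e^(delta/T)).  No random number
    is consumed when the acceptance probability is exactly zero."""
    if delta_lnl >= 0:
        return True
    if temperature <= 0:
        return False
    prob = min(max_accept_prob, float(np.exp(delta_lnl / temperature)))
    if prob <= 0.0:
        return False
    return float(rng.random()) < prob


class CoolingSchedule:
    """Temperature control for simulated annealing.

    Families (all with floor 1e-12, ``decrease_every`` proposals between
    decrease events, optional reheating every ``reheat_every`` decrease
    events):

    - geometric:    T <- T * factor
    - linear:       T <- max(T - (1 - factor) * T0, floor)
    - logarithmic:  T = T0 / ln(e + n) after n decrease events
    - adaptive:     geometric decrease applied only while the recent
                    acceptance ratio stays above 2%, so cooling pauses once
                    the chain freezes
    - staged:       geometric cooling with mandatory periodic reheating
    """

    # Guards division by zero only; far below any representable lnL delta,
    # so a schedule driven to the floor behaves exactly like hill climbing.
    FLOOR = 1e-300

    def __init__(self, settings: RunSettings, start_temperature: float):
        self.family = settings.cooling_schedule
        self.factor = settings.cooling_factor
        self.decrease_every = max(settings.temperature_decrease_every, 1)
        self.max_accept_prob = settings.max_accept_prob
        self.reheat_every = settings.reheat_every
        if self.family == "staged" and self.reheat_every == 0:
            self.reheat_every = 20
        self.reheat_factor = settings.reheat_factor
        self.t0 = max(start_temperature, self.FLOOR)
        self.temperature = self.t0
        self._proposals = 0
        self._decreases = 0
        self._recent: list[bool] = []

    def note(self, accepted: bool) -> None:
        self._proposals += 1
        self._recent.append(accepted)
        if len(self._recent) > 4 * self.decrease_every:
            self._recent.pop(0)
        if self._proposals % self.decrease_every == 0:
            self._decrease()

    def _decrease(self) -> None:
        self._decreases += 1
        if self.family == "geometric" or self.family == "staged":
            self.temperature *= self.factor
        elif self.family == "linear":
            self.temperature -= (1.0 - self.factor) * self.t0
        elif self.family == "logarithmic":
            self.temperature = self.t0 / np.log(np.e + self._decreases)
        elif self.family == "adaptive":
            ratio = sum(self._recent) / max(len(self._recent), 1)
            if ratio > 0.02:
                self.temperature *= self.factor
        self.temperature = max(self.temperature, self.FLOOR)
        if self.reheat_every and self._decreases % self.reheat_every == 0:
            self.temperature = min(self.temperature * self.reheat_factor, self.t0)

    @staticmethod
    def calibrate_start(ind: Individual, engine: LikelihoodEngine,
                        opset: OperatorSet, rng: np.random.Generator,
                        probes: int = 100, target: float = 0.5) -> float:
        """Starting temperature such that the median early deterioration is
        accepted with probability ``target``."""
        deltas = []
        for _ in range(probes):
            _, cand = _propose_mutation(ind, engine, opset, rng)
            if cand is not None and cand.lnl < ind.lnl:
                deltas.append(ind.lnl - cand.lnl)
        if not deltas:
            return 1.0
        return float(np.median(deltas) / -np.log(target))


def _local_search(start: Individual, engine: LikelihoodEngine,
                  opset: OperatorSet, settings: RunSettings,
                  rng: np.random.Generator,
                  schedule: CoolingSchedule | None) -> SearchResult:
    """Shared propose/accept loop: hill climbing when ``schedule`` is None,
    otherwise simulated annealing."""
    current = start
    best = start
    trace: list[tuple] = []
    best_trace: list[float] = []
    accepted_steps = 0
    t_start = time.monotonic()
    reason = "max steps reached"
    for step in range(settings.max_steps):
        op, cand = _propose_mutation(current, engine, opset, rng)
        accepted = False
        if cand is not None:
            delta = cand.lnl - current.lnl
            if schedule is None:
                # Likelihood-neutral moves (exact ties, e.g. between trees
                # related by swapping identical sequences) are accepted:
                # the trace stays non-decreasing and plateaus can be crossed.
                accepted = delta >= 0
            else:
                accepted = sa_accept(delta, schedule.temperature, rng,
                                     schedule.max_accept_prob)
            if accepted:
                opset.record_gain(op, delta)
                current = cand
                accepted_steps += 1
                if current.lnl > best.lnl:
                    best = current
                if settings.optimize_every and accepted_steps % settings.optimize_every == 0:
                    current = _optimize_individual(current, engine, ("branch_lengths",))
                    if current.lnl > best.lnl:
                        best = current
            else:
                opset.record_gain(op, 0.0)
        if schedule is not None:
            schedule.note(accepted)
        trace.append((step, 0, round(current.lnl, 10), op, accepted))
        best_trace.append(best.lnl)
        if settings.stability_window and likelihood_stability_stop(
                best_trace, settings.stability_window, settings.stability_epsilon):
            reason = "likelihood stability"
            break
        if settings.max_time_seconds and time.monotonic() - t_start > settings.max_time_seconds:
            reason = "time limit"
            break
    if settings.optimize_final:
        best = _optimize_individual(best, engine, _final_targets(best))
    return SearchResult(best, trace, reason, population_best=[best],
                        generations=len(trace))


def _final_targets(ind: Individual) -> tuple[str, ...]:
    targets = ["branch_lengths"]
    if any(m.family != "JC" for m in ind.models):
        targets.append("rate_matrix")
    if any(m.has_gamma for m in ind.models):
        targets.append("gamma_shape")
    if any(m.pinv > 0 for m in ind.models):
        targets.append("pinv")
    if len(ind.partition_rates) > 1:
        targets.append("partition_rates")
    return tuple(targets)


def _optimize_individual(ind: Individual, engine: LikelihoodEngine,
                         targets: tuple[str, ...]) -> Individual:
    engine.models = list(ind.models)
    engine.set_partition_rates(ind.partition_rates)
    tree = ind.tree.copy()
    value = optimize_parameters(tree, engine, targets=targets)
    return Individual(tree, list(engine.models), list(engine.partition_rates),
                      value.total)


def hill_climb(start: Individual, engine: LikelihoodEngine, opset: OperatorSet,
               settings: RunSettings, rng: np.random.Generator) -> SearchResult:
    """Accept-only-if-better baseline; the best-lnL trace is non-decreasing."""
    return _local_search(start, engine, opset, settings, rng, schedule=None)


def simulated_annealing(start: Individual, engine: LikelihoodEngine,
                        opset: OperatorSet, settings: RunSettings,
                        rng: np.random.Generator) -> SearchResult:
    t0 = settings.start_temperature
    if t0 <= 0:
        probe_rng = np.random.default_rng(np.random.SeedSequence([settings.seed, 977]))
        t0 = CoolingSchedule.calibrate_start(start, engine, opset, probe_rng)
    return _local_search(start, engine, opset, settings, rng,
                         schedule=CoolingSchedule(settings, t0))


# ---------------------------------------------------------------- GA layer


def _best_index(population: list[Individual]) -> int:
    best = 0
    for i, ind in enumerate(population):
        if ind.lnl > population[best].lnl:
            best = i
    return best


def select_parents(population: list[Individual], scheme: str,
                   rng: np.random.Generator) -> list[Individual]:
    """Reproduction assignment for one generation.

    rank:        parents drawn with probability proportional to fitness rank
    tournament:  repeated best-of-2 uniform draws
    replacement: the worst floor(I/2) individuals replaced by copies of the
                 best individuals (cycling through the best ceil(I/2))
    improve:     identity (the offspring-only-if-better gate happens later)
    keepthebest: the single best survives untouched; other slots drawn by rank
    """
    n = len(population)
    order = sorted(range(n), key=lambda i: (population[i].lnl, -i))  # worst first
    if scheme == "rank":
        weights = np.zeros(n)
        for rank, idx in enumerate(order, start=1):
            weights[idx] = rank
        weights /= weights.sum()
        return [population[_weighted_draw(weights, rng)] for _ in range(n)]
    if scheme == "tournament":
        out = []
        for _ in range(n):
            a = int(rng.integers(n))
            b = int(rng.integers(n))
            out.append(population[a] if population[a].lnl >= population[b].lnl else population[b])
        return out
    if scheme == "replacement":
        keep = int(np.ceil(n / 2))
        best_first = order[::-1]
        out = list(population)
        for slot, idx in enumerate(order[: n - keep]):
            out[idx] = population[best_first[slot % keep]]
        return out
    if scheme in ("improve", "keepthebest"):
        if scheme == "keepthebest" and n > 1:
            best = _best_index(population)
            weights = np.zeros(n)
            for rank, idx in enumerate(order, start=1):
                weights[idx] = rank
            weights /= weights.sum()
            return [population[i] if i == best else population[_weighted_draw(weights, rng)]
                    for i in range(n)]
        return list(population)
    raise OperatorError(f"unknown selection scheme {scheme!r}")


def _weighted_draw(weights: np.ndarray, rng: np.random.Generator) -> int:
    u = float(rng.random())
    acc = 0.0
    for i, w in enumerate(weights):
        acc += w
        if u < acc:
            return i
    return len(weights) - 1


def recombine(parent_a: Individual, parent_b: Individual,
              rng: np.random.Generator) -> Individual | None:
    """Exchange the subtrees defined by a shared bipartition.

    A random bipartition present in both parents is chosen; the offspring
    is parent A with that subtree replaced by parent B's subtree for the
    same taxon set (B's sub-topology and branch lengths, including the
    branch realizing the split).  Returns None when the parents share no
    nontrivial bipartition."""
    tree_a, tree_b = parent_a.tree, parent_b.tree
    if tree_a.taxa != tree_b.taxa:
        raise TreeError("parents have different taxon sets")
    shared = sorted(bipartitions(tree_a) & bipartitions(tree_b),
                    key=lambda s: (len(s), tuple(sorted(s))))
    if not shared:
        return None
    split = shared[int(rng.integers(len(shared)))]
    from .trees import split_to_edge

    ua, va = split_to_edge(tree_a)[split]
    ub, vb = split_to_edge(tree_b)[split]
    out = tree_a.copy()
    for node in tree_a.side_nodes(ua, va):
        out.remove_node(node)
    mapping: dict[int, int] = {}
    stack = [vb]
    seen = {ub, vb}
    mapping[vb] = out.new_node(tree_b.labels.get(vb))
    while stack:
        node = stack.pop()
        for nb in tree_b.adj[node]:
            if nb in seen:
                continue
            seen.add(nb)
            mapping[nb] = out.new_node(tree_b.labels.get(nb))
            out.connect(mapping[node], mapping[nb], tree_b.adj[node][nb])
            stack.append(nb)
    out.connect(ua, mapping[vb], tree_b.adj[ub][vb])
    return Individual(out, parent_a.models, parent_a.partition_rates)


def _ga_generation(population: list[Individual], engine: LikelihoodEngine,
                   opset: OperatorSet, settings: RunSettings,
                   rng: np.random.Generator,
                   cp: "ConsensusPruningState | None" = None) -> list[Individual]:
    """One generation: selection, then recombination-or-mutation per slot."""
    scheme = settings.selection_scheme
    selected = select_parents(population, scheme, rng)
    best = _best_index(population)
    new_population: list[Individual] = []
    for slot, parent in enumerate(selected):
        if scheme == "keepthebest" and slot == best:
            new_population.append(parent)
            continue
        child: Individual | None = None
        is_suboptimal = parent.lnl < population[best].lnl
        if is_suboptimal and float(rng.random()) < settings.recombination_prob:
            better = [ind for ind in population if ind.lnl > parent.lnl]
            if better:
                partner = better[int(rng.integers(len(better)))]
                child = recombine(parent, partner, rng)
                if child is not None:
                    child = child.evaluated(engine)
        op = None
        if child is None:
            op, child = _propose_mutation(parent, engine, opset, rng, cp=cp)
        if child is None:
            new_population.append(parent)
            continue
        if scheme == "improve" and child.lnl <= parent.lnl:
            if op is not None:
                opset.record_gain(op, 0.0)
            new_population.append(parent)
            continue
        if op is not None:
            opset.record_gain(op, max(child.lnl - parent.lnl, 0.0))
        new_population.append(child)
    return new_population


def genetic_algorithm(population: list[Individual], engine: LikelihoodEngine,
                      opset: OperatorSet, settings: RunSettings,
                      rng: np.random.Generator) -> SearchResult:
    """Classical single-population GA."""
    if len(population) < 2:
        raise TreeError("GA needs a population of at least 2 individuals")
    best = population[_best_index(population)]
    trace: list[tuple] = []
    best_trace: list[float] = []
    t_start = time.monotonic()
    reason = "max generations reached"
    for gen in range(settings.max_generations):
        population = _ga_generation(population, engine, opset, settings, rng)
        gen_best = population[_best_index(population)]
        if gen_best.lnl > best.lnl:
            best = gen_best
        if settings.optimize_every and (gen + 1) % settings.optimize_every == 0:
            refined = _optimize_individual(gen_best, engine, ("branch_lengths",))
            population[_best_index(population)] = refined
            if refined.lnl > best.lnl:
                best = refined
        trace.append((gen, 0, round(gen_best.lnl, 10), "", True))
        best_trace.append(best.lnl)
        if settings.stability_window and likelihood_stability_stop(
                best_trace, settings.stability_window, settings.stability_epsilon):
            reason = "likelihood stability"
            break
        if settings.max_time_seconds and time.monotonic() - t_start > settings.max_time_seconds:
            reason = "time limit"
            break
    if settings.optimize_final:
        best = _optimize_individual(best, engine, _final_targets(best))
    return SearchResult(best, trace, reason, population_best=[best],
                        generations=len(trace))


# ------------------------------------------------------------- metaGA / CP


@dataclass
class ConsensusPruningState:
    """Bipartition agreement across all P*I current trees.

    ``counts[split] == total`` marks a branch shared by every tree; strict
    mode forbids mutating it (except with probability t), stochastic mode
    rejects mutations with probability (count/total) * (1 - t)."""

    counts: Counter
    total: int
    mode: str = "strict"
    tolerance: float = 0.0
    handling: str = "blind"

    def edge_filter(self, rng: np.random.Generator):
        """Candidate filter for supervised handling: operators only target
        branches this filter admits."""

        def admit(split: frozenset) -> bool:
            count = self.counts.get(split, 0)
            if self.mode == "strict":
                if count < self.total:
                    return True
                return float(rng.random()) < self.tolerance
            reject_prob = (count / self.total) * (1.0 - self.tolerance)
            return float(rng.random()) >= reject_prob

        return admit


def cp_update(populations: list[list[Individual]], mode: str = "strict",
              tolerance: float = 0.0, handling: str = "blind") -> ConsensusPruningState:
    """Recount bipartitions over all current trees (every generation)."""
    counts: Counter = Counter()
    total = 0
    for pop in populations:
        for ind in pop:
            counts.update(bipartitions(ind.tree))
            total += 1
    return ConsensusPruningState(counts, total, mode=mode,
                                 tolerance=tolerance, handling=handling)


def cp_filter(edit: TopologyEdit, cp: ConsensusPruningState,
              rng: np.random.Generator) -> bool:
    """Post-proposal veto (blind handling): True = allow the edit.

    Strict mode rejects any edit destroying a branch shared by all trees,
    except with probability t; stochastic mode rejects with probability
    max_over_affected(count/total) * (1 - t)."""
    if cp.mode == "off" or not edit.affected:
        return True
    counts = [cp.counts.get(split, 0) for split in edit.affected]
    if cp.mode == "strict":
        if max(counts) >= cp.total:
            return float(rng.random()) < cp.tolerance
        return True
    reject_prob = (max(counts) / cp.total) * (1.0 - cp.tolerance)
    if reject_prob <= 0:
        return True
    return float(rng.random()) >= reject_prob


def hybridize(populations: list[list[Individual]], engine: LikelihoodEngine,
              prob: float, rng: np.random.Generator) -> bool:
    """Inter-population hybridization event.

    With probability ``prob`` per generation, every sub-optimal individual
    of one random population is recombined with a random individual from
    another random population.  Population bests are never replaced, so the
    best solution cannot be lost.  Returns True when the event fired."""
    if len(populations) < 2 or float(rng.random()) >= prob:
        return False
    target = int(rng.integers(len(populations)))
    donor = int(rng.integers(len(populations) - 1))
    if donor >= target:
        donor += 1
    pop = populations[target]
    best = _best_index(pop)
    for i, ind in enumerate(pop):
        if i == best:
            continue
        partner = populations[donor][int(rng.integers(len(populations[donor])))]
        child = recombine(ind, partner, rng)
        if child is not None:
            pop[i] = child.evaluated(engine)
    return True


def metaga_search(alignment: Alignment, settings: RunSettings,
                  seed_sequence: np.random.SeedSequence | None = None) -> SearchResult:
    """Metapopulation GA: P populations of I individuals evolve under a
    per-population classical GA while consensus pruning guides every
    topology operator through inter-population agreement.  Consensus trees
    over all P*I individuals are sampled every ``mre_interval`` generations
    and feed the intra-replicate MRE stopping rule."""
    if settings.populations < 2:
        raise TreeError("metaGA needs at least 2 populations")
    if seed_sequence is None:
        seed_sequence = np.random.SeedSequence(settings.seed)
    base = seed_sequence.entropy if isinstance(seed_sequence.entropy, list) else [seed_sequence.entropy]
    pop_rngs = [np.random.default_rng(np.random.SeedSequence(base + [10 + p]))
                for p in range(settings.populations)]
    global_rng = np.random.default_rng(np.random.SeedSequence(base + [7]))
    init_rng = np.random.default_rng(np.random.SeedSequence(base + [3]))

    model = build_model(alignment, settings)
    engine = LikelihoodEngine(alignment, model)
    total = settings.populations * settings.individuals
    trees = make_starting_trees(alignment, settings, model, init_rng, total)
    rates = list(engine.partition_rates)
    populations = [
        [Individual(trees[p * settings.individuals + i], [model], rates).evaluated(engine)
         for i in range(settings.individuals)]
        for p in range(settings.populations)
    ]
    opset = build_operator_set(settings, [model], len(engine.partitions.partitions))

    hybridization_prob = settings.hybridization_prob
    if settings.populations < 2:
        hybridization_prob = 0.0

    best = max((ind for pop in populations for ind in pop), key=lambda i: i.lnl)
    cp = cp_update(populations, mode=settings.cp_mode,
                   tolerance=settings.cp_tolerance, handling=settings.cp_handling)
    stopper = MreStopper(threshold=settings.mre_threshold,
                         required=settings.mre_consecutive)
    series: list[tuple[int, ConsensusTree]] = []
    trace: list[tuple] = []
    best_trace: list[float] = []
    t_start = time.monotonic()
    reason = "max generations reached"

    for gen in range(settings.max_generations):
        for p, pop in enumerate(populations):
            cp_arg = cp if settings.cp_mode != "off" else None
            populations[p] = _ga_generation(pop, engine, opset, settings,
                                            pop_rngs[p], cp=cp_arg)
        hybridize(populations, engine, hybridization_prob, global_rng)
        cp = cp_update(populations, mode=settings.cp_mode,
                       tolerance=settings.cp_tolerance, handling=settings.cp_handling)
        gen_best = max((ind for pop in populations for ind in pop), key=lambda i: i.lnl)
        if gen_best.lnl > best.lnl:
            best = gen_best
        if settings.optimize_every and (gen + 1) % settings.optimize_every == 0:
            refined = _optimize_individual(gen_best, engine, ("branch_lengths",))
            if refined.lnl > best.lnl:
                best = refined
        for p, pop in enumerate(populations):
            trace.append((gen, p, round(pop[_best_index(pop)].lnl, 10), "", True))
        best_trace.append(best.lnl)
        if settings.mre_enabled and (gen + 1) % settings.mre_interval == 0:
            consensus = majority_consensus([ind.tree for pop in populations for ind in pop])
            series.append((gen + 1, consensus))
            if stopper.observe(consensus, index=gen + 1):
                reason = "intra-replicate MRE convergence"
                break
        if settings.stability_window and likelihood_stability_stop(
                best_trace, settings.stability_window, settings.stability_epsilon):
            reason = "likelihood stability"
            break
        if settings.max_time_seconds and time.monotonic() - t_start > settings.max_time_seconds:
            reason = "time limit"
            break

    population_best = [pop[_best_index(pop)] for pop in populations]
    if settings.optimize_final:
        best = _optimize_individual(best, engine, _final_targets(best))
    return SearchResult(best, trace, reason, population_best=population_best,
                        consensus_series=series, generations=len(best_trace))


# ----------------------------------------------------------------- driver


def run_search(alignment: Alignment, settings: RunSettings,
               seed_sequence: np.random.SeedSequence | None = None) -> SearchResult:
    """Dispatch one search under the configured heuristic."""
    if alignment.n_tax < 4:
        raise TreeError("searches need at least 4 taxa")
    if seed_sequence is None:
        seed_sequence = np.random.SeedSequence(settings.seed)
    if settings.heuristic == "metaga":
        return metaga_search(alignment, settings, seed_sequence)
    base = seed_sequence.entropy if isinstance(seed_sequence.entropy, list) else [seed_sequence.entropy]
    rng = np.random.default_rng(np.random.SeedSequence(base + [1]))
    if settings.heuristic == "ga":
        count = max(settings.individuals, 2)
        population, engine = _initial_population(alignment, settings, rng, count)
        opset = build_operator_set(settings, [population[0].models[0]],
                                   len(engine.partitions.partitions))
        return genetic_algorithm(population, engine, opset, settings, rng)
    population, engine = _initial_population(alignment, settings, rng, 1)
    opset = build_operator_set(settings, [population[0].models[0]],
                               len(engine.partitions.partitions))
    if settings.heuristic == "sa":
        return simulated_annealing(population[0], engine, opset, settings, rng)
    return hill_climb(population[0], engine, opset, settings, rng)
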