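# Methods

This note documents the models, algorithms, and design choices behind
`phyloga`. It covers the statistical model, the shared search machinery, the
four heuristics, convergence diagnostics, the simulator, and the numerical
conventions, together with the limitations a user should know about.

## Statistical model

Trees are unrooted binary topologies with non-negative branch lengths in
expected substitutions per site. Sequence evolution follows a reversible
continuous-time Markov chain on {A, C, G, T}; five nested parameterizations
are supported: JC (equal rates, uniform frequencies), K2P (one
transition/transversion ratio κ, uniform frequencies), HKY85 (κ plus free
frequencies π), TN93 (separate purine and pyrimidine transition ratios κ1,
κ2), and GTR (six exchangeabilities, with the G↔T rate fixed to 1 as the
reference). Every rate matrix Q satisfies detailed balance π_i q_ij = π_j
q_ji and is rescaled to unit expected rate, −Σ π_i q_ii = 1, so branch
lengths remain interpretable across models.

Among-site rate variation uses a proportion of invariant sites Pinv (rate 0)
and/or a discrete Gamma distribution: k equal-probability categories of
Gamma(α, α) represented by their conditional means (the mean-of-bins
construction; medians are a known alternative but means keep the category
average exactly 1). When Pinv and Gamma are combined, variable-site rates are
scaled by 1/(1 − Pinv), keeping the total expected rate at 1. The invariant
class is applied per partition: a pattern contributes to it only if some
state assignment is consistent with every leaf symbol in that partition's
column.

Partitioned data share one topology (the alignment is treated as a
non-recombining region), while base frequencies, exchange parameters, α and
Pinv are independent per partition. Each partition additionally carries a
relative rate multiplying its branch lengths; the rates are constrained so
that their partition-size-weighted mean is 1, enforced by renormalization
after every update.

## Likelihood computation

Log-likelihoods come from the pruning (post-order message passing) algorithm
over site patterns. Identical columns of a partition are collapsed into
weighted patterns; correctness of this compression is asserted against
per-site evaluation in the tests, and the pruning recursion itself is
validated against exhaustive enumeration over all internal-state assignments
on small instances (≤ 6 taxa), the module's primary oracle.

Underflow protection uses per-node scaling: after each node's conditional
likelihood vector is computed, it is divided by its per-pattern maximum
(shared across rate categories) and the logs accumulate separately. 50 taxa
× 10,000 sites evaluate to finite lnL without extended precision.

P(t) matrices are computed by eigendecomposition of the symmetrized matrix
diag(√π) Q diag(1/√π), which is real-symmetric, so eigenvalues are real and
the decomposition is stable; rows are clipped and renormalized against
rounding. The virtual root is placed on an internal node (reversibility
makes the choice irrelevant; tested to 1e-10 across root placements).

A cache of per-node partial vectors supports incremental updates: a
branch-length edit recomputes only the nodes from that branch to the virtual
root. Topology edits are produced as snapshot pairs (old tree, new tree), so
node identity is not stable across them and the cache is rebuilt — a
performance trade, not a correctness one; the equality of incremental and
from-scratch values is tested at 1e-12.

## Parameter optimization

Continuous parameters are optimized coordinate-wise with bounded Brent
searches: branch lengths on [1e-8, 10] (absolute tolerance 1e-6), rate
parameters and α in log space, Pinv on [0, 0.95], partition rates in log
space with the weighted-mean-1 constraint applied inside the objective.
Cycles repeat until the gain falls below 1e-4 (bounded cycle count). Every
candidate step is kept only if it does not lower the likelihood, so
optimization is monotone by construction. During stochastic searches,
optimization is deliberately sparse — by default branch lengths only, every
50 accepted steps or generations — because most parameter movement is meant
to happen through the operators themselves, and optimizing on clearly
sub-optimal intermediate trees is wasted effort; a full optimization pass
(rate parameters, α, Pinv, partition rates) runs once at the end of the
search. Rate parameters are initialized from a moment-style empirical
transition/transversion ratio, which puts TN93/GTR coordinate descent in the
right basin immediately.

## Shared search machinery

**Starting trees.** Neighbor joining (deterministic, with ties broken toward
the lowest index pair and negative length estimates clamped to zero with the
deficit moved to the sister branch), loose neighbor joining (LNJ), and
uniform random topologies (sequential random leaf insertion, exponential
branch lengths with mean 0.1). LNJ draws each agglomeration uniformly from
the ⌈m(m−1)p/2⌉ best candidate pairs (minimum list size 1), where m is the
*current* cluster count — the candidate pool shrinks as clusters merge.
Candidates are ranked by the same rate-corrected criterion NJ minimizes, not
by raw distance; this is what makes p = 0 reproduce NJ exactly, and p = 1
fully randomize the joins. Distance matrices are pairwise maximum-likelihood
estimates under any supported model (numerically optimized per pair;
saturated pairs capped at 10 substitutions/site and logged). Columns with
ambiguity codes or gaps are skipped in pairwise distances; the full
likelihood machinery treats them as partial information (a gap is a fully
ambiguous state).

**Operators.** Five topology operators — NNI, SPR, TBR, TXS (two leaves
exchange positions), STS (two node-disjoint subtrees exchange positions,
resampled up to 50 times before declaring a no-op) — and six parameter
operators (all branch lengths, internal branch lengths only, rate-matrix
parameters, Gamma shape, Pinv, among-partition rates). TBR bisects any
branch and reconnects arbitrary points of the two fragments (a single-leaf
fragment reattaches directly), which makes the TBR neighborhood a superset
of SPR's, itself a superset of NNI's. Positive parameters get multiplicative
log-uniform proposals (window λ per operator, defaults in
`operators.PROPOSAL_SCALES`); Pinv proposals are additive and reflected into
[0, 0.99]. Every edit carries a full undo snapshot, so apply-then-undo is
exact.

Operators are drawn by configurable frequencies (fixed, round-robin,
uniform, or dynamic). Dynamic adaptation credits each operator with the
realized (accepted) likelihood gains since the last adaptation and resets
frequencies to minima + (1 − Σ minima) · gain share; operators with
configured minimum frequencies can therefore never be starved out.

**Stopping rules.** Any combination of: step/generation caps, wall-clock
time (checked at step boundaries), likelihood stability (improvement over a
trailing window below ε, strict inequality), and the MRE rules below.

## The four heuristics

**Hill climbing** accepts a proposal iff it does not lower the likelihood.
Accepting likelihood-neutral moves (Δ = 0) keeps the trace non-decreasing
while letting the search drift across plateaus — and makes HC exactly the
zero-temperature limit of the annealer, which the tests exploit.

**Simulated annealing** accepts deteriorations with probability
min(maxAcceptProb, e^(ΔlnL/T)). Cooling schedules: geometric, linear,
logarithmic, adaptive (geometric decreases applied only while the recent
acceptance ratio exceeds 2%, so cooling pauses once the chain freezes), and
staged (geometric with mandatory periodic reheating); all share four
controls — starting temperature, maximum acceptance probability, decrease
frequency, and reheating (factor and period). The default starting
temperature is calibrated from 100 probe proposals so the median early
deterioration is accepted with probability 0.5. When the acceptance
probability is exactly zero no random number is drawn, which is what makes
a frozen annealer reproduce hill climbing draw-for-draw.

**Genetic algorithm.** A population of I individuals (trees plus full
parameter state) evolves by selection, recombination, and mutation. The five
selection schemes are implemented as: *Rank* (reproduction probability
proportional to fitness rank), *Tournament* (best of two uniform draws per
slot), *Replacement* (worst half replaced by copies of the best),
*Improve* (an offspring replaces its parent only if better), and
*KeepTheBest* (the single best is untouchable; other slots are filled by
rank). Recombination picks a bipartition shared by the two parents and
replaces the recipient's subtree on one side with the donor's subtree for
the same taxon set (donor sub-topology and branch lengths, including the
branch realizing the split); parents sharing no internal split fall back to
mutation. The default scheme is Improve: it guarantees a monotone
best-likelihood trace and — unlike KeepTheBest — still works for populations
of a single individual, the classic metaGA configuration.

**metaGA.** P populations of I individuals each run the GA per generation,
but all topology proposals are filtered by *consensus pruning* (CP): a table
of bipartition counts over all P·I current trees, recounted every
generation. An edit's "affected" branches are the splits it would destroy.
Strict CP rejects any edit destroying a split present in all P·I trees
(except with tolerance probability t); stochastic CP rejects with
probability (count/(P·I))·(1 − t), using the maximum count over affected
splits. In blind handling the veto is applied after proposal (a vetoed
mutation leaves the tree unchanged); in supervised handling operators
restrict their primary branch choices to the admitted pool up front.
Tolerance composition with stochastic CP (the (1 − t) factor) is this
package's convention. Inter-population *hybridization* fires with a
configured per-generation probability: every sub-optimal individual of one
random population is recombined with random individuals of another.
Population bests are never replaced by hybridization, so the best solution
cannot be lost; "sub-optimal" means everything except the single population
best (ties broken by index).

## Convergence diagnostics

The mean relative error between consensus trees Ti, Tj is

    MRE = (1/nPartition) Σ_p |Φ_i,p − Φ_j,p| / max(Φ_i,p, Φ_j,p)

summed over the bipartitions observed in either tree (counted once); a split
present in only one tree contributes 1; splits absent from both are not
enumerated. Consensus trees feeding the MRE keep *all* observed splits with
their frequencies (the displayed consensus remains majority-rule) — the sum
requires sub-majority splits to exist.

The intra-replicate rule samples the consensus of all P·I trees every n > 1
generations (default 5): an MRE below the threshold (default 5%) increments
a counter against a fixed reference sample; a value at or above it discards
the comparison, moves the reference to the newer sample, and resets the
counter; the replicate stops after a configured run of consecutive
below-threshold values (default 10). The inter-replicate rule applies the
same automaton to running consensuses T_{1..i} over completed replicates,
between a configured minimum and maximum count. Both rules can be combined.
The equality boundary (MRE exactly at the threshold) counts as an
exceedance.

Replicates are fully independent searches seeded by (master seed, replicate
index), so completion order cannot influence any result. Each replicate
contributes its single best tree; the final majority-rule consensus carries
support values equal to the fraction of replicates displaying each branch.
(Within one metaGA run, the per-population best trees are available
separately.) These support values are heuristic agreement frequencies, not
posterior probabilities.

## Simulator

The generator draws root states from π, assigns each site a rate from the
model's Pinv/Gamma mixture (invariant sites never change), and evolves
states down the tree with P(branch length × site rate × partition rate) per
branch. It reproduces the JC expected mismatch fraction and the stationary
frequencies within sampling error, and identical specs and seeds yield
identical alignments. What it does *not* emulate: indels (gaps only enter
data through user alignments), selection or covarion-style rate switching,
recombination, and alignment error. Passing recovery tests on simulated data
therefore demonstrates correctness of the inference machinery under the
model's own assumptions, not robustness to model violation.

Default study conditions used by the recovery tests and the acceptance
script: 10 taxa, 2000 (tests) or 1500 (script) sites, HKY85 with κ = 4 and
Γ(α = 0.5, k = 4), every branch 0.1 substitutions/site — short enough to be
informative, long enough that parsimony-like shortcuts fail; metaGA with
P = 4, I = 1, stochastic CP with t = 0.05, NNI + SPR + branch-length
operators, at most 300 generations with the default MRE stop.

## Determinism and parallelism

Runs are bit-reproducible: every population and every replicate draws from
its own RNG stream derived deterministically from the master seed, and a
`workers` setting is accepted as a performance knob that can never change
results (verified by the tests). Execution in this implementation is serial;
the per-stream design is what licenses distributing populations or
replicates across cores without breaking reproducibility.

## Numerical conventions and degenerate inputs

- Branch-length bounds [1e-8, 10]; model-parameter bounds roughly
  [0.02, 50] (log-Brent); Pinv ∈ [0, 0.95] during optimization.
- NJ/LNJ tie-breaks: lowest (row, column) index pair; random-tree edge
  choices index sorted edge lists, so equal seeds give equal trees.
- Site likelihoods are floored at 1e-300 before logs; with per-node scaling
  this floor is never reached on valid inputs.
- All-constant alignments drive Pinv estimates to the optimizer's upper
  bound (0.95) — reported as estimated, with the likelihood flat beyond it.
- Searches require ≥ 4 taxa (three-taxon unrooted trees admit a single
  topology); two-taxon trees are supported for likelihood evaluation only.
- Newick output prints branch lengths with shortest-exact float repr, so
  write→parse round-trips are bit-exact.

## Known limitations

- Nucleotide data only: no amino-acid or codon models, no ancestral-state
  reconstruction.
- The cooling-schedule catalogue is a five-family parameterization of the
  four named controls, not a reproduction of any particular larger named
  set.
- MATCHCHAR and step-matrix Nexus constructs are not supported; interleaved
  and sequential matrices are.
- No subtree-equality-vector or GPU acceleration; the engine favors clarity
  and testability at desk scale (tens of taxa, ~10^4 sites).
- Model selection evaluates candidates on a fixed NJ topology, the usual
  pragmatic choice; a poor NJ tree can in principle distort the ranking.
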