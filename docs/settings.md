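# The `phyloga` settings block

All run settings can be embedded in a Nexus file as a command block, so a
dataset travels with its analysis configuration:

```nexus
begin phyloga;
    heuristic = metaga;
    populations = 4;
    individuals = 1;
    model = HKY85;
    use_gamma = true;
    cp_mode = stochastic;
    cp_tolerance = 0.05;
    seed = 42;
end;
```

Grammar: `key = value;` statements between `begin phyloga;` and `end;`.
Keys are case-insensitive; lists are comma-separated; booleans are
`true`/`false`; `none` clears a value. Unknown keys are rejected. A Nexus
file without the block runs with the defaults below. Command-line flags
override block values.

## Keys and defaults

### Heuristic

| key | default | meaning |
|---|---|---|
| `heuristic` | `metaga` | `hc`, `sa`, `ga`, or `metaga` |
| `populations` | 4 | metaGA population count P |
| `individuals` | 4 | individuals per population I (GA: population size) |
| `selection_scheme` | `improve` | `rank`, `tournament`, `replacement`, `improve`, `keepthebest` |
| `recombination_prob` | 0.2 | intra-population recombination probability per sub-optimal individual |
| `hybridization_prob` | 0.1 | per-generation inter-population hybridization probability (metaGA) |
| `cp_mode` | `stochastic` | consensus pruning: `strict`, `stochastic`, `off` |
| `cp_tolerance` | 0.05 | tolerance t: probability a fully-agreed branch may still be mutated |
| `cp_handling` | `blind` | `blind` (post-proposal veto) or `supervised` (pre-filtered candidates) |

### Simulated annealing

| key | default | meaning |
|---|---|---|
| `cooling_schedule` | `geometric` | `linear`, `geometric`, `logarithmic`, `adaptive`, `staged` |
| `start_temperature` | 0.0 | 0 = calibrate from 100 probe proposals (median deterioration accepted at 0.5) |
| `cooling_factor` | 0.95 | per-decrease multiplier (linear: fraction of T0 subtracted) |
| `temperature_decrease_every` | 10 | proposals between decrease events |
| `max_accept_prob` | 1.0 | cap on the acceptance probability of deteriorations |
| `reheat_every` | 0 | decrease events between reheats (0 = off; `staged` forces 20) |
| `reheat_factor` | 2.0 | temperature multiplier on reheat (capped at T0) |

### Model

| key | default | meaning |
|---|---|---|
| `model` | `HKY85` | `JC`, `K2P`, `HKY85`, `TN93`, `GTR` |
| `use_pinv` | false | estimate a proportion of invariant sites |
| `use_gamma` | false | discrete-Gamma rate heterogeneity |
| `gamma_categories` | 4 | number of Gamma categories k |

### Starting trees

| key | default | meaning |
|---|---|---|
| `starting_tree` | `lnj` | `nj`, `lnj`, `random`, `user` |
| `lnj_p` | 0.25 | LNJ randomization (0 = NJ, 1 = random joins) |
| `random_branch_length_mean` | 0.1 | exponential mean for random-tree branch lengths |
| `user_tree_file` | none | Newick file (one tree per line, cycled over individuals) |

### Operators

| key | default | meaning |
|---|---|---|
| `enabled_operators` | `NNI,SPR,branch_lengths` | any of `NNI,SPR,TBR,TXS,STS,branch_lengths,internal_branch_lengths,rate_matrix,gamma_shape,pinv,partition_rates`; operators the model cannot use are dropped automatically |
| `operator_mode` | `fixed` | `fixed`, `ordered`, `random`, `dynamic` |
| `operator_frequencies` | none | per-operator frequencies (equal when empty) |
| `operator_min_frequency` | 0.02 | floor per operator under dynamic adaptation |
| `adapt_interval` | 100 | steps between dynamic re-weightings |

### Optimization and stopping

| key | default | meaning |
|---|---|---|
| `optimize_every` | 50 | branch-length optimization every N accepted steps (HC/SA) or generations (GA/metaGA); 0 = never |
| `optimize_final` | true | full parameter optimization of the best tree at the end |
| `max_steps` | 20000 | HC/SA step cap |
| `max_generations` | 2000 | GA/metaGA generation cap |
| `max_time_seconds` | 0 | wall-clock cap, checked at step boundaries (0 = off) |
| `stability_window` | 0 | likelihood-stability window (0 = off) |
| `stability_epsilon` | 1e-4 | minimum improvement over the window |
| `mre_enabled` | true | intra-replicate MRE stop (metaGA) |
| `mre_interval` | 5 | generations between consensus samples (must be > 1) |
| `mre_threshold` | 0.05 | MRE threshold |
| `mre_consecutive` | 10 | consecutive below-threshold samples required |

### Replicates

| key | default | meaning |
|---|---|---|
| `replicates` | 1 | fixed replicate count |
| `min_replicates` / `max_replicates` | 0 / 0 | min > 0 enables automatic stopping by inter-replicate MRE |
| `inter_mre_threshold` | 0.05 | inter-replicate MRE threshold |
| `inter_mre_consecutive` | 10 | consecutive below-threshold replicates required |

### Miscellaneous

| key | default | meaning |
|---|---|---|
| `seed` | 1 | master random seed; all per-population/per-replicate streams derive from it |
| `workers` | 1 | performance knob only; results are identical for any value |
| `lrt_alpha` | 0.05 | significance level for the likelihood ratio test |
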