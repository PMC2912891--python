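"""Compare starting-tree generators and the four search heuristics.

Builds NJ, loose-NJ (p=0.25), and random starting trees for the same
dataset, then runs hill climbing, simulated annealing, the classical GA,
and the metaGA, printing each heuristic's final log-likelihood.  Higher
(less negative) is better; on easy data all four should agree.
"""

import numpy as np

from phyloga import (
    RunSettings,
    SimulationSpec,
    SubstitutionModel,
    lnj_tree,
    model_distance_matrix,
    nj_tree,
    random_tree,
    robinson_foulds,
    run_search,
    simulate_alignment,
)

truth = random_tree([f"x{i}" for i in range(9)], np.random.default_rng(21),
                    branch_length_mean=0.1)
model = SubstitutionModel(family="JC")
alignment = simulate_alignment(SimulationSpec(truth, [model], n_sites=1000, seed=22))

dist = model_distance_matrix(alignment, model)
taxa = list(alignment.taxa)
nj = nj_tree(dist, taxa)
lnj = lnj_tree(dist, taxa, 0.25, np.random.default_rng(23))
rand = random_tree(taxa, np.random.default_rng(24))
print("starting trees, RF distance to the true topology:")
print(f"  NJ:          {robinson_foulds(nj, truth)}")
print(f"  LNJ(p=0.25): {robinson_foulds(lnj, truth)}")
print(f"  random:      {robinson_foulds(rand, truth)}")

for heuristic in ("hc", "sa", "ga", "metaga"):
    settings = RunSettings(heuristic=heuristic, model="JC", individuals=4,
                           max_steps=2000, max_generations=150,
                           stability_window=300, stability_epsilon=1e-4,
                           seed=25)
    result = run_search(alignment, settings)
    rf = robinson_foulds(result.best.tree, truth)
    print(f"{heuristic:>7}: lnL {result.best.lnl:10.2f}  RF {rf}  "
          f"({result.stop_reason})")
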