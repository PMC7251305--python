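"""Discretize a block series into states and export its transition network.

Simulates one dyad, z-scores the patient's three linguistic features, fits an
8-state K-means model, prunes scarce states, estimates the Markov transition
matrix and writes a GraphML network with row-maximum edges flagged.
"""

import numpy as np

from tcmnet import (
    GeneratorConfig,
    export_network,
    mtm,
    simulate_dyad,
    fit_states,
    prune_outlier_states,
    standardize,
)
from tcmnet.markov import row_max_flags

sim = simulate_dyad(GeneratorConfig(n_blocks=5000, emission_sd=0.7), seed=1)
Z, constants = standardize(sim.series.features("patient"))
model, labels = fit_states(Z, k=8, n_restarts=50, seed=0, constants=constants)
print(f"variance explained by 8 clusters: {model.variance_explained:.1%}")

model, seq = prune_outlier_states(model, labels, min_share=0.01)
print(f"active states after 1% pruning:   {list(model.active_states)}")
print(f"blocks dropped by pruning:        {len(seq.dropped_indices)}")

T = mtm(seq, k=8)
np.set_printoptions(precision=3, suppress=True)
print("transition matrix row 1 (NaN rows = pruned/unvisited states):")
print(" ", T.probs[0])
export_network(T, "scratch_network.graphml", fmt="graphml")
print("most probable destination per state:", row_max_flags(T))
# Each flagged (i, j) pair marks state i's most likely next state - the
# skeleton of the linguistic network's attractor structure.
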