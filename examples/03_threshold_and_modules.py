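"""Group consistency thresholding and consensus modular decomposition.

Edges kept in >=50% of subjects form the group mask; the group-mean matrix
is partitioned by Louvain at the resolution that gives the most
reproducible partitions, then stabilized by agreement-matrix consensus.
"""

import numpy as np

import hallnet as hn

_, cohort, nodes, truth = hn.generate_cohort(hn.SimulationConfig(seed=1))

mask = hn.consistency_mask(cohort, fraction=0.5)
print(f"consistency mask density: {mask.density:.3f} "
      "(fraction of possible edges retained)")

binned = hn.distance_binned_mask(cohort, nodes, target_density=0.15)
print(f"distance-binned mask density: {binned.density:.3f} "
      "(quota per length bin avoids short-edge bias)")

gmean = hn.group_mean_matrix(cohort, mask)
sweep = hn.select_gamma(gmean, gammas=np.arange(0.5, 2.01, 0.25), n_runs=20,
                        seed=2)
print(f"\nresolution sweep -> gamma = {sweep.selected_gamma:g} "
      f"(highest mean pairwise partition similarity)")

part = hn.consensus_partition(gmean, gamma=sweep.selected_gamma, n_runs=100,
                              seed=3)
nmi = hn.partition_similarity(part.assignment, truth.true_partition)
print(f"consensus partition: {part.n_modules} modules, Q = {part.quality:.3f}, "
      f"similarity to planted partition = {nmi:.2f}")
print("Similarity 1.0 means the planted community structure was recovered exactly.")
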