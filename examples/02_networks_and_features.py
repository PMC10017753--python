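"""From connectivity matrices to the 685-dimensional feature vector.

Takes one synthetic subject, builds the weighted structural network from
streamline counts, selects the small-world cost range for the functional
correlation matrix, and assembles the named topological feature vector
(390 structural + 295 functional features).
"""

import numpy as np

from connsae import CohortConfig, generate_cohort
from connsae.networks import build_structural_network, select_smallworld_cost_range
from connsae.metrics import (assemble_feature_vector, average_metrics_over_costs,
                             compute_nodal_metrics)

cohort = generate_cohort(CohortConfig(n_per_group=2, seed=3))
counts = cohort.structural_counts[0]
corr = cohort.functional_corr[0]

net = build_structural_network(counts)
print(f"structural network: {net.n_nodes} nodes, "
      f"max weight {net.weights.max():.2f} (normalised to 1), "
      f"density {(net.weights > 0).sum() / (78 * 77):.2f}")
struct = compute_nodal_metrics(net.weights, weighted=True)

fns = select_smallworld_cost_range(corr, n_random=10, seed=0)
print(f"functional network: retained costs {fns.costs[0]}..{fns.costs[-1]} "
      f"({len(fns.costs)} costs where small-world sigma > 1.1)")
func = average_metrics_over_costs(fns.adjacencies)

vec = assemble_feature_vector(struct, func)
print(f"feature vector length: {len(vec)} "
      "(5 nodal metrics x 78 structural + x 59 functional nodes)")
print("first entries:")
print(vec.head(3).to_string(float_format="%.3f"))
print("highest-strength structural node:",
      vec.filter(like="struct_strength").idxmax())
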