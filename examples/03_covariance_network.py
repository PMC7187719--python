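"""Build a structural covariance network and threshold it by density.

One cohort cell's regional thickness values are correlated across
subjects to give a 68 x 68 covariance network; the network is then
binarized at the minimum density that keeps it fully connected and at
the default analysis threshold (0.50).
"""

from morphnet import (CohortConfig, build_covariance_network, generate_cohort,
                      graph_density, min_connected_density, threshold_to_density)

cohort = generate_cohort(CohortConfig(n_subjects_per_cell=40, seed=1))
net = build_covariance_network(cohort.table("CT", "HC", "3T"))

print(f"covariance matrix: {net.matrix.shape}, "
      f"off-diagonal range [{net.matrix.min():.2f}, 1.00]")

d_min = min_connected_density(net)
print(f"minimum fully-connected density: {d_min:.2f}")

g = threshold_to_density(net, 0.50)
print(f"graph at density 0.50: {g.number_of_edges()} edges "
      f"(achieved density {graph_density(g):.4f})")
print("\nEdges keep the strongest inter-regional correlations; densities on")
print("the analysis grid (0.50-0.69) are all above the connectivity floor.")
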