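"""Inferring a sex-specific mutual-information expression network.

Standardizes each gene's profile across one sex's samples, estimates
kernel MI (Gaussian kernels, bandwidth 0.3) for all pairs, keeps edges
beating a pooled permutation null at p < 0.005, and summarizes topology.
Significance of the clustering coefficient is assessed against a
degree-preserving edge-shuffle null.
"""

import networkx as nx
import numpy as np

import dosagenet as d
from dosagenet import network as net

study = d.generate_study(n_genes=300, genes_per_df=2, coexpression_weight=0.45,
                         coexpression_per="sample", seed=21)
z = net.standardize(study.expression, "female")
print(f"standardized female matrix: {z.shape[0]} genes x {z.shape[1]} samples")

edges = net.edge_significance(z, h=0.3, n_perm=2000, seed=22, alpha=0.005)
g = net.build_network(edges, alpha=0.005, nodes=z.index)
topo = net.topology_stats(g)
print(f"\nMI network (edges at permutation p < 0.005): {topo.n_edges} edges")
print(f"  clustering coefficient = {topo.clustering_coefficient:.3f}")
print(f"  average neighbors      = {topo.average_neighbors:.2f}")
print(f"  density                = {topo.density:.4f}")
print(f"  power-law slope        = {topo.power_law_exponent:.2f} "
      "(log-log degree-frequency fit; negative slope = scale-free-like)")

planted = {frozenset(e) for e in study.truth.edges}
found = {frozenset(e) for e in g.edges()}
deg = {v: 0 for v in z.index}
for a, b in study.truth.edges:
    deg[a] += 1
    deg[b] += 1
low = [e for e in study.truth.edges if max(deg[e[0]], deg[e[1]]) <= 2]
recall_low = np.mean([frozenset(e) in found for e in low])
print(f"\nplanted-edge recall (low-degree pairs) = {recall_low:.2f}; "
      f"non-planted edges = {len(found - planted)}")
print("  -> pairwise MI recovers strongly coupled pairs; hub edges dilute the")
print("     hub's variance across neighbors and sit near the estimator floor")

shuffle = net.degree_preserving_shuffle(
    g, nx.average_clustering, n_randomizations=100, seed=23
)
print(f"\nclustering vs degree-preserving null: observed {shuffle['observed']:.3f}, "
      f"null mean {shuffle['null'].mean():.3f}, p = {shuffle['p_greater']:.3f}")
print("  -> the shuffle keeps every gene's degree; excess clustering therefore")
print("     reflects genuine local structure, not the degree sequence")
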