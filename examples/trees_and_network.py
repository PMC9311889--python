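"""Distance trees and a median-joining haplotype network.

Simulates a structured sample, builds the UPGMA population tree (K2P
dxy distances) with bootstrap supports, an NJ haplotype tree, and the
median-joining network with frequency node weights.
"""

from mitopop import (
    SimConfig,
    ancestral_weights,
    bootstrap_support,
    collapse_haplotypes,
    haplotype_distance_matrix,
    median_joining,
    neighbor_joining,
    simulate_dataset,
    write_newick,
)
from mitopop.network import edge_list

aln, _ = simulate_dataset(
    SimConfig(scenario="island", n_per_pop=(15, 15, 15, 15),
              theta=3.0, M=0.5),
    seed=11,
)
tab = collapse_haplotypes(aln)

boot = bootstrap_support(aln, tree_method="upgma", B=200, seed=1)
print("UPGMA population tree (internal labels = bootstrap %):")
print(write_newick(boot))

hap_d = haplotype_distance_matrix(tab, "k2p")
print("\nNJ haplotype tree (K2P distances):")
print(write_newick(neighbor_joining(hap_d)))

g = median_joining(tab)
print("\nmedian-joining network edges (steps = substitutions):")
print(edge_list(g))
w = ancestral_weights(tab).sort_values(ascending=False).round(4)
print("node weights (pooled frequencies, highest = ancestral candidate):")
print(w.head(4).to_string())
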