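"""Build the mutation, expression and integrative networks.

Vertex weights: coverage h_i = m_i/m on the mutation side, influence
f_i = 1 - mean differential-expression p-value on the expression side.
Edge weights: mutual exclusivity v_ij and absolute correlation u_ij of
mutation-ordered expression.  The integrative network balances the two
sources through constants xi, eta, delta derived from the weight maxima.
"""

import itertools

from coremod import (PlantConfig, build_binary_mutation_matrix,
                     build_expression_network, build_mutation_network,
                     collapse_metagenes, compute_gene_universe,
                     generate_dataset, integrate_networks)

somatic, cnv, expression, truth = generate_dataset(PlantConfig(seed=11))
a = collapse_metagenes(build_binary_mutation_matrix(somatic, cnv))
universe = compute_gene_universe(a, expression)
print(f"|S| = {len(universe.samples)} common samples, "
      f"|G0| = {len(universe.g0)} units with expression, "
      f"|G| = {len(universe.units)} units after the group-size filter")

en = build_expression_network(a, expression, universe)
mn = build_mutation_network(a, universe)
net = integrate_networks(en, mn, k=1.0)
print("balancing constants:",
      {k: round(v, 3) for k, v in net.constants.items()})

trio = [u for u in truth.modules[0] if u in universe.units]
print("\nplanted drivers (high coverage, high influence):")
for u in trio:
    print(f"  {u}: h = {mn.vertex_weight[u]:.3f}, f = {en.vertex_weight[u]:.3f}, "
          f"c = {net.vertex_weight[u]:.3f}")
print("planted pairs (v = 1 means perfectly exclusive):")
for i, j in itertools.combinations(trio, 2):
    print(f"  {i}-{j}: v = {mn.edge_weight.loc[i, j]:.3f}, "
          f"u = {en.edge_weight.loc[i, j]:.3f}, "
          f"w = {net.edge_weight.loc[i, j]:.3f}")
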