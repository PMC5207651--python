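"""Full pipeline on the karate club: communities, cores and outliers.

Runs detection with defaults (gap threshold, greedy sub-graph-density
expansion, re-seeding completion, refinement), prints each community
with its seed center and sub-graph density D_C, the partition modularity
Q, and the per-community border density rho_b that splits members into
cores (rho >= rho_b) and outliers.
"""

import lccd

g = lccd.karate_fixture()
table = lccd.structural_centrality(g)
partition = lccd.detect_communities(g)
roles = lccd.assign_roles(g, partition, table.rho)

print(f"Q = {lccd.modularity(g, partition):.4f}  ({len(partition)} communities)\n")
for c in partition.communities:
    members = sorted(c.members, key=int)
    outliers = sorted((v for v in c.members if roles.role[v] == "outlier"), key=int)
    print(f"community {c.id}: center={c.center} size={len(c)} "
          f"D_C={c.density:.3f} rho_b={roles.border_density[c.id]:.1f}")
    print(f"  members:  {' '.join(members)}")
    print(f"  outliers: {' '.join(outliers) if outliers else '(none)'}")
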