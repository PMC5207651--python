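"""Decision graph of the Zachary karate club.

Computes per-node density rho, relative distance delta and structural
centrality sc = rho * delta, then locates the community structural
centers with the automatic gap threshold. The two club leaders emerge:
the instructor (node 34, rho=17, delta=4) and the administrator
(node 1, rho=16, delta=2); every other member sits within one hop of
someone denser (delta = 1).
"""

import lccd

g = lccd.karate_fixture()
table = lccd.structural_centrality(g)  # d_c = 1: density is degree

print("node  rho  delta    sc")
for v in table.nodes_by_sc()[:5]:
    print(f"{v:>4} {table.rho[v]:>4} {table.delta[v]:>6} {table.sc[v]:>5.0f}")

eps = lccd.select_threshold(table, method="gap")
centers = lccd.locate_centers(g, table, eps)
print(f"\ngap threshold epsilon = {eps}")
print(f"located centers: {centers.centers}  (k = {centers.k})")
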