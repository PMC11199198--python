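"""Fit a common + differential network on simulated two-condition data.

Simulates a sparse Gaussian graphical model whose structure is partly
rewired between two conditions, fits the fused-lasso neighborhood model at
a manual penalty pair, and prints the recovered edges by class.
"""

from collections import Counter

from fusedggm import (
    RegularizationPair,
    SimulationSpec,
    differential_edges,
    fit_differential_network,
    simulate_study,
    standardize,
)

spec = SimulationSpec("random", p=20, n1=80, n2=80,
                      rewire_fraction=0.2, seed=1)
truth, pair = simulate_study(spec)
std = standardize(pair)

# lambda1 controls overall sparsity; lambda2 penalizes cross-condition
# coefficient differences, so only well-supported rewirings survive
reg = RegularizationPair(lambda1=0.2, lambda2=0.05)
net = fit_differential_network(std, reg)

counts = Counter(e.edge_class for e in net.edges)
print(f"p={std.p} features, N1={std.n1}, N2={std.n2}, "
      f"lambda=({reg.lambda1}, {reg.lambda2})")
print(f"{len(net.edges)} edges: {dict(counts)}")
print("differential edges (presence or strength differs between conditions):")
for e in differential_edges(net)[:8]:
    print(f"  {e.node_a} -- {e.node_b}: beta1={e.beta1:+.3f} "
          f"beta2={e.beta2:+.3f} [{e.edge_class}]")
print("Common edges have bitwise-equal coefficients (exact fusion); "
      "condition-specific edges are exactly zero in the other condition.")
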