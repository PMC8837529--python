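"""Generate a multifactorial expression dataset and write it to disk in the
tab-separated benchmark dialect, together with its gold-standard edge list.

Each sample perturbs a random handful of nodes with hidden basal shifts and
observes the network's steady state with measurement noise — the clinical
analogue where every patient differs in unknown ways.
"""

from pathlib import Path

from dekernet import SimulationConfig, sample_network, simulate_multifactorial
from dekernet.io import write_edge_list, write_expression_tsv

out = Path("simulated")
out.mkdir(exist_ok=True)

net = sample_network(n_nodes=30, mean_degree=2.0, seed=1)
data, gold = simulate_multifactorial(
    net, SimulationConfig(n_samples=100, perturbation_count=(3, 10), seed=2)
)

write_expression_tsv(data, out / "expression.tsv")
write_edge_list(gold, out / "gold.tsv")

print(f"network : {net.n_nodes} nodes, {net.n_edges} directed edges "
      f"({len(gold.true_edges)} undirected pairs)")
print(f"dataset : {data.n_samples} samples x {data.n_features} features")
print(f"written : {out/'expression.tsv'} and {out/'gold.tsv'}")

# The same files work with the command line:
#   dekernet infer simulated/expression.tsv --out net.tsv
#   dekernet eval net.tsv simulated/gold.tsv --pr-out pr.tsv
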