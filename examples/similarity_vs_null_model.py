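"""Compare walk sets between a network and its randomized surrogate.

Extracts temporal sequences from a geometric network and from a Gilbert
(edge-density-matched) surrogate, then counts how many reference walks
survive in the surrogate at increasing match thresholds alpha.
"""

import numpy as np

from tseqnet import (
    SignalingParams,
    extract_tseqs,
    gilbert_randomize,
    run_simulation,
    similarity_table,
)
from tseqnet import fixtures as fx

params = SignalingParams(
    conduction_velocity=1.0, refractory_period=4.0, dt=1.0, n_steps=250
)
fixture = fx.make_random_geometric(
    n=35, p=0.09, seed=1, n_steps=250, inhibitory_fraction=0.1, params=params
)
net = fixture.network
log = run_simulation(net, fixture.delays, params, fixture.stimuli)
X = extract_tseqs(log, fixture.start_node, fixture.end_nodes, max_paths=10000)

g_net, report = gilbert_randomize(net, seed=2)
rng = np.random.default_rng(3)
g_delays = {e: int(rng.integers(1, 6)) for e in sorted(g_net.edges)}
g_log = run_simulation(g_net, g_delays, params, fixture.stimuli)
Y = extract_tseqs(g_log, fixture.start_node, fixture.end_nodes, max_paths=10000)

table = similarity_table(X, Y)
print(f"reference walks |X| = {table.n_reference}, "
      f"surrogate walks |Y| = {table.n_comparison}")
print("alpha  walks-of-X-matched")
for alpha, count in zip(table.alphas, table.counts):
    print(f"{alpha:5.2f}  {count}")
print(
    "-> at alpha = 0 every reference walk trivially matches; as alpha "
    "rises toward exact-order matching, the randomized wiring preserves "
    "almost none of the original signaling pathways."
)
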