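"""Combine simulated edge-confidence sources with every closed-form combiner.

Simulates a ground-truth network and five Beta-distributed sources, then
builds Noisy-OR, product and mean consensus priors (plus their rank-based
variants) and scores each against the truth.
"""

import numpy as np

from netprior import (
    BetaSourceParams,
    combine,
    obac,
    random_walk_subnetwork,
    scale_free_seed_graph,
    simulate_sources,
)

rng = np.random.default_rng(0)

seed_graph = scale_free_seed_graph(200, rng)
truth = random_walk_subnetwork(seed_graph, 20, rng)
print(f"truth network: {truth.m} nodes, {truth.n_edges} edges")

params = BetaSourceParams(np.full(5, 10.0), np.full(5, 10.0))
thetas = simulate_sources(truth, params, rng)

for method in ("NOM", "NOM.RNK", "IP", "IP.RNK", "MP", "MP.RNK"):
    prior = combine(method, thetas)
    print(f"{method:8s} oBAC = {obac(prior.values, truth):.3f}")
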