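"""Shared construction helpers for solver oracle tests."""

import numpy as np

from netsynergy.io import PPINetwork


def random_ppi(rng, n_nodes, p_edge=0.5):
    """Random connected-ish PPI with uniform evidence, for solver oracles."""
    names = [f"N{i:02d}" for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                edges.append((names[i], names[j], float(rng.uniform(0.05, 0.95))))
    # spanning chain so every node is reachable
    for i in range(n_nodes - 1):
        edges.append((names[i], names[i + 1], float(rng.uniform(0.05, 0.95))))
    return PPINetwork.from_edges(edges)


def random_prizes(rng, ppi, scale=40.0):
    return {
        n: float(rng.uniform(0, scale)) if rng.random() < 0.6 else 0.0
        for n in sorted(ppi.nodes)
    }
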