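import dataclasses

import numpy as np
import pytest

from pleionet import lifecycle as lc
from pleionet import model_core as mc
from pleionet.config import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240605)


@pytest.fixture
def schedule():
    return lc.SignallingSchedule()


@pytest.fixture
def tiny_config():
    """A miniature but fully wired configuration for fast end-to-end runs."""
    return dataclasses.replace(
        SimulationConfig(),
        host_population=40,
        parasite_population=20,
        burn_in_host_population=20,
        burn_in_parasite_population=10,
        competition_host_population=80,
        competition_parasite_population=20,
        generations=10,
        burn_in_generations=3,
        competition_generations=5,
    )


# ---------------------------------------------------------------------------
# independent scalar oracle for the dynamics
# ---------------------------------------------------------------------------

def oracle_deltas(nodes, active, edges, use_coef):
    """Literal per-node evaluation of the activation equations.

    ``edges`` is a plain list of (source, target, coefficient); positive
    coefficients feed the upregulatory sum, magnitudes of negative ones the
    downregulatory sum, and each node pays use_coef per outgoing edge.
    """
    deltas = {}
    for node in nodes:
        up = sum(c * active[s] for (s, t, c) in edges if t == node and c >= 0)
        down = sum(-c * active[s] for (s, t, c) in edges if t == node and c < 0)
        out = sum(1 for (s, t, c) in edges if s == node)
        deltas[node] = (
            (1.0 - active[node]) * up - active[node] * down - use_coef * out
        )
    return deltas


def oracle_step(nodes, active, edges, use_coef, limit):
    """One capped, clamped Euler step computed without any vectorization."""
    deltas = oracle_deltas(nodes, active, edges, use_coef)
    positive = sum(v for v in deltas.values() if v > 0)
    if positive > limit:
        scale = limit / positive
        deltas = {k: (v * scale if v > 0 else v) for k, v in deltas.items()}
    return {k: min(1.0, max(0.0, active[k] + deltas[k])) for k in nodes}


def random_toy_host(rng, n_max=6):
    """A small host-shaped container with arbitrary wiring for dynamics tests."""
    n = int(rng.integers(2, n_max + 1))
    proteins = tuple(mc.Protein(i, mc.SIGNAL, mc.IMMUNE) for i in range(n))
    edges = []
    for s in range(n):
        for t in range(n):
            if rng.random() < 0.5:
                edges.append(mc.RegulatoryEdge(s, t, float(rng.uniform(-1, 1))))
    return mc.Host(mc.INDEPENDENT, proteins, tuple(edges))
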