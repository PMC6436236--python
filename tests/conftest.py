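"""Shared fixtures: small hand-built graphs and one planted-module world."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from gwasnet.apcst import ApcstConfig, Interactome, PrizeMap, load_interactome
from gwasnet.fixtures import FixtureConfig, simulate_interactome


def make_interactome(edges):
    """Interactome from (a, b, cost) triples (confidence fixed at 0.9)."""
    g = nx.Graph()
    for a, b, cost in edges:
        g.add_edge(a, b, confidence=0.9, cost=float(cost))
    return Interactome(graph=g)


def random_instance(n, p, rng, beta_prizes=(0.0, 1.0)):
    """Random connected G(n, p) with U(0,1) costs and prizes."""
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    lo, hi = beta_prizes
    inter = make_interactome(
        (f"n{a:02d}", f"n{b:02d}", rng.uniform(0, 1)) for a, b in g.edges
    )
    prizes = PrizeMap(
        prizes={f"n{i:02d}": float(rng.uniform(lo, hi)) for i in range(n)}
    )
    return inter, prizes


@pytest.fixture
def path_interactome():
    """A(p=1) - B(p=0) - C(p=1) path, both edge costs 0.5."""
    inter = make_interactome([("A", "B", 0.5), ("B", "C", 0.5)])
    prizes = PrizeMap(prizes={"A": 1.0, "B": 0.0, "C": 1.0})
    return inter, prizes


@pytest.fixture(scope="session")
def planted_world():
    """One planted-module interactome with seeds = half the module."""
    cfg = FixtureConfig(seed=0)
    fx = simulate_interactome(cfg, seed=0)
    inter = load_interactome(fx.edges)
    rng = np.random.default_rng(1000)
    seeds = sorted(rng.choice(fx.module, size=len(fx.module) // 2, replace=False).tolist())
    prizes = PrizeMap(prizes={s: float(rng.uniform(0.2, 0.8)) for s in seeds})
    return {
        "config": cfg,
        "fixture": fx,
        "interactome": inter,
        "seeds": seeds,
        "unseeded": [m for m in fx.module if m not in seeds],
        "prizes": prizes,
        "apcst_config": ApcstConfig(beta=8.0, seed=42),
    }
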