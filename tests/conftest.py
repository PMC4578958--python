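import numpy as np
import pytest

from scaffoldscan import (
    CompositeNetwork,
    KSRNetwork,
    PPINetwork,
    SyntheticConfig,
    build_composite,
)


@pytest.fixture
def toy_composite() -> CompositeNetwork:
    """X interacts with every member of the cascade A -> B -> C."""
    ppi = PPINetwork([("X", "A"), ("X", "B"), ("X", "C")])
    ksr = KSRNetwork([("A", "B"), ("B", "C")])
    return build_composite(ppi, ksr)


@pytest.fixture
def small_config() -> SyntheticConfig:
    """Down-scaled synthetic config for fast unit tests."""
    return SyntheticConfig(
        n_proteins=300,
        n_kinases=30,
        cascades=(2, 3, 4, 5),
        n_background_ksr=15,
        n_planted_scaffolds=6,
        seed=42,
    )


def random_ppi(n_nodes: int, p: float, rng: np.random.Generator) -> PPINetwork:
    """Erdos-Renyi PPI over string ids, no self-pairs."""
    net = PPINetwork()
    ids = [f"N{i}" for i in range(n_nodes)]
    for q in ids:
        net.add_protein(q)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                net.add_edge(ids[i], ids[j])
    return net


def random_ksr(n_nodes: int, p: float, rng: np.random.Generator) -> KSRNetwork:
    """Random directed graph over string ids (cycles allowed), no self-edges."""
    net = KSRNetwork()
    ids = [f"N{i}" for i in range(n_nodes)]
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < p:
                net.add_edge(ids[i], ids[j])
    return net
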