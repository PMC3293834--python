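import numpy as np
import pytest

from gifilters import (GIEdge, HomologMap, HomologRecord, MotifPrediction,
                       WorldConfig, build_network, simulate_world)


def make_motif(mid, s, t, activity="binds", **kw):
    return MotifPrediction(motif_id=mid, source_protein=s, target_protein=t,
                           activity=activity, **kw)


def random_network(rng, n_nodes, n_edges, prefix="n"):
    """Random simple graph as (edges, gene names); may be disconnected."""
    genes = [f"{prefix}{i}" for i in range(n_nodes)]
    edges, seen = [], set()
    while len(edges) < n_edges:
        i, j = rng.integers(0, n_nodes, size=2)
        if i == j:
            continue
        key = frozenset((i, j))
        if key in seen:
            continue
        seen.add(key)
        edges.append(GIEdge(genes[i], genes[j]))
    return edges, genes


@pytest.fixture
def rng():
    return np.random.default_rng(20120326)


@pytest.fixture(scope="session")
def small_world():
    """A modest synthetic world shared across read-only tests."""
    cfg = WorldConfig(n_genes=300, n_species=3, n_positive_motifs=600,
                      n_negative_pairs=2000, background_edge_prob=0.001,
                      seed=11)
    return simulate_world(cfg)


@pytest.fixture
def toy_net():
    """Path a-b-c-d plus alias CDK1 -> a and shared alias twin -> {c, d}."""
    from gifilters import AliasRecord
    edges = [GIEdge("a", "b"), GIEdge("b", "c"), GIEdge("c", "d")]
    aliases = [AliasRecord("a", "CDK1"), AliasRecord("c", "twin"),
               AliasRecord("d", "twin")]
    return build_network(edges, aliases)


@pytest.fixture
def fly_homology():
    """Two 2-species clusters: {s, s_fly}, {t, t_fly}."""
    return HomologMap.from_records([
        HomologRecord("C1", "human", "s"), HomologRecord("C1", "fly", "s_fly"),
        HomologRecord("C2", "human", "t"), HomologRecord("C2", "fly", "t_fly"),
    ])
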