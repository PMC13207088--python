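import networkx as nx
import pytest
from hypothesis import settings

import bridgenet as bn
from bridgenet import io as bio

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

#: the published bridge endpoints: CKD-side and PD-side gene symbols
CKD_GENES = ("FN1", "APOA1", "UMOD", "ACE", "WT1")
PD_GENES = ("TNF", "INS", "IL6", "SNCA", "IL1B", "AKT1", "IGF2", "SOD1", "MAPK1")


@pytest.fixture(scope="session")
def published_bridges():
    return bio.load_bridge_fixture()


@pytest.fixture(scope="session")
def study_shaped():
    """Synthetic inputs at the published study conditions.

    64 PD + 17 CKD disjoint genes (including the named bridge endpoints),
    the packaged bridge fixture embedded as the planted cross-set edges,
    265 within-set edges (280 total at the 0.700 cutoff) plus sub-threshold
    cross-set distractors and background genes.
    """
    cfg = bn.SyntheticConfig(
        include_set_a=PD_GENES, include_set_b=CKD_GENES, seed=7
    )
    sets, assocs = bn.generate_gene_sets(cfg)
    edges, planted = bn.generate_interactome(
        cfg, sets, planted_edges=bio.load_bridge_fixture()
    )
    return cfg, sets, assocs, edges, planted


def random_graph(n: int, p: float, seed: int):
    """A seeded Erdos-Renyi graph with string labels plus its edge set."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    g = nx.relabel_nodes(g, {i: f"G{i:02d}" for i in g.nodes})
    edge_set = {frozenset(e) for e in g.edges}
    return g, sorted(g.nodes), edge_set
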