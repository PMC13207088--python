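"""Hub ranking by Maximal Clique Centrality (MCC), degree and betweenness.

MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!. A maximal
clique of size 2 contributes 1! = 1 per edge, so a node whose neighborhood
contains no internal edge scores exactly its degree, and an isolated node
scores 0 — the degree fallback is the formula's own limit, not a special
case. Factorials are exact Python integers, so large cliques cannot
overflow.

Betweenness is unnormalized shortest-path betweenness (endpoints excluded);
only ranks are consumed downstream.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import networkx as nx

from .datamodel import DiseaseNetwork, HubScore, ValidationError
from .interactome import to_graph

__all__ = ["enumerate_maximal_cliques", "mcc_scores", "top_hubs"]

logger = logging.getLogger(__name__)


def enumerate_maximal_cliques(net: DiseaseNetwork | nx.Graph) -> list[frozenset[str]]:
    """All maximal cliques of size >= 2 (pivoting Bron-Kerbosch)."""
    g = net if isinstance(net, nx.Graph) else to_graph(net)
    return [frozenset(c) for c in nx.find_cliques(g) if len(c) >= 2]


def mcc_scores(net: DiseaseNetwork | nx.Graph) -> list[HubScore]:
    """MCC, degree and betweenness per node, ranked by MCC.

    Ties break by degree (descending) then gene symbol; ranks are 1..N.
    """
    g = net if isinstance(net, nx.Graph) else to_graph(net)
    mcc = {v: 0 for v in g.nodes}
    for clique in enumerate_maximal_cliques(g):
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            mcc[v] += contrib
    betweenness = nx.betweenness_centrality(g, normalized=False)
    ordered = sorted(g.nodes, key=lambda v: (-mcc[v], -g.degree(v), v))
    return [
        HubScore(
            gene_symbol=v,
            mcc=mcc[v],
            degree=g.degree(v),
            betweenness=betweenness[v],
            rank_mcc=i,
        )
        for i, v in enumerate(ordered, start=1)
    ]


def top_hubs(scores: Sequence[HubScore], k: int = 10) -> list[HubScore]:
    """First k hub scores by MCC rank."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if k > len(scores):
        logger.warning("requested top %d hubs from %d nodes; returning all", k, len(scores))
    return sorted(scores, key=lambda h: h.rank_mcc)[:k]
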