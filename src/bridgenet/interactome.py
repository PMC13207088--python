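"""Network construction, topology metrics and edge-enrichment statistics.

The combined interaction score follows the STRING convention: each evidence
channel score s is corrected for the prior probability p0 of a random pair
interacting, s' = max(0, (s - p0) / (1 - p0)); the corrected scores are
combined as independent probabilities, S' = 1 - prod(1 - s'); and the prior
is added back, S = S' * (1 - p0) + p0 (0 when no channel exceeds the prior).
The default prior is 0.041.

Edge enrichment of the disease module is quantified against either an
analytic Poisson null (given an expected edge count) or a degree-preserving
double-edge-swap permutation null over the full candidate edge set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .datamodel import (
    ChannelScores,
    DiseaseGeneSets,
    DiseaseNetwork,
    InteractionEdge,
    NetworkSummary,
    ValidationError,
)

__all__ = [
    "DEFAULT_PRIOR",
    "NullModelConfig",
    "combine_channel_scores",
    "build_network",
    "to_graph",
    "summarize_topology",
    "swap_null_replicates",
    "ppi_enrichment",
]

DEFAULT_PRIOR = 0.041


@dataclass(frozen=True)
class NullModelConfig:
    """Configuration of the edge-enrichment null model.

    ``analytic_poisson`` needs an expected edge count (override or swap-null
    mean); ``degree_preserving_swap`` rewires the candidate graph with
    ``swaps_per_edge`` attempted double-edge swaps per edge per replicate.
    """

    method: Literal["analytic_poisson", "degree_preserving_swap"] = "analytic_poisson"
    n_replicates: int = 1000
    swaps_per_edge: int = 100
    seed: int = 0
    prior: float = DEFAULT_PRIOR

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if not (0 <= self.prior < 1):
            raise ValidationError("prior must lie in [0, 1)")


def combine_channel_scores(
    channels: ChannelScores, prior: float = DEFAULT_PRIOR
) -> float:
    """Combine per-channel evidence scores into a single probability.

    Monotone non-decreasing in every channel, symmetric across channels, and
    bounded in [0, 1). Returns 0 when no channel exceeds the prior.
    """
    if not (0 <= prior < 1):
        raise ValidationError(f"prior must lie in [0, 1), got {prior}")
    corrected = [
        max(0.0, (s - prior) / (1.0 - prior)) for s in channels.as_tuple()
    ]
    if all(c == 0.0 for c in corrected):
        return 0.0
    one_minus = math.prod(1.0 - c for c in corrected)
    combined_corrected = 1.0 - one_minus
    return combined_corrected * (1.0 - prior) + prior


def build_network(
    sets: DiseaseGeneSets,
    edges: Iterable[InteractionEdge],
    cutoff: float = 0.700,
) -> DiseaseNetwork:
    """Keep edges scoring >= cutoff with both endpoints in the gene-set union.

    Isolated genes remain as network nodes. The cutoff comparison is
    inclusive, matching a "minimum required interaction score".
    """
    union = sets.union
    if not union:
        raise ValidationError("cannot build a network over empty gene sets")
    kept = tuple(
        sorted(
            (
                e
                for e in edges
                if e.combined_score >= cutoff
                and e.gene_a in union
                and e.gene_b in union
            ),
            key=lambda e: e.pair,
        )
    )
    return DiseaseNetwork(gene_sets=sets, edges=kept, confidence_cutoff=cutoff)


def to_graph(net: DiseaseNetwork) -> nx.Graph:
    """The network as an undirected simple graph including isolated nodes."""
    g = nx.Graph()
    g.add_nodes_from(sorted(net.nodes))
    g.add_edges_from(
        (e.gene_a, e.gene_b, {"combined_score": e.combined_score}) for e in net.edges
    )
    return g


def summarize_topology(net: DiseaseNetwork) -> NetworkSummary:
    """Node/edge counts, average degree 2E/N and mean local clustering.

    Nodes of degree < 2 contribute 0 to the clustering coefficient.
    """
    g = to_graph(net)
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValidationError("cannot summarize an empty network")
    return NetworkSummary(
        n_nodes=n,
        n_edges=m,
        average_degree=2.0 * m / n,
        clustering_coefficient=nx.average_clustering(g, count_zeros=True),
    )


def swap_null_replicates(g: nx.Graph, null: NullModelConfig):
    """Yield degree-preserving rewired copies of ``g``, one per replicate.

    Each copy is produced by ``swaps_per_edge * m`` attempted double edge
    swaps of a fresh copy of ``g``; every node keeps its degree exactly.
    Graphs with fewer than 2 edges admit no swap and are yielded unchanged.
    """
    m = g.number_of_edges()
    rng = np.random.default_rng(null.seed)
    nswap = null.swaps_per_edge * max(m, 1)
    for _ in range(null.n_replicates):
        h = g.copy()
        if m >= 2:
            seed = int(rng.integers(0, 2**31 - 1))
            nx.double_edge_swap(h, nswap=nswap, max_tries=100 * nswap + 100, seed=seed)
        yield h


def _swap_null_internal_edges(
    candidate_edges: Sequence[InteractionEdge],
    module_nodes: frozenset[str],
    cutoff: float,
    null: NullModelConfig,
) -> np.ndarray:
    """Per-replicate counts of supra-cutoff edges internal to the module.

    The full supra-cutoff candidate graph (module plus background genes) is
    rewired with degree-preserving double edge swaps; each replicate counts
    the edges with both endpoints inside the module.
    """
    g = nx.Graph()
    for e in candidate_edges:
        if e.combined_score >= cutoff:
            g.add_edge(e.gene_a, e.gene_b)
    return np.array(
        [
            sum(1 for a, b in h.edges if a in module_nodes and b in module_nodes)
            for h in swap_null_replicates(g, null)
        ],
        dtype=int,
    )


def ppi_enrichment(
    net: DiseaseNetwork,
    null: NullModelConfig | None = None,
    expected_edges_override: float | None = None,
    candidate_edges: Sequence[InteractionEdge] | None = None,
) -> tuple[float, float, float]:
    """Edge enrichment of the observed network versus a random expectation.

    Returns (expected_edges, fold_enrichment, p_value). In analytic mode the
    expected count lambda comes from ``expected_edges_override`` (or, when
    candidate edges are supplied, the swap-null mean) and p is the Poisson
    upper tail Pr(X >= E). In permutation mode p is the add-one permutation
    p-value over degree-preserving rewired replicates.
    """
    null = null or NullModelConfig()
    g_edges = len(net.edges)
    if not net.nodes:
        raise ValidationError("cannot test an empty network")

    counts = None
    if expected_edges_override is not None:
        lam = float(expected_edges_override)
    else:
        if candidate_edges is None:
            raise ValidationError(
                "permutation null needs the full candidate edge set; supply "
                "candidate_edges or expected_edges_override"
            )
        counts = _swap_null_internal_edges(
            candidate_edges, net.nodes, net.confidence_cutoff, null
        )
        lam = float(counts.mean())

    fold = g_edges / lam if lam > 0 else math.inf

    if null.method == "analytic_poisson" or counts is None:
        if lam == 0:
            # no random expectation: any observed edge is infinitely enriched
            p = 0.0 if g_edges > 0 else 1.0
        else:
            p = float(stats.poisson.sf(g_edges - 1, lam))
    else:
        p = (1 + int((counts >= g_edges).sum())) / (1 + null.n_replicates)
    return lam, fold, p
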