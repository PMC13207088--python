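"""End-to-end orchestration: curation -> network -> bridges -> hubs -> ORA.

``run_pipeline`` is a pure function of (inputs, parameters): identical
inputs and parameters give identical results, which is what makes the
threshold-sensitivity grid and the deterministic report writer possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

from .bridges import extract_bridges, prioritize_bridges, theme_tally
from .curation import OverlapReport, check_overlap, filter_associations
from .datamodel import (
    AnnotationSet,
    BridgeRecord,
    DiseaseGeneSets,
    DiseaseNetwork,
    EnrichmentResult,
    GeneDiseaseAssociation,
    HubScore,
    InteractionEdge,
    NetworkSummary,
)
from .enrichment import hypergeometric_ora
from .hubs import mcc_scores, top_hubs
from .interactome import (
    NullModelConfig,
    build_network,
    ppi_enrichment,
    summarize_topology,
)

__all__ = ["PipelineParams", "PipelineResults", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """Thresholds for every stage; defaults are the study's settings."""

    label_a: str = "PD"
    label_b: str = "CKD"
    score_min_a: float = 0.8
    ei_min_a: float = 0.4
    score_min_b: float = 0.6
    ei_min_b: float = 0.4
    confidence_cutoff: float = 0.700
    bridge_min_score: float = 0.700
    bridge_high_score: float = 0.800
    top_k_hubs: int = 10


@dataclass(frozen=True)
class PipelineResults:
    gene_sets: DiseaseGeneSets
    overlap: OverlapReport
    network: DiseaseNetwork
    summary: NetworkSummary
    bridges: tuple[BridgeRecord, ...]
    themes: dict[str, int]
    hub_scores: tuple[HubScore, ...]
    top_hubs: tuple[HubScore, ...]
    enrichment: tuple[EnrichmentResult, ...] = field(default_factory=tuple)


def run_pipeline(
    assocs: Sequence[GeneDiseaseAssociation],
    edges: Sequence[InteractionEdge],
    params: PipelineParams = PipelineParams(),
    terms: Sequence[AnnotationSet] | None = None,
    theme_map: dict[str, frozenset[str]] | None = None,
    null: NullModelConfig | None = None,
    expected_edges_override: float | None = None,
) -> PipelineResults:
    """Run curation through enrichment on in-memory inputs.

    ``edges`` is the full candidate edge table (it may include background
    genes; the network keeps only disease-set edges at the cutoff, and the
    permutation null rewires the whole candidate set). Enrichment runs only
    when ``terms`` is supplied; its universe is the network node set.
    """
    set_a = filter_associations(assocs, params.label_a, params.score_min_a, params.ei_min_a)
    set_b = filter_associations(assocs, params.label_b, params.score_min_b, params.ei_min_b)
    # symbols passing both filters would make bridge orientation ambiguous;
    # assign them to neither side, mirroring the disjointness the analysis assumes
    shared = set_a & set_b
    if shared:
        logger.warning("%d genes pass both disease filters; excluded: %s",
                       len(shared), sorted(shared)[:5])
        set_a, set_b = set_a - shared, set_b - shared
    sets = DiseaseGeneSets(params.label_a, set_a, params.label_b, set_b)
    overlap = check_overlap(sets)

    net = build_network(sets, edges, params.confidence_cutoff)
    summary = summarize_topology(net)

    if expected_edges_override is not None or null is not None:
        lam, fold, p = ppi_enrichment(
            net,
            null,
            expected_edges_override=expected_edges_override,
            candidate_edges=edges if expected_edges_override is None else None,
        )
        summary = replace(
            summary, expected_edges_null=lam, fold_enrichment=fold, ppi_enrichment_p=p
        )

    ranked = prioritize_bridges(
        extract_bridges(net, params.bridge_min_score), params.bridge_high_score
    )
    themes = dict(theme_tally(ranked, theme_map)) if theme_map is not None else {}

    scores = mcc_scores(net)
    top = top_hubs(scores, min(params.top_k_hubs, len(scores)) or 1)

    enrich: tuple[EnrichmentResult, ...] = ()
    if terms is not None:
        query = {g for b in ranked for g in (b.source_set_gene, b.target_set_gene)}
        enrich = tuple(hypergeometric_ora(query, list(terms), net.nodes))

    return PipelineResults(
        gene_sets=sets,
        overlap=overlap,
        network=net,
        summary=summary,
        bridges=tuple(ranked),
        themes=themes,
        hub_scores=tuple(scores),
        top_hubs=tuple(top),
        enrichment=enrich,
    )
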