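"""Domain types for cross-disease interactome analysis.

The pipeline operates on four kinds of evidence: gene-disease association
scores (DisGeNET-style, a [0,1] confidence plus an Evidence Index), scored
protein-protein interaction edges (STRING-style, seven evidence channels
combined into a single probability), gene-set annotations (GMT), and tissue
expression (TPM). Each record type validates its own invariants on
construction so that malformed data fails at the boundary, not mid-pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

__all__ = [
    "CHANNELS",
    "ValidationError",
    "FormatError",
    "GeneDiseaseAssociation",
    "ChannelScores",
    "InteractionEdge",
    "DiseaseGeneSets",
    "DiseaseNetwork",
    "NetworkSummary",
    "BridgeRecord",
    "HubScore",
    "AnnotationSet",
    "EnrichmentResult",
    "TissueExpressionRecord",
    "SensitivityReport",
]

#: Evidence channel names, in the column order used by the edge-table dialect.
CHANNELS = (
    "experimental",
    "database",
    "textmining",
    "coexpression",
    "neighborhood",
    "fusion",
    "cooccurrence",
)


class ValidationError(ValueError):
    """A record violates a domain invariant (e.g. score outside [0,1])."""


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


def _check_unit(value: float, name: str, context: str = "") -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        where = f" ({context})" if context else ""
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}{where}")
    return value


def _clean_symbol(symbol: str, name: str = "gene_symbol") -> str:
    symbol = str(symbol).strip().upper()
    if not symbol:
        raise ValidationError(f"{name} must be a non-empty string")
    return symbol


@dataclass(frozen=True)
class GeneDiseaseAssociation:
    """One gene-disease pair with its association score and Evidence Index.

    ``score`` is the aggregated [0,1] confidence that the gene is associated
    with the disease; ``evidence_index`` is the fraction of supporting (vs.
    contradicting) publications.
    """

    gene_symbol: str
    disease_label: str
    score: float
    evidence_index: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_symbol", _clean_symbol(self.gene_symbol))
        object.__setattr__(self, "disease_label", str(self.disease_label).strip())
        object.__setattr__(self, "score", _check_unit(self.score, "score"))
        object.__setattr__(
            self, "evidence_index", _check_unit(self.evidence_index, "evidence_index")
        )


@dataclass(frozen=True)
class ChannelScores:
    """Per-channel interaction evidence scores, each in [0,1]."""

    experimental: float = 0.0
    database: float = 0.0
    textmining: float = 0.0
    coexpression: float = 0.0
    neighborhood: float = 0.0
    fusion: float = 0.0
    cooccurrence: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            object.__setattr__(self, f.name, _check_unit(getattr(self, f.name), f.name))

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, c) for c in CHANNELS)

    def present(self) -> list[str]:
        """Names of channels with a strictly positive score."""
        return [c for c in CHANNELS if getattr(self, c) > 0.0]


@dataclass(frozen=True)
class InteractionEdge:
    """An undirected scored protein pair, stored in lexicographic order."""

    gene_a: str
    gene_b: str
    channels: ChannelScores
    combined_score: float

    def __post_init__(self) -> None:
        a = _clean_symbol(self.gene_a, "gene_a")
        b = _clean_symbol(self.gene_b, "gene_b")
        if a == b:
            raise ValidationError(f"self-loop edge {a!r}-{b!r} is not allowed")
        if a > b:
            a, b = b, a
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)
        object.__setattr__(
            self, "combined_score", _check_unit(self.combined_score, "combined_score")
        )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class DiseaseGeneSets:
    """Two labelled disease gene sets (e.g. PD and CKD)."""

    set_a_label: str
    set_a: frozenset[str]
    set_b_label: str
    set_b: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "set_a", frozenset(_clean_symbol(g) for g in self.set_a))
        object.__setattr__(self, "set_b", frozenset(_clean_symbol(g) for g in self.set_b))

    @property
    def union(self) -> frozenset[str]:
        return self.set_a | self.set_b


@dataclass(frozen=True)
class DiseaseNetwork:
    """A confidence-filtered interaction network over two disease gene sets."""

    gene_sets: DiseaseGeneSets
    edges: tuple[InteractionEdge, ...]
    confidence_cutoff: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "confidence_cutoff",
            _check_unit(self.confidence_cutoff, "confidence_cutoff"),
        )
        union = self.gene_sets.union
        for e in self.edges:
            if e.gene_a not in union or e.gene_b not in union:
                raise ValidationError(
                    f"edge {e.gene_a}-{e.gene_b} has an endpoint outside the gene sets"
                )
            if e.combined_score < self.confidence_cutoff:
                raise ValidationError(
                    f"edge {e.gene_a}-{e.gene_b} scores {e.combined_score} below "
                    f"the cutoff {self.confidence_cutoff}"
                )

    @property
    def nodes(self) -> frozenset[str]:
        # isolated genes remain nodes: the node set is the full union
        return self.gene_sets.union


@dataclass(frozen=True)
class NetworkSummary:
    """Topology metrics plus the edge-enrichment statistic versus a null."""

    n_nodes: int
    n_edges: int
    average_degree: float
    clustering_coefficient: float
    expected_edges_null: float | None = None
    fold_enrichment: float | None = None
    ppi_enrichment_p: float | None = None


@dataclass(frozen=True)
class BridgeRecord:
    """A high-confidence edge whose endpoints lie in different disease sets."""

    edge: InteractionEdge
    source_set_gene: str  # set_b side (e.g. the CKD gene)
    target_set_gene: str  # set_a side (e.g. the PD gene)
    evidence_channels_present: tuple[str, ...]
    priority_rank: int = 0


@dataclass(frozen=True)
class HubScore:
    """Centrality scores for one node.

    ``mcc`` is Maximal Clique Centrality: the sum over maximal cliques C
    containing the node of (|C| - 1)!. Python integers make the factorials
    exact at any clique size.
    """

    gene_symbol: str
    mcc: int
    degree: int
    betweenness: float
    rank_mcc: int = 0


@dataclass(frozen=True)
class AnnotationSet:
    """A named gene set (pathway, compartment, vesicle catalog...)."""

    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "members", frozenset(_clean_symbol(m, "member") for m in self.members)
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """One over-representation test result.

    observed_count (k) of query_size (n) query genes fall in a term of
    term_size_in_universe (K) members out of universe_size (M) genes.
    ``strength`` is log10(observed/expected) = log10(k / (n*K/M)); -inf when
    k = 0.
    """

    term: AnnotationSet
    observed_count: int
    query_size: int
    term_size_in_universe: int
    universe_size: int
    p_value: float
    fdr: float
    strength: float


@dataclass(frozen=True)
class TissueExpressionRecord:
    """Gene expression in one tissue, in transcripts per million."""

    gene_symbol: str
    tissue: str
    tpm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_symbol", _clean_symbol(self.gene_symbol))
        object.__setattr__(self, "tissue", str(self.tissue).strip())
        tpm = float(self.tpm)
        if math.isnan(tpm) or tpm < 0:
            raise ValidationError(f"tpm must be >= 0, got {tpm!r}")
        object.__setattr__(self, "tpm", tpm)


@dataclass(frozen=True)
class SensitivityGridPoint:
    """One re-run of the pipeline at perturbed thresholds."""

    score_min_a: float
    score_min_b: float
    confidence_cutoff: float
    n_bridges: int
    bridge_jaccard: float
    hub_overlap_topk: float
    is_baseline: bool = False


@dataclass(frozen=True)
class SensitivityReport:
    """Stability of bridges and hubs over a threshold grid."""

    baseline_params: tuple[float, float, float]
    grid: tuple[SensitivityGridPoint, ...] = field(default_factory=tuple)
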