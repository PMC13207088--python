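"""Tiered disease-specific filtering of gene-disease associations.

Each disease gets its own (score, Evidence Index) thresholds — a stringent
pair for the disease with the better-established genetics, a broader pair
for the more heterogeneous one. Comparisons are inclusive (>=). A gene with
several rows for one disease is retained if any row passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .datamodel import DiseaseGeneSets, GeneDiseaseAssociation, ValidationError

__all__ = ["filter_associations", "check_overlap", "OverlapReport"]

logger = logging.getLogger(__name__)


def filter_associations(
    assocs: Iterable[GeneDiseaseAssociation],
    disease: str,
    score_min: float,
    ei_min: float,
) -> frozenset[str]:
    """Genes associated with ``disease`` at score >= score_min and EI >= ei_min."""
    for name, v in (("score_min", score_min), ("ei_min", ei_min)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} must lie in [0, 1], got {v}")
    seen_disease = False
    kept = set()
    for a in assocs:
        if a.disease_label != disease:
            continue
        seen_disease = True
        if a.score >= score_min and a.evidence_index >= ei_min:
            kept.add(a.gene_symbol)
    if not seen_disease:
        logger.warning("no association rows found for disease label %r", disease)
    return frozenset(kept)


@dataclass(frozen=True)
class OverlapReport:
    """Intersection of two disease gene sets and their Jaccard index."""

    intersection: frozenset[str]
    union_size: int
    jaccard: float


def check_overlap(sets: DiseaseGeneSets) -> OverlapReport:
    """Intersection members and Jaccard |A&B| / |A|B| of the two sets."""
    inter = sets.set_a & sets.set_b
    union = sets.set_a | sets.set_b
    jaccard = len(inter) / len(union) if union else 0.0
    return OverlapReport(
        intersection=frozenset(inter), union_size=len(union), jaccard=jaccard
    )
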