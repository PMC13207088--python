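"""Extraction and prioritization of cross-disease molecular bridges.

A bridge is a high-confidence edge whose endpoints belong to different
disease gene sets. Extraction uses a strict (>) score comparison —
"combined confidence score > threshold" — unlike network construction's
inclusive cutoff; the asymmetry is deliberate and documented.

Prioritization follows a two-criterion scheme: a high-score tier first
(combined score above a stricter bound, 0.800 by default), then evidence-
channel consistency — edges backed by experimental or curated-database
evidence outrank those supported by other channels, which outrank
text-mining-only edges — then combined score descending, with the
lexicographic endpoint pair as a total tie-break.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Mapping, Sequence

from dataclasses import replace

from .datamodel import BridgeRecord, DiseaseNetwork, ValidationError

__all__ = ["extract_bridges", "prioritize_bridges", "theme_tally"]

logger = logging.getLogger(__name__)

#: channel-consistency tiers: lower is stronger evidence
_DIRECT = {"experimental", "database"}
_TEXTMINING = {"textmining"}


def _evidence_tier(present: Sequence[str]) -> int:
    if any(c in _DIRECT for c in present):
        return 0
    if any(c not in _TEXTMINING for c in present):
        return 1
    return 2


def extract_bridges(net: DiseaseNetwork, min_score: float = 0.700) -> list[BridgeRecord]:
    """Cross-set edges with combined score strictly above ``min_score``.

    Records are returned unranked (priority_rank 0), source endpoint taken
    from set_b and target from set_a, sorted by combined score descending
    then endpoint pair.
    """
    if not (0.0 <= min_score <= 1.0):
        raise ValidationError(f"min_score must lie in [0, 1], got {min_score}")
    a_set, b_set = net.gene_sets.set_a, net.gene_sets.set_b
    records = []
    for e in net.edges:
        if e.combined_score <= min_score:
            continue
        in_a = (e.gene_a in a_set, e.gene_b in a_set)
        in_b = (e.gene_a in b_set, e.gene_b in b_set)
        if in_a[0] and in_b[1] and not in_b[0] and not in_a[1]:
            target, source = e.gene_a, e.gene_b
        elif in_b[0] and in_a[1] and not in_a[0] and not in_b[1]:
            source, target = e.gene_a, e.gene_b
        else:
            continue  # within-set edge (or ambiguous membership)
        records.append(
            BridgeRecord(
                edge=e,
                source_set_gene=source,
                target_set_gene=target,
                evidence_channels_present=tuple(e.channels.present()),
            )
        )
    records.sort(key=lambda r: (-r.edge.combined_score, r.edge.pair))
    return records


def prioritize_bridges(
    bridges: Sequence[BridgeRecord], high_score: float = 0.800
) -> list[BridgeRecord]:
    """Rank bridges 1..n by (high-score tier, evidence tier, score, pair)."""
    ordered = sorted(
        bridges,
        key=lambda r: (
            0 if r.edge.combined_score > high_score else 1,
            _evidence_tier(r.evidence_channels_present),
            -r.edge.combined_score,
            r.edge.pair,
        ),
    )
    return [replace(r, priority_rank=i) for i, r in enumerate(ordered, start=1)]


def theme_tally(
    bridges: Sequence[BridgeRecord],
    theme_map: Mapping[str, frozenset[str]],
) -> Counter[str]:
    """Count bridges per functional theme (themes are not exclusive).

    A bridge is tallied under every theme whose gene list contains both of
    its endpoints; a bridge matching no theme counts under "unassigned".
    """
    tally: Counter[str] = Counter({t: 0 for t in theme_map})
    for b in bridges:
        matched = False
        for theme, genes in theme_map.items():
            if b.source_set_gene in genes and b.target_set_gene in genes:
                tally[theme] += 1
                matched = True
        if not matched:
            logger.warning(
                "bridge %s-%s matches no theme; counted as unassigned",
                b.source_set_gene,
                b.target_set_gene,
            )
            tally["unassigned"] += 1
    return tally
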