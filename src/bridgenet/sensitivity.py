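"""Threshold-sensitivity analysis of the bridge and hub findings.

The pipeline is re-run over a factorial grid of offsets on the two disease
association-score thresholds and the interaction confidence cutoff
(default +/- 0.1 on each). Stability is quantified as the Jaccard index of
the bridge edge set versus baseline and the fractional overlap of the
top-k hub list versus baseline; both equal 1.0 at the baseline grid point
by construction.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from itertools import product
from typing import Sequence

from .datamodel import (
    GeneDiseaseAssociation,
    InteractionEdge,
    SensitivityGridPoint,
    SensitivityReport,
)
from .pipeline import PipelineParams, run_pipeline

__all__ = ["run_grid"]

logger = logging.getLogger(__name__)


def _bridge_pairs(results) -> frozenset[tuple[str, str]]:
    return frozenset(b.edge.pair for b in results.bridges)


def _hub_set(results, k: int) -> frozenset[str]:
    return frozenset(h.gene_symbol for h in results.top_hubs[:k])


def _jaccard(x: frozenset, y: frozenset) -> float:
    if not x and not y:
        return 1.0
    return len(x & y) / len(x | y)


def run_grid(
    assocs: Sequence[GeneDiseaseAssociation],
    edges: Sequence[InteractionEdge],
    baseline: PipelineParams = PipelineParams(),
    deltas: Sequence[float] = (-0.1, 0.0, 0.1),
    top_k: int = 10,
) -> SensitivityReport:
    """Re-run the pipeline over the threshold grid and score stability.

    The grid is the Cartesian product of ``deltas`` applied to
    (score_min_a, score_min_b, confidence_cutoff). Grid points pushing any
    threshold outside [0, 1] are skipped with a warning. The bridge
    extraction threshold moves with the confidence cutoff.
    """
    base = run_pipeline(assocs, edges, baseline)
    base_bridges = _bridge_pairs(base)
    base_hubs = _hub_set(base, top_k)

    points = []
    for da, db, dc in product(deltas, deltas, deltas):
        sa = baseline.score_min_a + da
        sb = baseline.score_min_b + db
        cc = baseline.confidence_cutoff + dc
        if not all(0.0 <= v <= 1.0 for v in (sa, sb, cc)):
            logger.warning(
                "skipping grid point (%.2f, %.2f, %.2f): threshold outside [0, 1]",
                sa, sb, cc,
            )
            continue
        params = replace(
            baseline,
            score_min_a=sa,
            score_min_b=sb,
            confidence_cutoff=cc,
            bridge_min_score=cc,
        )
        res = run_pipeline(assocs, edges, params)
        is_base = da == 0.0 and db == 0.0 and dc == 0.0
        points.append(
            SensitivityGridPoint(
                score_min_a=sa,
                score_min_b=sb,
                confidence_cutoff=cc,
                n_bridges=len(res.bridges),
                bridge_jaccard=_jaccard(base_bridges, _bridge_pairs(res)),
                hub_overlap_topk=(
                    len(base_hubs & _hub_set(res, top_k)) / len(base_hubs)
                    if base_hubs
                    else 1.0
                ),
                is_baseline=is_base,
            )
        )

    return SensitivityReport(
        baseline_params=(
            baseline.score_min_a,
            baseline.score_min_b,
            baseline.confidence_cutoff,
        ),
        grid=tuple(points),
    )
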