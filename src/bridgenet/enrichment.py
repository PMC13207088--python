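"""Over-representation statistics and candidate annotation joins.

Over-representation of a query gene set in an annotation term is tested
with the upper-tail hypergeometric distribution: with a universe of M
genes of which K carry the term, drawing n query genes and observing k
annotated ones, p = Pr(X >= k). Benjamini-Hochberg step-up controls the
FDR across all terms tested in one call; "strength" is the STRING-style
log10 of observed over expected count, log10(k / (n*K/M)).

Also houses the two annotation joins the candidate work-up needs:
vesicle-catalog membership flags and the tissue-expression context table.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    AnnotationSet,
    EnrichmentResult,
    TissueExpressionRecord,
    ValidationError,
)

__all__ = [
    "hypergeometric_ora",
    "bh_fdr",
    "vesicle_membership",
    "expression_context",
]

logger = logging.getLogger(__name__)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adjusted_(i) = min over j >= i of min(1, m * p_(j) / j) on the sorted
    scale, mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted_sorted
    return out.tolist()


def hypergeometric_ora(
    query: Iterable[str],
    terms: Sequence[AnnotationSet],
    universe: Iterable[str],
    min_term_size: int = 2,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of the query against every term.

    Terms are intersected with the universe before testing; terms with
    fewer than ``min_term_size`` members in the universe are skipped.
    Results are sorted by p-value (ties by term_id).
    """
    universe = frozenset(g.strip().upper() for g in universe)
    if not universe:
        raise ValidationError("universe must be non-empty")
    query = frozenset(g.strip().upper() for g in query)
    stray = query - universe
    if stray:
        raise ValidationError(
            f"query genes outside the universe: {sorted(stray)[:5]}"
        )
    n = len(query)

    tested: list[tuple[AnnotationSet, int, int]] = []
    for term in terms:
        in_universe = term.members & universe
        if len(in_universe) < min_term_size:
            logger.info(
                "skipping term %s: %d members in universe (< %d)",
                term.term_id,
                len(in_universe),
                min_term_size,
            )
            continue
        k = len(term.members & query)
        tested.append((term, len(in_universe), k))

    m_universe = len(universe)
    p_values = []
    for _, big_k, k in tested:
        if k == 0:
            p_values.append(1.0)
        else:
            p_values.append(float(stats.hypergeom.sf(k - 1, m_universe, big_k, n)))
    fdrs = bh_fdr(p_values)

    results = []
    for (term, big_k, k), p, fdr in zip(tested, p_values, fdrs):
        expected = n * big_k / m_universe
        strength = math.log10(k / expected) if k > 0 and expected > 0 else -math.inf
        results.append(
            EnrichmentResult(
                term=term,
                observed_count=k,
                query_size=n,
                term_size_in_universe=big_k,
                universe_size=m_universe,
                p_value=p,
                fdr=fdr,
                strength=strength,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term.term_id))
    return results


def vesicle_membership(
    genes: Iterable[str], catalogs: Sequence[AnnotationSet]
) -> pd.DataFrame:
    """Boolean membership of each gene in each vesicle catalog.

    Returns a gene x catalog DataFrame of flags, indexed by gene symbol,
    columns named by catalog term_id.
    """
    genes = sorted({g.strip().upper() for g in genes})
    data = {
        c.term_id: [g in c.members for g in genes] for c in catalogs
    }
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"))


def expression_context(
    genes: Iterable[str],
    expr: Iterable[TissueExpressionRecord],
    tissues: Sequence[str],
) -> pd.DataFrame:
    """Wide gene x tissue TPM table with the per-gene argmax tissue.

    Missing gene/tissue combinations are NaN; ``top_tissue`` is the tissue
    of maximal TPM, ties resolved by the supplied tissue order; genes with
    no measurements get a null top_tissue.
    """
    genes = sorted({g.strip().upper() for g in genes})
    tpm = {(r.gene_symbol, r.tissue): r.tpm for r in expr}
    table = pd.DataFrame(
        [[tpm.get((g, t), np.nan) for t in tissues] for g in genes],
        index=pd.Index(genes, name="gene"),
        columns=list(tissues),
    )
    top = []
    for g in genes:
        row = table.loc[g]
        if row.isna().all():
            top.append(None)
        else:
            best = -math.inf
            best_t = None
            for t in tissues:  # first tissue in supplied order wins ties
                v = row[t]
                if not np.isnan(v) and v > best:
                    best, best_t = v, t
            top.append(best_t)
    table["top_tissue"] = top
    return table
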