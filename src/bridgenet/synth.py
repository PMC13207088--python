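"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emits the four input kinds the analysis consumes — two
disjoint disease gene sets with association scores, a scored interactome
with planted cross-set bridges, GMT annotation sets with one planted
enriched term, and a tissue-expression table is available as a packaged
fixture — all deterministic under a fixed seed.

Planting guarantees drive the test suite:

* association rows are drawn so that exactly the intended members pass the
  tiered (score, Evidence Index) thresholds; decoys are drawn strictly
  below the score threshold;
* exactly ``n_planted_bridges`` cross-set pairs receive combined scores in
  the planted range (strictly above the downstream confidence cutoff),
  while distractor cross-set edges score strictly below it — so bridge
  extraction at the cutoff must return exactly the planted pairs;
* per-channel scores are solved algebraically so that recombining them
  reproduces the assigned combined score to within 1e-9 (text-mining fixed
  near 0.400 where feasible, the experimental channel solved; single-channel
  fallback otherwise);
* the planted annotation term consists of exactly its member list, giving
  it the smallest achievable hypergeometric p for its query; decoy terms
  never contain the full planted member list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .datamodel import (
    AnnotationSet,
    ChannelScores,
    DiseaseGeneSets,
    GeneDiseaseAssociation,
    InteractionEdge,
    ValidationError,
)
from .interactome import DEFAULT_PRIOR, combine_channel_scores

__all__ = [
    "SyntheticConfig",
    "generate_gene_sets",
    "generate_interactome",
    "generate_annotations",
    "channels_for_combined",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults mirror the published study conditions.

    64 + 17 disjoint disease genes, 15 planted bridges scoring in
    (0.70, 0.97] against a 0.700 confidence cutoff, and 265 within-set
    edges for a 280-edge network over 81 nodes. Decoy association rows are
    generated at ``decoy_factor`` times the passing count per disease.
    """

    n_set_a: int = 64
    n_set_b: int = 17
    n_background_genes: int = 40
    n_planted_bridges: int = 15
    bridge_score_low: float = 0.705
    bridge_score_high: float = 0.97
    confidence_cutoff: float = 0.700
    n_within_edges: int | None = 265
    within_set_edge_prob: float | None = None
    subthreshold_crossset_edge_prob: float = 0.05
    background_edge_prob: float = 0.08
    channel_noise_sd: float = 0.05
    score_threshold_a: float = 0.8
    score_threshold_b: float = 0.6
    ei_threshold: float = 0.4
    decoy_factor: int = 2
    topology: str = "erdos_renyi"  # or "preferential_attachment"
    seed: int = 0
    include_set_a: tuple[str, ...] = field(default_factory=tuple)
    include_set_b: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_set_a < 0 or self.n_set_b < 0:
            raise ValidationError("set sizes must be non-negative")
        if self.n_planted_bridges > self.n_set_a * self.n_set_b:
            raise ValidationError(
                "n_planted_bridges exceeds the number of available cross-set pairs"
            )
        if not (self.confidence_cutoff < self.bridge_score_low <= self.bridge_score_high <= 1):
            raise ValidationError(
                "the planted bridge score range must lie strictly above the "
                "confidence cutoff"
            )
        if self.topology not in ("erdos_renyi", "preferential_attachment"):
            raise ValidationError(f"unknown topology {self.topology!r}")
        if len(self.include_set_a) > self.n_set_a or len(self.include_set_b) > self.n_set_b:
            raise ValidationError("included symbols exceed the requested set size")


def _symbols(prefix: str, n: int, included: Sequence[str]) -> list[str]:
    out = [s.strip().upper() for s in included]
    i = 1
    while len(out) < n:
        candidate = f"{prefix}{i:03d}"
        if candidate not in out:
            out.append(candidate)
        i += 1
    return out


def generate_gene_sets(
    config: SyntheticConfig,
) -> tuple[DiseaseGeneSets, list[GeneDiseaseAssociation]]:
    """Two disjoint symbol sets plus an association table that recovers them.

    Passing rows draw score uniformly in [threshold, 1] and EI in
    [ei_threshold, 1]; decoy rows draw score strictly below the threshold,
    so tiered filtering at the configured thresholds retains exactly the
    planted members.
    """
    rng = np.random.default_rng(config.seed)
    set_a = _symbols("PDG", config.n_set_a, config.include_set_a)
    set_b = _symbols("CKG", config.n_set_b, config.include_set_b)
    if set(set_a) & set(set_b):
        raise ValidationError("included symbols make the two sets overlap")

    assocs: list[GeneDiseaseAssociation] = []

    def _rows(genes: list[str], label: str, thr: float) -> None:
        for g in genes:
            score = float(rng.uniform(thr, 1.0))
            ei = float(rng.uniform(config.ei_threshold, 1.0))
            assocs.append(GeneDiseaseAssociation(g, label, score, ei))
        for j in range(config.decoy_factor * len(genes)):
            decoy = f"DEC{label}{j:04d}"
            score = float(rng.uniform(0.0, max(thr - 1e-6, 0.0)))
            ei = float(rng.uniform(0.0, 1.0))
            assocs.append(GeneDiseaseAssociation(decoy, label, score, ei))

    _rows(set_a, "PD", config.score_threshold_a)
    _rows(set_b, "CKD", config.score_threshold_b)

    sets = DiseaseGeneSets("PD", frozenset(set_a), "CKD", frozenset(set_b))
    return sets, assocs


def channels_for_combined(
    combined: float,
    rng: np.random.Generator,
    noise_sd: float = 0.05,
    prior: float = DEFAULT_PRIOR,
) -> ChannelScores:
    """Channel scores whose combination reproduces ``combined`` exactly.

    Fixes the text-mining channel near 0.400 (jittered by ``noise_sd``)
    and solves the experimental channel algebraically; falls back to a
    single experimental channel equal to the combined score when the
    two-channel split is infeasible.
    """
    tm = float(np.clip(0.400 + rng.normal(0.0, noise_sd), 0.05, 0.60))
    if prior < tm < combined:
        s_corr = (combined - prior) / (1 - prior)
        t_corr = (tm - prior) / (1 - prior)
        e_corr = 1.0 - (1.0 - s_corr) / (1.0 - t_corr)
        if 0.0 < e_corr <= 1.0:
            exp = e_corr * (1 - prior) + prior
            ch = ChannelScores(experimental=exp, textmining=tm)
            if abs(combine_channel_scores(ch, prior) - combined) <= 1e-9:
                return ch
    # single-channel identity: the prior correct/uncorrect round trip
    return ChannelScores(experimental=combined)


def _edge(a: str, b: str, combined: float, rng, noise_sd: float) -> InteractionEdge:
    return InteractionEdge(a, b, channels_for_combined(combined, rng, noise_sd), combined)


def generate_interactome(
    config: SyntheticConfig,
    sets: DiseaseGeneSets,
    planted_edges: Sequence[InteractionEdge] | None = None,
) -> tuple[list[InteractionEdge], list[tuple[str, str]]]:
    """A scored edge table with planted bridges, plus the planted pair list.

    Exactly ``n_planted_bridges`` cross-set pairs score in the planted range
    (or the supplied ``planted_edges`` are used verbatim); distractor
    cross-set edges score strictly below the cutoff; within-set edges score
    at or above it; background genes contribute supra-cutoff edges outside
    the disease union for permutation nulls.
    """
    rng = np.random.default_rng(config.seed + 1)
    a_sorted, b_sorted = sorted(sets.set_a), sorted(sets.set_b)
    cross_pairs = [(a, b) for a in a_sorted for b in b_sorted]

    edges: list[InteractionEdge] = []
    if planted_edges is not None:
        union = sets.union
        for e in planted_edges:
            if e.gene_a not in union or e.gene_b not in union:
                raise ValidationError(
                    f"planted edge {e.gene_a}-{e.gene_b} has endpoints outside the sets"
                )
        edges.extend(planted_edges)
        planted_pairs = [e.pair for e in planted_edges]
    else:
        if config.n_planted_bridges > len(cross_pairs):
            raise ValidationError("not enough cross-set pairs to plant bridges")
        idx = rng.choice(len(cross_pairs), size=config.n_planted_bridges, replace=False)
        planted_pairs = []
        for i in sorted(idx):
            a, b = cross_pairs[i]
            combined = float(
                rng.uniform(config.bridge_score_low, config.bridge_score_high)
            )
            edges.append(_edge(a, b, combined, rng, config.channel_noise_sd))
            planted_pairs.append(edges[-1].pair)

    planted_set = set(planted_pairs)

    # distractor cross-set edges, strictly sub-cutoff
    lo_dist = 0.15
    hi_dist = config.confidence_cutoff - 1e-3
    for a, b in cross_pairs:
        key = (a, b) if a < b else (b, a)
        if key in planted_set:
            continue
        if rng.random() < config.subthreshold_crossset_edge_prob:
            combined = float(rng.uniform(lo_dist, hi_dist))
            edges.append(_edge(a, b, combined, rng, config.channel_noise_sd))

    # within-set edges at or above the cutoff
    within_pairs = list(combinations(a_sorted, 2)) + list(combinations(b_sorted, 2))
    hi_within = 0.995

    def _supra(rng) -> float:
        return float(rng.uniform(config.confidence_cutoff, hi_within))

    if config.topology == "preferential_attachment":
        import networkx as nx

        chosen = []
        for group in (a_sorted, b_sorted):
            if len(group) >= 3:
                g = nx.barabasi_albert_graph(
                    len(group), m=2, seed=int(rng.integers(0, 2**31 - 1))
                )
                chosen.extend((group[u], group[v]) for u, v in g.edges)
    elif config.n_within_edges is not None:
        if config.n_within_edges > len(within_pairs):
            raise ValidationError(
                f"n_within_edges={config.n_within_edges} exceeds the "
                f"{len(within_pairs)} available within-set pairs"
            )
        idx = rng.choice(len(within_pairs), size=config.n_within_edges, replace=False)
        chosen = [within_pairs[i] for i in sorted(idx)]
    else:
        prob = config.within_set_edge_prob or 0.0
        chosen = [p for p in within_pairs if rng.random() < prob]

    for a, b in chosen:
        edges.append(_edge(a, b, _supra(rng), rng, config.channel_noise_sd))

    # background-gene edges (outside the union; feed the permutation null)
    if config.n_background_genes:
        bg = [f"BGG{i:03d}" for i in range(1, config.n_background_genes + 1)]
        all_nodes = a_sorted + b_sorted + bg
        for g in bg:
            for other in all_nodes:
                if other == g or (other in bg and other < g):
                    continue
                if rng.random() < config.background_edge_prob:
                    edges.append(_edge(g, other, _supra(rng), rng, config.channel_noise_sd))

    edges.sort(key=lambda e: e.pair)
    return edges, sorted(planted_set)


def generate_annotations(
    sets: DiseaseGeneSets,
    n_terms: int,
    planted_term: Sequence[str],
    seed: int = 0,
    universe: Sequence[str] | None = None,
) -> list[AnnotationSet]:
    """GMT-style terms with one planted term of minimal hypergeometric p.

    The planted term contains exactly its member list, which is the
    smallest-p configuration for a query equal to those members; decoy
    terms are drawn from the universe with one planted member always
    withheld, so no decoy can tie the planted term.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(universe) if universe is not None else sorted(sets.union)
    planted = sorted({g.strip().upper() for g in planted_term})
    if not set(planted) <= set(universe):
        raise ValidationError("planted term members must lie inside the universe")
    if len(planted) >= len(universe):
        raise ValidationError("planted term must be smaller than the universe")

    terms = [AnnotationSet("PLANTED_TERM", "planted enriched term", frozenset(planted))]
    if planted:
        withheld = planted[int(rng.integers(0, len(planted)))]
    else:
        withheld = None
    pool = [g for g in universe if g != withheld]
    max_size = min(15, len(pool))
    for i in range(1, n_terms):
        size = int(rng.integers(2, max(3, max_size + 1)))
        members = rng.choice(len(pool), size=min(size, len(pool)), replace=False)
        terms.append(
            AnnotationSet(
                f"RAND_TERM_{i:03d}",
                f"random background term {i}",
                frozenset(pool[j] for j in members),
            )
        )
    return terms
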