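# Methods

## Problem setting

Two diseases with disjoint susceptibility gene sets can still converge on a
shared pathophysiological module: the proteins encoded by the two sets may
interact densely within the human interactome, and individual cross-set
interactions ("molecular bridges") are candidate mechanistic links between
the diseases. The package quantifies that convergence for a two-disease
design — a larger, stringently curated set (labelled PD throughout, 64
genes by default) and a smaller, more genetically heterogeneous set (CKD,
17 genes) — and prioritizes the bridges.

## Curation

Gene–disease association rows carry a [0,1] aggregated association score
and an Evidence Index (EI; the fraction of supporting publications). Each
disease gets its own thresholds, applied inclusively (≥): defaults are
score ≥ 0.8, EI ≥ 0.4 for the stringent set and score ≥ 0.6, EI ≥ 0.4 for
the broader one. A gene with several rows for one disease is kept if any
row passes, since duplicate rows arise only from dialect quirks of the
export format. Genes passing both disease filters would make bridge
orientation ambiguous; the pipeline excludes them from both sides and logs
a warning (the intended study design has zero overlap). Filtering is
monotone: raising either threshold can only shrink the retained set.

## Combined interaction score

Per-channel evidence scores (experimental, curated database, text-mining,
co-expression, neighborhood, fusion, co-occurrence) are integrated with the
documented STRING convention. Each channel score s is corrected for the
prior probability p0 that a random protein pair interacts,

    s' = max(0, (s - p0) / (1 - p0)),

the corrected scores are combined as independent probabilities,

    S' = 1 - prod_i (1 - s'_i),

and the prior is restored: S = S'(1 - p0) + p0, with S = 0 when no channel
exceeds the prior. p0 = 0.041. The function is monotone in every channel,
symmetric, and the identity for a single channel. Edge tables that already
carry a combined score keep it verbatim (published scores are treated as
authoritative rather than recomputed from partial channel listings); when
the column is absent the combination above fills it in.

## Network construction and topology

The network keeps edges with combined score ≥ cutoff (default 0.700,
an inclusive "minimum required score") whose endpoints both lie in the
union of the two disease sets; curated genes without surviving edges remain
as isolated nodes. Reported metrics: node and edge counts, average degree
2E/N, and the mean local clustering coefficient with nodes of degree < 2
contributing 0 — the only convention that yields a [0,1] network-level
value on sparse graphs.

## Edge enrichment against a null

The convergence claim is that the observed edge count E inside the module
far exceeds the expectation λ for a random network of the same size and
degree structure. Two nulls are provided:

* **Analytic Poisson.** Given λ (supplied directly, or estimated by the
  permutation null), p = Pr(X ≥ E) for X ~ Poisson(λ), the standard
  approximation for edge counts under degree-preserving randomization. A
  binomial alternative differs negligibly at these scales.
* **Degree-preserving permutation.** The full supra-cutoff candidate graph
  — module plus background genes — is rewired by double edge swaps (100
  attempted swaps per edge per replicate, 1000 replicates by default,
  seedable); each replicate counts the edges falling inside the module, and
  p is the add-one permutation p-value (1 + #{replicates ≥ E}) / (1 + R).
  Rewiring only the module-internal graph would be degenerate (its edge
  count is invariant under swaps), which is why the null is defined over
  the global candidate set.

A caveat the test suite makes visible: when the synthetic background is
small, the module's nodes carry most of the degree, and degree-preserving
rewiring then reproduces most module-internal edges — λ stays close to E.
A published expected count like "45 edges against 280 observed" reflects a
genome-scale background that a desk-scale simulation does not contain; the
`expected_edges_override` parameter (CLI `--expected-edges`) exists to
reproduce such printed statistics. Fold enrichment is E/λ in either mode.

## Bridges

Bridges are edges with one endpoint in each disease set and combined score
strictly above the threshold (default 0.700). The strict comparison follows
the phrasing "score > 0.700" used for bridge selection, deliberately
asymmetric to the network's inclusive cutoff; at 0.700 the packaged fixture
gives 15 bridges under either reading. Prioritization uses, in order: a
high-score tier (combined > 0.800 first); an evidence-consistency tier —
experimental or curated-database evidence beats other channels, which beat
text-mining-only support (the stated preference, ordinalized minimally
since no scoring formula is given); combined score descending; and the
lexicographic endpoint pair, making the ranking total and deterministic.
Theme tallies count a bridge under every theme whose gene list contains
both endpoints (themes are not exclusive); unmatched bridges are counted
as unassigned with a warning. The packaged default theme map covers the
inflammation/ECM, metabolic/RAS and lipid/protein-homeostasis axes.

## Hubs

Maximal cliques are enumerated with pivoting Bron–Kerbosch; MCC(v) is the
sum of (|C| − 1)! over maximal cliques containing v, computed in exact
Python integers (cliques of 81 nodes would overflow fixed-width types).
A node whose neighborhood has no internal edges scores exactly its degree
— each incident edge is then itself a maximal 2-clique — so the degree
fallback is the formula's own limit. Betweenness is unnormalized
shortest-path betweenness, endpoints excluded; only ranks are consumed.
Hub ranking is MCC descending with degree then symbol as tie-breaks.

## Over-representation

For a query of n genes in a universe of M (default: the network's node
set), a term with K members in the universe and k in the query gets the
upper-tail hypergeometric p = Pr(X ≥ k). Benjamini–Hochberg step-up is
applied across all terms tested in one call (one family, no per-category
split), implemented directly so that input order is preserved and inputs
outside (0,1] are rejected; strength = log10(k/(nK/M)), with k = 0
reported at p = 1 and strength −inf. Terms with fewer than 2 universe
members are skipped to avoid degenerate multiplicity. Vesicle-catalog
membership is a plain set lookup against packaged catalogs (synthetic
stand-ins for exosome/sEV cargo databases); the tissue-expression join
produces a gene × tissue TPM table with a per-gene argmax tissue, ties
resolved by the caller's tissue order.

## Synthetic data

The generator's defaults are the study conditions: 64 + 17 disjoint genes,
15 planted bridges, 265 within-set edges (280 total at the 0.700 cutoff
over 81 nodes), decoy association rows at twice the passing count per
disease. Specifics:

* Passing association rows draw score uniformly in [threshold, 1] and EI
  in [EI-threshold, 1]; decoys draw score strictly below the threshold, so
  the tiered filter recovers exactly the planted membership.
* Planted bridges draw combined scores in (cutoff, 0.97]; distractor
  cross-set edges draw strictly below the cutoff; within-set edges draw at
  or above it. Within-set topology is an exact-count uniform draw by
  default (a Bernoulli per-pair mode and a preferential-attachment mode are
  available for hub-robustness checks; the real network's degree
  distribution is unknown beyond its average, so topology realism is
  unconstrained).
* Channel decomposition: text-mining is fixed near 0.400 (jittered by
  `channel_noise_sd`, default 0.05) and the experimental channel is solved
  in closed form so recombination reproduces the assigned combined score to
  1e-9; infeasible cases fall back to a single experimental channel equal
  to the combined score (the single-channel identity).
* Background genes (default 40) contribute supra-cutoff edges outside the
  disease union at probability 0.08 per pair, giving the permutation null
  a candidate set to rewire.
* The planted annotation term contains exactly its member list; for a query
  equal to those members this attains the minimum achievable p (k = K = n),
  and decoy terms always omit at least one planted member, so the planted
  term is strictly rank 1.

What the generator does not emulate: correlated evidence channels,
literature co-mention structure, realistic degree distributions, or a
genome-scale interactome background. Passing tests therefore demonstrate
correctness of the algorithms under the planted model, not biological
validity on real exports.

## Sensitivity analysis

The pipeline is re-run over the Cartesian product of offsets (default
−0.1, 0, +0.1) on the two association-score thresholds and the confidence
cutoff (the bridge threshold moves with the cutoff); points leaving [0,1]
are skipped with a warning. Stability is reported as the Jaccard index of
the bridge edge set and the fractional overlap of the top-10 hub list
against the baseline point, both 1.0 at baseline by construction. Bridge
sets are nested along the cutoff axis (raising the cutoff never adds a
bridge). The stability metrics are the minimal quantitative reading of a
qualitative robustness claim; no canonical metric exists.

## Numerical and design choices

* Reported rounding: combined scores 3 decimals, average degree 2,
  clustering 3 — matching the precision of the source tables; report
  writing is byte-deterministic for identical inputs and seed.
* Edge identity is unordered; canonical storage is lexicographic, and
  duplicate unordered pairs merge by per-channel (and combined) maximum —
  conservative and deterministic.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the configuration objects; derived seeds stay below 2^31.
* Problem sizes in the test suite (graphs of ≤ 12 nodes against exhaustive
  subset/path/draw-enumeration oracles, ≥ 100 seeded trials; 50 planted-
  recovery configurations; 600-replicate swap nulls on 6-node graphs
  against full degree-sequence enumeration) were chosen so exhaustive
  oracles stay exact while exercising every code path.

## Known limitations

* Published quantities that depend on undisclosed inputs — the full edge
  list behind the clustering coefficient 0.556, the expected-45 null, the
  real hub identities, enrichment FDRs against proprietary annotation
  backgrounds — cannot be re-derived from first principles here; the
  pipeline reproduces their computation, not their data.
* Gene symbols are matched exactly after case-folding; no alias or
  identifier mapping is attempted.
* The hypergeometric universe defaults to the network's node set;
  genome-scale backgrounds must be supplied explicitly.
* Bridge "biological relevance" beyond the theme map (e.g. organ-axis
  plausibility) is narrative judgment and is not encoded.
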