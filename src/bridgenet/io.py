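"""Readers and writers for the tabular dialects the pipeline touches.

All tables are UTF-8, tab-separated, with a required header row and
``#``-prefixed comment lines ignored. Gene symbols are uppercased and
whitespace-stripped on ingest; no alias resolution is attempted.
"""

from __future__ import annotations

import os
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .datamodel import (
    CHANNELS,
    AnnotationSet,
    BridgeRecord,
    EnrichmentResult,
    FormatError,
    GeneDiseaseAssociation,
    HubScore,
    InteractionEdge,
    ChannelScores,
    NetworkSummary,
    SensitivityReport,
    TissueExpressionRecord,
    ValidationError,
)

__all__ = [
    "read_association_table",
    "read_edge_table",
    "read_gmt",
    "read_expression_table",
    "write_association_table",
    "write_edge_table",
    "write_gmt",
    "write_expression_table",
    "write_report",
    "load_bridge_fixture",
    "load_vesicle_catalogs",
    "load_expression_fixture",
    "load_default_theme_map",
]

_TSV_KW = dict(sep="\t", comment="#", dtype=str, keep_default_na=False)


def _read_tsv(path: str | os.PathLike, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, **_TSV_KW)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty (a header row is required)")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def _num(value: str, name: str, row: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: cannot parse {name}={value!r} as a number")


def read_association_table(path: str | os.PathLike) -> list[GeneDiseaseAssociation]:
    """Read a gene-disease association table (columns gene, disease, score, ei).

    Row numbers in error messages count data rows from 1.
    """
    df = _read_tsv(path, ["gene", "disease", "score", "ei"])
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                GeneDiseaseAssociation(
                    gene_symbol=row.gene,
                    disease_label=row.disease,
                    score=_num(row.score, "score", i),
                    evidence_index=_num(row.ei, "EI", i),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
    return out


def read_edge_table(path: str | os.PathLike) -> list[InteractionEdge]:
    """Read a scored interaction edge table.

    Expects endpoint columns ``gene_a``/``gene_b`` and the seven evidence
    channel columns; ``combined_score`` is optional and computed from the
    channels when absent. Duplicate unordered pairs are merged keeping the
    per-channel (and combined) maximum.
    """
    from .interactome import combine_channel_scores

    df = _read_tsv(path, ["gene_a", "gene_b", *CHANNELS])
    has_combined = "combined_score" in df.columns

    merged: dict[tuple[str, str], dict[str, float]] = {}
    for i, row in enumerate(df.to_dict("records"), start=1):
        a = str(row["gene_a"]).strip().upper()
        b = str(row["gene_b"]).strip().upper()
        if not a or not b:
            raise ValidationError(f"{path}: row {i}: empty gene symbol")
        if a == b:
            raise ValidationError(f"{path}: row {i}: self-loop {a}-{b}")
        key = (a, b) if a < b else (b, a)
        scores = {c: _num(row[c], c, i) for c in CHANNELS}
        if has_combined:
            scores["combined_score"] = _num(row["combined_score"], "combined_score", i)
        prev = merged.get(key)
        if prev is None:
            merged[key] = scores
        else:
            for k, v in scores.items():
                prev[k] = max(prev[k], v)

    out = []
    for (a, b), scores in merged.items():
        channels = ChannelScores(**{c: scores[c] for c in CHANNELS})
        combined = scores.get("combined_score")
        if combined is None:
            combined = combine_channel_scores(channels)
        try:
            out.append(InteractionEdge(a, b, channels, combined))
        except ValidationError as exc:
            raise ValidationError(f"{path}: edge {a}-{b}: {exc}") from None
    out.sort(key=lambda e: e.pair)
    return out


def read_gmt(path: str | os.PathLike) -> list[AnnotationSet]:
    """Read a GMT gene-set file: term_id TAB description TAB member..."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {i}: GMT lines need term, description and "
                    f"at least one member ({len(parts)} fields found)"
                )
            term_id, desc, *members = parts
            out.append(AnnotationSet(term_id, desc, frozenset(m for m in members if m)))
    return out


def read_expression_table(path: str | os.PathLike) -> list[TissueExpressionRecord]:
    """Read a gene x tissue TPM table (columns gene, tissue, tpm)."""
    df = _read_tsv(path, ["gene", "tissue", "tpm"])
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(TissueExpressionRecord(row.gene, row.tissue, _num(row.tpm, "tpm", i)))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
    return out


# ---------------------------------------------------------------- writers


def write_association_table(
    assocs: Iterable[GeneDiseaseAssociation], path: str | os.PathLike
) -> None:
    rows = [(a.gene_symbol, a.disease_label, a.score, a.evidence_index) for a in assocs]
    pd.DataFrame(rows, columns=["gene", "disease", "score", "ei"]).to_csv(
        path, sep="\t", index=False
    )


def write_edge_table(edges: Iterable[InteractionEdge], path: str | os.PathLike) -> None:
    rows = [
        (e.gene_a, e.gene_b, *e.channels.as_tuple(), e.combined_score) for e in edges
    ]
    pd.DataFrame(
        rows, columns=["gene_a", "gene_b", *CHANNELS, "combined_score"]
    ).to_csv(path, sep="\t", index=False)


def write_gmt(terms: Iterable[AnnotationSet], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in terms:
            members = "\t".join(sorted(t.members))
            fh.write(f"{t.term_id}\t{t.term_name}\t{members}\n")


def write_expression_table(
    records: Iterable[TissueExpressionRecord], path: str | os.PathLike
) -> None:
    rows = [(r.gene_symbol, r.tissue, r.tpm) for r in records]
    pd.DataFrame(rows, columns=["gene", "tissue", "tpm"]).to_csv(
        path, sep="\t", index=False
    )


def write_report(
    outdir: str | os.PathLike,
    *,
    summary: NetworkSummary | None = None,
    bridges: Sequence[BridgeRecord] = (),
    hubs: Sequence[HubScore] = (),
    enrichment: Sequence[EnrichmentResult] = (),
    sensitivity: SensitivityReport | None = None,
    themes: Mapping[str, int] | None = None,
) -> list[Path]:
    """Write the pipeline report TSVs with fixed column order and rounding.

    Combined scores are printed with 3 decimals, average degree with 2,
    clustering with 3; identical inputs produce byte-identical files.
    Returns the list of written paths.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write to report directory {outdir}: {exc}") from None

    written = []

    def _emit(name: str, header: list[str], rows: list[tuple]) -> None:
        p = outdir / name
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("\t".join(header) + "\n")
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")
        written.append(p)

    srows = []
    if summary is not None:
        srows = [
            ("n_nodes", summary.n_nodes),
            ("n_edges", summary.n_edges),
            ("average_degree", f"{summary.average_degree:.2f}"),
            ("clustering_coefficient", f"{summary.clustering_coefficient:.3f}"),
        ]
        if summary.expected_edges_null is not None:
            srows.append(("expected_edges_null", f"{summary.expected_edges_null:.1f}"))
        if summary.fold_enrichment is not None:
            srows.append(("fold_enrichment", f"{summary.fold_enrichment:.1f}"))
        if summary.ppi_enrichment_p is not None:
            srows.append(("ppi_enrichment_p", f"{summary.ppi_enrichment_p:.3g}"))
    _emit("summary.tsv", ["metric", "value"], srows)

    _emit(
        "bridges.tsv",
        ["rank", "source_gene", "target_gene", *CHANNELS, "combined_score", "channels_present"],
        [
            (
                b.priority_rank,
                b.source_set_gene,
                b.target_set_gene,
                *(f"{s:.3f}" for s in b.edge.channels.as_tuple()),
                f"{b.edge.combined_score:.3f}",
                ",".join(b.evidence_channels_present),
            )
            for b in bridges
        ],
    )

    _emit(
        "hubs.tsv",
        ["rank_mcc", "gene", "mcc", "degree", "betweenness"],
        [(h.rank_mcc, h.gene_symbol, h.mcc, h.degree, f"{h.betweenness:.3f}") for h in hubs],
    )

    _emit(
        "enrichment.tsv",
        ["term_id", "term_name", "k", "K", "n", "M", "p_value", "fdr", "strength"],
        [
            (
                r.term.term_id,
                r.term.term_name,
                r.observed_count,
                r.term_size_in_universe,
                r.query_size,
                r.universe_size,
                f"{r.p_value:.4g}",
                f"{r.fdr:.4g}",
                f"{r.strength:.3f}" if r.strength != float("-inf") else "-inf",
            )
            for r in enrichment
        ],
    )

    grid_rows = []
    if sensitivity is not None:
        grid_rows = [
            (
                f"{g.score_min_a:.2f}",
                f"{g.score_min_b:.2f}",
                f"{g.confidence_cutoff:.2f}",
                g.n_bridges,
                f"{g.bridge_jaccard:.3f}",
                f"{g.hub_overlap_topk:.3f}",
                int(g.is_baseline),
            )
            for g in sensitivity.grid
        ]
    _emit(
        "sensitivity.tsv",
        [
            "score_min_a",
            "score_min_b",
            "confidence_cutoff",
            "n_bridges",
            "bridge_jaccard",
            "hub_overlap_topk",
            "is_baseline",
        ],
        grid_rows,
    )

    if themes is not None:
        _emit("themes.tsv", ["theme", "n_bridges"], sorted(themes.items()))

    return written


# ------------------------------------------------------------- fixtures


def _data_path(name: str):
    return resources.files("bridgenet.data").joinpath(name)


def load_bridge_fixture() -> list[InteractionEdge]:
    """The 15 published cross-disease bridge edges with printed scores."""
    with resources.as_file(_data_path("published_bridges.tsv")) as p:
        return read_edge_table(p)


def load_vesicle_catalogs() -> list[AnnotationSet]:
    """Synthetic stand-in vesicle-cargo catalogs (exosome / sEV membership)."""
    with resources.as_file(_data_path("vesicle_catalogs_synthetic.gmt")) as p:
        return read_gmt(p)


def load_expression_fixture() -> list[TissueExpressionRecord]:
    """Published TPM values for the lead bridge genes."""
    with resources.as_file(_data_path("tissue_expression.tsv")) as p:
        return read_expression_table(p)


def load_default_theme_map() -> dict[str, frozenset[str]]:
    """Default theme -> gene-set map for bridge theme tallies."""
    with resources.as_file(_data_path("bridge_themes.tsv")) as p:
        df = _read_tsv(p, ["gene", "theme"])
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.theme, set()).add(row.gene.strip().upper())
    return {k: frozenset(v) for k, v in sorted(out.items())}
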