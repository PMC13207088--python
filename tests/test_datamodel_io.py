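"""Tabular dialect readers/writers, edge canonicalization, fixtures."""

import random

import pytest

import bridgenet as bn
from bridgenet import io as bio
from bridgenet.datamodel import FormatError, ValidationError


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestAssociationTable:
    def test_well_formed_rows_preserved(self, tmp_path):
        p = _write(
            tmp_path,
            "a.tsv",
            "# comment\ngene\tdisease\tscore\tei\n"
            "snca\tPD\t0.9\t0.5\nUMOD\tCKD\t0.7\t0.4\napoa1\tCKD\t0.65\t0.6\n",
        )
        recs = bio.read_association_table(p)
        assert len(recs) == 3
        assert recs[0].gene_symbol == "SNCA"  # uppercased on ingest

    def test_out_of_range_score_cites_row(self, tmp_path):
        p = _write(
            tmp_path, "a.tsv",
            "gene\tdisease\tscore\tei\nA\tPD\t0.5\t0.5\nB\tPD\t1.2\t0.5\n",
        )
        with pytest.raises(ValidationError, match="row 2"):
            bio.read_association_table(p)

    def test_missing_column_names_it(self, tmp_path):
        p = _write(tmp_path, "a.tsv", "gene\tdisease\tscore\nA\tPD\t0.5\n")
        with pytest.raises(FormatError, match="ei"):
            bio.read_association_table(p)

    def test_unparseable_score_rejected(self, tmp_path):
        p = _write(
            tmp_path, "a.tsv", "gene\tdisease\tscore\tei\nA\tPD\thigh\t0.5\n"
        )
        with pytest.raises(ValidationError, match="row 1"):
            bio.read_association_table(p)

    def test_study_shaped_fixture_has_81_rows_at_max_stringency(self, study_shaped):
        cfg, sets, assocs, _, _ = study_shaped
        pd_genes = bn.filter_associations(assocs, "PD", 0.8, 0.4)
        ckd_genes = bn.filter_associations(assocs, "CKD", 0.6, 0.4)
        assert len(pd_genes) == 64 and len(ckd_genes) == 17
        assert len(pd_genes | ckd_genes) == 81


class TestEdgeTable:
    HEADER = (
        "gene_a\tgene_b\texperimental\tdatabase\ttextmining\tcoexpression"
        "\tneighborhood\tfusion\tcooccurrence\tcombined_score\n"
    )

    def test_unordered_duplicates_merge_to_one_canonical_edge(self, tmp_path):
        p = _write(
            tmp_path, "e.tsv",
            self.HEADER
            + "B\tA\t0.5\t0\t0\t0\t0\t0\t0\t0.8\n"
            + "A\tB\t0.2\t0.3\t0\t0\t0\t0\t0\t0.7\n",
        )
        edges = bio.read_edge_table(p)
        assert len(edges) == 1
        e = edges[0]
        assert e.pair == ("A", "B")
        # per-channel and combined maxima survive the merge
        assert e.channels.experimental == 0.5
        assert e.channels.database == 0.3
        assert e.combined_score == 0.8

    def test_empty_file_with_header_gives_empty_collection(self, tmp_path):
        p = _write(tmp_path, "e.tsv", self.HEADER)
        assert bio.read_edge_table(p) == []

    def test_self_loop_row_rejected(self, tmp_path):
        p = _write(
            tmp_path, "e.tsv", self.HEADER + "A\tA\t0.5\t0\t0\t0\t0\t0\t0\t0.8\n"
        )
        with pytest.raises(ValidationError, match="self-loop"):
            bio.read_edge_table(p)

    def test_combined_computed_when_column_absent(self, tmp_path):
        p = _write(
            tmp_path, "e.tsv",
            "gene_a\tgene_b\texperimental\tdatabase\ttextmining\tcoexpression"
            "\tneighborhood\tfusion\tcooccurrence\n"
            "A\tB\t0.9\t0\t0\t0\t0\t0\t0\n",
        )
        (e,) = bio.read_edge_table(p)
        assert e.combined_score == pytest.approx(0.9, abs=1e-12)

    def test_published_fixture_scores_as_printed(self, published_bridges):
        assert len(published_bridges) == 15
        scores = {e.pair: e.combined_score for e in published_bridges}
        assert scores[("FN1", "TNF")] == 0.970
        assert scores[("APOA1", "SNCA")] == 0.883
        assert scores[("IL1B", "UMOD")] == 0.850

    def test_canonicalization_is_order_independent(self, tmp_path, published_bridges):
        rows = [
            f"{e.gene_b}\t{e.gene_a}\t"
            + "\t".join(str(s) for s in e.channels.as_tuple())
            + f"\t{e.combined_score}\n"
            for e in published_bridges
        ]
        random.Random(3).shuffle(rows)
        p = _write(tmp_path, "shuffled.tsv", self.HEADER + "".join(rows))
        assert bio.read_edge_table(p) == published_bridges


class TestGmt:
    def test_members_parsed_and_deduplicated(self, tmp_path):
        p = _write(tmp_path, "x.gmt", "EXOSOME\tdesc\tAPOA1\tSNCA\tSNCA\n")
        (term,) = bio.read_gmt(p)
        assert term.members == frozenset({"APOA1", "SNCA"})

    def test_short_line_is_format_error_with_line_number(self, tmp_path):
        p = _write(tmp_path, "x.gmt", "GOOD\tdesc\tA\tB\nBAD\tdesc\n")
        with pytest.raises(FormatError, match="line 2"):
            bio.read_gmt(p)


class TestExpressionTable:
    def test_published_rows_parse(self, tmp_path):
        p = _write(
            tmp_path, "t.tsv",
            "gene\ttissue\ttpm\nSNCA\tsubstantia_nigra\t20.81\n"
            "UMOD\tkidney_cortex\t1000\n",
        )
        recs = bio.read_expression_table(p)
        assert recs[0].tpm == 20.81
        assert recs[1].tpm == 1000.0

    def test_negative_tpm_rejected(self, tmp_path):
        p = _write(tmp_path, "t.tsv", "gene\ttissue\ttpm\nSNCA\tbrain\t-1\n")
        with pytest.raises(ValidationError):
            bio.read_expression_table(p)


class TestRoundTrips:
    def test_association_round_trip(self, tmp_path, study_shaped):
        _, _, assocs, _, _ = study_shaped
        p = tmp_path / "rt.tsv"
        bio.write_association_table(assocs, p)
        assert bio.read_association_table(p) == list(assocs)

    def test_edge_round_trip(self, tmp_path, study_shaped):
        _, _, _, edges, _ = study_shaped
        p = tmp_path / "rt.tsv"
        bio.write_edge_table(edges, p)
        assert bio.read_edge_table(p) == list(edges)

    def test_gmt_round_trip(self, tmp_path):
        terms = [
            bn.AnnotationSet("T1", "first", frozenset({"A", "B", "C"})),
            bn.AnnotationSet("T2", "second", frozenset({"B", "D"})),
        ]
        p = tmp_path / "rt.gmt"
        bio.write_gmt(terms, p)
        assert bio.read_gmt(p) == terms


class TestDomainInvariants:
    def test_edge_identity_is_unordered(self):
        ch = bn.ChannelScores(experimental=0.5)
        assert bn.InteractionEdge("ZZZ", "AAA", ch, 0.8).pair == ("AAA", "ZZZ")

    def test_self_loop_forbidden(self):
        with pytest.raises(ValidationError):
            bn.InteractionEdge("A", "a", bn.ChannelScores(), 0.5)

    @pytest.mark.parametrize("bad", [-0.1, 1.5, float("nan")])
    def test_scores_confined_to_unit_interval(self, bad):
        with pytest.raises(ValidationError):
            bn.GeneDiseaseAssociation("A", "PD", bad, 0.5)

    def test_network_rejects_foreign_endpoints_and_subcutoff_edges(self):
        sets = bn.DiseaseGeneSets("PD", frozenset({"A"}), "CKD", frozenset({"B"}))
        edge = bn.InteractionEdge("A", "C", bn.ChannelScores(), 0.9)
        with pytest.raises(ValidationError):
            bn.DiseaseNetwork(sets, (edge,), 0.7)
        weak = bn.InteractionEdge("A", "B", bn.ChannelScores(), 0.5)
        with pytest.raises(ValidationError):
            bn.DiseaseNetwork(sets, (weak,), 0.7)


class TestWriteReport:
    def test_fixture_run_writes_15_bridge_rows(self, tmp_path, study_shaped):
        _, _, assocs, edges, _ = study_shaped
        res = bn.run_pipeline(assocs, edges, expected_edges_override=45.0)
        bio.write_report(tmp_path, summary=res.summary, bridges=res.bridges,
                         hubs=res.hub_scores)
        lines = (tmp_path / "bridges.tsv").read_text().splitlines()
        assert len(lines) == 16  # header + 15 bridges

    def test_rerun_is_byte_identical(self, tmp_path, study_shaped):
        _, _, assocs, edges, _ = study_shaped
        outs = []
        for d in ("r1", "r2"):
            res = bn.run_pipeline(assocs, edges, expected_edges_override=45.0)
            bio.write_report(tmp_path / d, summary=res.summary,
                             bridges=res.bridges, hubs=res.hub_scores)
            outs.append(
                b"".join(sorted((tmp_path / d).glob("*.tsv"))[i].read_bytes()
                         for i in range(5))
            )
        assert outs[0] == outs[1]

    def test_empty_network_writes_headers_only(self, tmp_path):
        bio.write_report(tmp_path)
        for name in ("summary", "bridges", "hubs", "enrichment", "sensitivity"):
            lines = (tmp_path / f"{name}.tsv").read_text().splitlines()
            assert len(lines) == 1
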