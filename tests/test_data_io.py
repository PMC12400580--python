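import pytest

from formula_nettarget import data_io
from formula_nettarget.data_io import (
    DataIOError,
    DEGTable,
    GeneSetCollection,
    PPIEdgeList,
    TargetProfile,
)


def _write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


class TestCompoundAndHerbTables:
    def test_example_formula_loads(self):
        compounds, herbs = data_io.load_example_formula()
        assert len(compounds) == 49
        assert len(herbs) == 10
        roles = {h.role for h in herbs}
        assert roles == {"JUN", "CHEN", "ZUO_SHI"}
        assert sum(h.role == "JUN" for h in herbs) == 2

    def test_duplicate_compound_id_rejected(self, tmp_path):
        p = _write(
            tmp_path / "c.tsv",
            "compound_id\tname\tchemical_class\therb_ids\tquality_control_marker\n"
            "C1\tA\tflavonoid\tH1\tfalse\n"
            "C1\tB\tflavonoid\tH1\tfalse\n",
        )
        with pytest.raises(DataIOError, match="C1"):
            data_io.read_compound_table(p)

    def test_unknown_chemical_class_lists_vocabulary(self, tmp_path):
        p = _write(
            tmp_path / "c.tsv",
            "compound_id\tname\tchemical_class\therb_ids\tquality_control_marker\n"
            "C1\tA\talkaloid\tH1\tfalse\n",
        )
        with pytest.raises(DataIOError, match="flavonoid"):
            data_io.read_compound_table(p)

    def test_missing_value_marker_rejected(self, tmp_path):
        p = _write(
            tmp_path / "c.tsv",
            "compound_id\tname\tchemical_class\therb_ids\tquality_control_marker\n"
            "C1\tA\tflavonoid\t.\tfalse\n",
        )
        with pytest.raises(DataIOError, match="missing value"):
            data_io.read_compound_table(p)

    def test_zuo_shi_slash_normalized(self, tmp_path):
        p = _write(
            tmp_path / "h.tsv",
            "herb_id\tname\trole\nH1\tHerb\tZUO/SHI\n",
        )
        herbs = data_io.read_herb_table(p)
        assert herbs[0].role == "ZUO_SHI"


class TestProfiles:
    def test_truncation_keeps_best_ranks(self, tmp_path):
        lines = ["compound_id\trank\ttarget"]
        lines += [f"C1\t{r}\tGENE{r}" for r in range(1, 151)]
        p = _write(tmp_path / "p.tsv", "\n".join(lines) + "\n")
        profiles = data_io.read_profiles(p, max_rank=100)
        assert len(profiles) == 1
        assert len(profiles[0].targets) == 100
        assert profiles[0].targets[0] == "GENE1"
        assert profiles[0].targets[-1] == "GENE100"

    def test_empty_profile_file_ok(self, tmp_path):
        p = _write(tmp_path / "p.tsv", "compound_id\trank\ttarget\n")
        assert data_io.read_profiles(p) == []

    def test_duplicate_gene_in_profile_rejected(self):
        with pytest.raises(DataIOError, match="duplicate"):
            TargetProfile("C1", ("TP53", "TP53"), max_rank=10)

    def test_dataset_cross_validation(self, tmp_path, benchmark):
        dataset, _ = benchmark
        paths = dataset.write(tmp_path)
        compounds, herbs, profiles = data_io.read_dataset(
            paths["compounds"], paths["herbs"], paths["profiles"]
        )
        assert len(compounds) == 49
        assert len(herbs) == 10
        assert len(profiles) == 49
        # profile referencing a compound absent from the table is an error
        bad = _write(
            tmp_path / "extra.tsv",
            "compound_id\trank\ttarget\nNOPE\t1\tTP53\n",
        )
        with pytest.raises(DataIOError, match="NOPE"):
            data_io.read_dataset(paths["compounds"], paths["herbs"], bad)


class TestGMT:
    def test_roundtrip_preserves_sets(self, tmp_path):
        coll = GeneSetCollection()
        import random

        rnd = random.Random(11)
        for i in range(10):
            genes = {f"G{rnd.randrange(500):04d}" for _ in range(20)}
            coll.add(f"SET{i}", f"desc {i}", genes)
        path = tmp_path / "sets.gmt"
        data_io.write_gene_sets_gmt(coll, path)
        back = data_io.read_gene_sets_gmt(path)
        assert back.names() == sorted(coll.names())
        for name in coll.names():
            assert back.genes(name) == coll.genes(name)

    def test_case_collapse_within_line(self, tmp_path):
        p = _write(tmp_path / "s.gmt", "S1\tdesc\tTP53\ttp53\n")
        coll = data_io.read_gene_sets_gmt(p)
        assert coll.genes("S1") == frozenset({"TP53"})

    def test_short_line_reports_line_number(self, tmp_path):
        p = _write(tmp_path / "s.gmt", "S1\tdesc\tTP53\nBAD\tdesc\n")
        with pytest.raises(DataIOError, match=":2"):
            data_io.read_gene_sets_gmt(p)

    def test_duplicate_set_name_rejected(self, tmp_path):
        p = _write(tmp_path / "s.gmt", "S1\td\tTP53\nS1\td\tBRCA1\n")
        with pytest.raises(DataIOError, match="duplicate"):
            data_io.read_gene_sets_gmt(p)


class TestDEGTables:
    def test_parse_and_column_mapping(self, tmp_path):
        canonical = _write(
            tmp_path / "a.tsv",
            "gene\tlog2FoldChange\tpadj\nTP53\t1.5\t0.01\nBRCA1\t-2.0\t0.2\n",
        )
        permuted = _write(
            tmp_path / "b.tsv",
            "fdr\tsymbol\tlfc\n0.01\tTP53\t1.5\n0.2\tBRCA1\t-2.0\n",
        )
        t1 = data_io.read_deg_table(canonical, "c1")
        t2 = data_io.read_deg_table(
            permuted, "c1", gene_col="symbol", lfc_col="lfc", padj_col="fdr"
        )
        assert t1.frame.to_dict("records") == t2.frame.to_dict("records")

    def test_duplicate_gene_named_in_error(self, tmp_path):
        p = _write(
            tmp_path / "a.tsv",
            "gene\tlog2FoldChange\tpadj\nTP53\t1\t0.1\nTP53\t2\t0.2\n",
        )
        with pytest.raises(DataIOError, match="TP53"):
            data_io.read_deg_table(p, "c")

    def test_padj_outside_unit_interval_rejected(self, tmp_path):
        p = _write(
            tmp_path / "a.tsv",
            "gene\tlog2FoldChange\tpadj\nTP53\t1\t1.5\n",
        )
        with pytest.raises(DataIOError):
            data_io.read_deg_table(p, "c")

    def test_roundtrip(self, tmp_path, deg_pair):
        model, _, _ = deg_pair
        path = tmp_path / "deg.tsv"
        data_io.write_deg_table(model, path)
        back = data_io.read_deg_table(path, model.contrast_label)
        a = model.frame.sort_values("gene").reset_index(drop=True)
        b = back.frame.sort_values("gene").reset_index(drop=True)
        assert a.equals(b)


class TestPPI:
    def test_dedupe_keeps_max_and_drops_self_loops(self):
        ppi = PPIEdgeList.from_records(
            [
                ("B", "A", 0.5),
                ("A", "B", 0.9),
                ("C", "C", 0.99),
                ("a", "b", 0.2),
            ]
        )
        assert ppi.edges == [("A", "B", 0.9)]

    def test_score_bounds_enforced(self):
        with pytest.raises(DataIOError):
            PPIEdgeList.from_records([("A", "B", 1.2)])

    def test_roundtrip(self, tmp_path, benchmark):
        dataset, _ = benchmark
        path = tmp_path / "ppi.tsv"
        data_io.write_ppi_edges(dataset.ppi, path)
        back = data_io.read_ppi_edges(path)
        assert back.edges == dataset.ppi.edges
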