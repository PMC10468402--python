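"""Ligand-receptor database construction, merging, mapping and filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contacttracing.expression import ExpressionDataset
from contacttracing.lrdb import (ComplexDefinition, EmptyDatabaseError,
                                 InteractionRecord, OrthologMap, SchemaError,
                                 apply_complex_rule, filter_interactions,
                                 from_pairs, load_pair_table, map_orthologs,
                                 merge_databases)


def _write_simple(path, rows):
    pd.DataFrame(rows, columns=["ligand_gene_symbol", "receptor_gene_symbol"]).to_csv(
        path, sep="\t", index=False)


class TestLoadPairTable:
    def test_deduplicates_simple_pairs(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        _write_simple(p, [("L1", "R1"), ("L2", "R2"), ("L1", "R1")])
        db = load_pair_table(p, dialect="simple", source="src")
        assert len(db) == 2
        assert ("L1", "R1") in db and ("L2", "R2") in db

    def test_complex_aware_returns_complex_definitions(self, tmp_path):
        pairs = tmp_path / "pairs.csv"
        pd.DataFrame({"partner_a": ["IFNB1"], "partner_b": ["IFNAR"]}).to_csv(pairs, index=False)
        comp = tmp_path / "complexes.csv"
        pd.DataFrame({"complex_name": ["IFNAR"], "component_1": ["IFNAR1"],
                      "component_2": ["IFNAR2"]}).to_csv(comp, index=False)
        db = load_pair_table(pairs, dialect="complex-aware", complex_path=comp)
        assert len(db) == 1
        assert db.complexes["IFNAR"].components == ("IFNAR1", "IFNAR2")

    def test_missing_receptor_value_is_schema_error(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        (tmp_path / "pairs.tsv").write_text(
            "ligand_gene_symbol\treceptor_gene_symbol\nL1\t\n")
        with pytest.raises(SchemaError, match="receptor_gene_symbol"):
            load_pair_table(p, dialect="simple")

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        pd.DataFrame({"ligand_gene_symbol": ["L1"]}).to_csv(p, sep="\t", index=False)
        with pytest.raises(SchemaError, match="receptor_gene_symbol"):
            load_pair_table(p, dialect="simple")

    def test_empty_file_is_empty_database_error(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        _write_simple(p, [])
        with pytest.raises(EmptyDatabaseError):
            load_pair_table(p, dialect="simple")


class TestMerge:
    def test_union_cardinality_with_overlap(self):
        a = from_pairs([(f"L{i}", f"R{i}") for i in range(10)], source="a")
        b = from_pairs([(f"L{i}", f"R{i}") for i in range(7, 15)], source="b")
        merged = merge_databases(a, b)
        assert len(merged) == 10 + 8 - 3

    def test_self_merge_is_idempotent_and_tags_union(self):
        a = from_pairs([("L", "R")], source="a")
        b = from_pairs([("L", "R")], source="b")
        merged = merge_databases(a, b)
        assert len(merged) == 1
        assert merged.records[("L", "R")].sources == frozenset({"a", "b"})

    def test_disjoint_merge_adds(self):
        a = from_pairs([("L1", "R1")], source="a")
        b = from_pairs([("L2", "R2")], source="b")
        assert len(merge_databases(a, b)) == 2

    def test_reversed_pair_is_distinct(self):
        db = from_pairs([("A", "B"), ("B", "A")], source="s")
        assert len(db) == 2

    @settings(max_examples=50, deadline=None)
    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
    def test_merge_key_identity_and_commutativity(self, xs, ys):
        a = from_pairs([(f"L{i}", f"R{i}") for i in xs], source="a")
        b = from_pairs([(f"L{i}", f"R{i}") for i in ys], source="b")
        ab, ba = merge_databases(a, b), merge_databases(b, a)
        assert ab.keys == ba.keys
        assert len(ab) + len(a.keys & b.keys) == len(a) + len(b)


class TestOrthologMapping:
    def test_capitalization_fallback(self):
        db = from_pairs([("Lgals9", "Havcr2")], source="s")
        omap = OrthologMap(pairs=[("Havcr2", "HAVCR2")])
        mapped, averaged, report = map_orthologs(db, omap, {"LGALS9", "HAVCR2"})
        assert ("LGALS9", "HAVCR2") in mapped
        assert report["capitalized"] == 1 and report["one_to_one"] == 1

    def test_drop_list_removes_interactions(self):
        db = from_pairs([("H2-K1", "Cd8a"), ("L2", "R2")], source="s")
        omap = OrthologMap(pairs=[("H2-K1", "HLA-A"), ("H2-D1", "HLA-A"),
                                  ("Cd8a", "CD8A"), ("L2", "LL2"), ("R2", "RR2")],
                           drop=frozenset({"HLA-A"}))
        mapped, averaged, report = map_orthologs(db, omap, {"CD8A", "LL2", "RR2"})
        assert ("LL2", "RR2") in mapped and len(mapped) == 1
        assert report["dropped_multi"] == 1

    def test_multi_mapped_destination_becomes_averaged_gene(self):
        db = from_pairs([("Klrb1a", "Lig")], source="s")
        omap = OrthologMap(pairs=[("Klrb1a", "KLRB1"), ("Klrb1c", "KLRB1"),
                                  ("Lig", "LIG")])
        mapped, averaged, _ = map_orthologs(db, omap, {"LIG"})
        assert ("KLRB1_avg", "LIG") in mapped
        assert averaged["KLRB1_avg"] == ["Klrb1a", "Klrb1c"]

    def test_identity_map_keeps_database(self):
        db = from_pairs([("L1", "R1")], source="s")
        omap = OrthologMap(pairs=[("L1", "L1"), ("R1", "R1")])
        mapped, _, _ = map_orthologs(db, omap, {"L1", "R1"})
        assert mapped.keys == db.keys

    def test_unmappable_gene_drops_interaction(self):
        db = from_pairs([("Xyz1", "R1"), ("L2", "R1")], source="s")
        omap = OrthologMap(pairs=[("R1", "RR1"), ("L2", "LL2")])
        mapped, _, report = map_orthologs(db, omap, {"RR1", "LL2"})
        assert mapped.keys == {("LL2", "RR1")}
        assert report["unmapped"] == 1


class TestComplexRule:
    def _ds(self, counts, genes):
        obs = pd.DataFrame({"cell_id": [f"c{i}" for i in range(len(counts))],
                            "cell_type": "A", "condition": "x"})
        return ExpressionDataset.from_counts(np.asarray(counts), genes, obs)

    def test_complex_value_is_cellwise_min(self):
        ds = self._ds([[4, 1, 2, 10], [0, 5, 5, 10]], ["a", "b", "c", "hk"])
        out = apply_complex_rule(ds, [ComplexDefinition("cx", ("a", "b", "c"))])
        ln = out.gene_lognorm("cx")
        expected = np.minimum.reduce([out.gene_lognorm(g) for g in "abc"])
        np.testing.assert_allclose(ln, expected)
        assert ln[1] == 0.0  # any zero component zeroes the complex
        assert out.gene_counts("cx").tolist() == [1, 0]

    def test_two_identical_genes_reproduce_gene_value(self):
        ds = self._ds([[3, 3, 7]], ["a", "a2", "hk"])
        out = apply_complex_rule(ds, [ComplexDefinition("cx", ("a", "a2"))])
        np.testing.assert_allclose(out.gene_lognorm("cx"), out.gene_lognorm("a"))

    def test_unresolvable_complex_skipped(self):
        ds = self._ds([[3, 1]], ["a", "hk"])
        out = apply_complex_rule(ds, [ComplexDefinition("cx", ("a", "missing"))])
        assert "cx" not in out.genes

    def test_complex_never_exceeds_components(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 6, size=(20, 5))
        counts[:, -1] += 1  # keep library sizes positive
        ds = self._ds(counts, ["a", "b", "c", "d", "hk"])
        out = apply_complex_rule(ds, [ComplexDefinition("cx", ("a", "b", "c", "d"))])
        cx = out.gene_lognorm("cx")
        for g in "abcd":
            assert (cx <= out.gene_lognorm(g) + 1e-12).all()


class TestFilter:
    def _ds(self):
        counts = np.zeros((10, 3), dtype=int)
        counts[:, 0] = 1              # always detected
        counts[:3, 1] = 1             # detected in 30%
        obs = pd.DataFrame({"cell_id": [f"c{i}" for i in range(10)],
                            "cell_type": "A", "condition": "x"})
        return ExpressionDataset.from_counts(counts, ["lig", "rec", "dead"], obs)

    def test_undetected_receptor_removes_interaction(self):
        db = from_pairs([("lig", "rec"), ("lig", "dead")], source="s")
        out = filter_interactions(db, self._ds(), min_detect_frac=0.01)
        assert out.keys == {("lig", "rec")}

    def test_zero_threshold_keeps_everything(self):
        db = from_pairs([("lig", "rec"), ("lig", "dead")], source="s")
        out = filter_interactions(db, self._ds(), min_detect_frac=0.0)
        assert out.keys == db.keys

    def test_boundary_is_inclusive(self):
        db = from_pairs([("lig", "rec")], source="s")
        out = filter_interactions(db, self._ds(), min_detect_frac=0.3)
        assert ("lig", "rec") in out
        out = filter_interactions(db, self._ds(), min_detect_frac=0.300001)
        assert ("lig", "rec") not in out


def test_record_invariants():
    with pytest.raises(ValueError):
        InteractionRecord("", "R")
    with pytest.raises(ValueError):
        ComplexDefinition("cx", ("a",))
    with pytest.raises(ValueError):
        ComplexDefinition("cx", ("a", "a"))
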