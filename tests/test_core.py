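"""Target / interaction / ligand tests, summaries, response matrix, embedding."""

import numpy as np
import pandas as pd
import pytest

from contacttracing.core import (InteractionSummary, Thresholds,
                                 build_response_matrix, contrast_name,
                                 embed_responses, interaction_test, kneepoint,
                                 ligand_condition_test, rank_interactions,
                                 summarize_interactions, target_test,
                                 ContactTracingResults)
from contacttracing.lrdb import from_pairs


class TestTargetTest:
    def test_planted_effects_and_confounders_detected(self, tme, target_table):
        _, _, truth = tme
        eff = target_table[target_table.gene.str.startswith("EFF")]
        cnf = target_table[target_table.gene.str.startswith("CNF")]
        # confounders shift in target+ cells of every condition: strong signal
        assert (cnf.fdr < 0.05).mean() >= 0.9
        # condition-specific effects visible too, though diluted because they
        # shift expression in only one of three conditions
        assert (eff.fdr < 0.05).mean() >= 0.25
        assert (eff.fdr < 0.05).mean() < (cnf.fdr < 0.05).mean()

    def test_receptor_self_association(self, target_table):
        row = target_table[target_table.gene == "RCPT1"]
        assert row.fdr.item() < 1e-10  # sanity: conditioning gene is "significant"

    def test_null_genes_mostly_not_significant(self, target_table):
        null = target_table[target_table.gene.str.startswith("G")]
        assert (null.fdr < 0.05).mean() <= 0.07

    def test_constant_receptor_yields_empty_slice(self, tiny_dataset, caplog):
        # g4 is detected in every type-A cell, so there are no target- cells
        with caplog.at_level("WARNING"):
            out = target_test(tiny_dataset, "g4", "A", min_cells=2)
        assert out.empty
        assert "detected" in caplog.text

    def test_log2fc_sign_matches_planted_direction(self, target_table):
        cnf = target_table[target_table.gene.str.startswith("CNF")]
        assert (cnf.log2fc > 0).mean() >= 0.9


class TestInteractionTest:
    def test_separates_effects_from_confounders(self, interaction_table):
        eff = interaction_table[interaction_table.gene.str.startswith("EFF")]
        cnf = interaction_table[interaction_table.gene.str.startswith("CNF")]
        assert (eff.fdr < 0.25).mean() >= 0.6
        assert (cnf.fdr < 0.25).mean() <= 0.10

    def test_single_condition_is_error(self, tme):
        ds, _, _ = tme
        with pytest.raises(ValueError, match="aliased|present"):
            interaction_test(ds, "RCPT1", "Macrophage", ("CINhigh", "CINhigh"))

    def test_coi_must_be_in_contrast(self, tme):
        ds, _, _ = tme
        with pytest.raises(ValueError, match="condition_of_interest"):
            interaction_test(ds, "RCPT1", "Macrophage", ("CINhigh", "CINlow"),
                             condition_of_interest="STINGkd")


class TestLigandConditionTest:
    def test_planted_ligand_positive_and_significant(self, tme):
        ds, _, _ = tme
        out = ligand_condition_test(ds, ["LIG1"], "Tumor", ("CINhigh", "CINlow"))
        assert out.log2fc.item() > 0 and out.fdr.item() < 0.05

    def test_sign_flips_with_contrast_order(self, tme):
        ds, _, _ = tme
        hi = ligand_condition_test(ds, ["LIG1"], "Tumor", ("CINhigh", "CINlow"))
        lo = ligand_condition_test(ds, ["LIG1"], "Tumor", ("CINlow", "CINhigh"))
        assert np.sign(hi.log2fc.item()) == -np.sign(lo.log2fc.item())

    def test_missing_level_raises_naming_it(self, tme):
        ds, _, _ = tme
        with pytest.raises(ValueError, match="nosuch"):
            ligand_condition_test(ds, ["LIG1"], "Tumor", ("CINhigh", "nosuch"))

    def test_constant_ligand_degenerate(self, tiny_dataset):
        # gene g4 is detected in every cell of type A -> discrete degenerate;
        # with 3 cells the continuous part still fits, so just check log2fc finite
        out = ligand_condition_test(tiny_dataset, ["g4"], "A", ("hi", "lo"))
        assert len(out) == 1


def _summary(n_eff, lfc, fdr, degs=0, name="R"):
    cn = ["c1", "c2"]
    return InteractionSummary(
        ligand="L", donor_type="D", receptor=name, target_type="T",
        n_effects=dict(zip(cn, n_eff)), ligand_log2fc=dict(zip(cn, lfc)),
        ligand_fdr=dict(zip(cn, fdr)), n_target_degs=degs, significant=False)


class TestSignificanceRule:
    def _make_results(self, n_eff_sig, lig_lfc, lig_fdr):
        """Craft result tables that produce the given summary inputs."""
        res = ContactTracingResults(contrasts=[("hi", "lo"), ("hi", "kd")])
        genes = [f"g{i}" for i in range(30)]
        tt = pd.DataFrame({"gene": genes, "chisq": 1.0, "df": 2, "p": 0.5,
                           "log2fc": 0.1, "status": "ok", "fdr": 0.9})
        res.target[("R", "T")] = tt
        for cname, n_sig, lfc, fdr in zip(["hi-vs-lo", "hi-vs-kd"], n_eff_sig,
                                          lig_lfc, lig_fdr):
            it = tt.copy()
            it.loc[: n_sig - 1, "fdr"] = 0.01
            res.interaction[("R", "T", cname)] = it
            res.ligand[("D", cname)] = pd.DataFrame(
                {"gene": ["L"], "log2fc": [lfc], "fdr": [fdr]}).set_index("gene")
        return res

    def test_passing_all_clauses_is_significant(self):
        res = self._make_results([12, 12], [0.5, 0.3], [0.01, 0.01])
        db = from_pairs([("L", "R")], source="s")
        (s,) = summarize_interactions(res, db)
        assert s.significant and s.n_effects == {"hi-vs-lo": 12, "hi-vs-kd": 12}

    def test_count_below_ten_fails(self):
        res = self._make_results([9, 12], [0.5, 0.3], [0.01, 0.01])
        db = from_pairs([("L", "R")], source="s")
        (s,) = summarize_interactions(res, db)
        assert not s.significant

    def test_sign_disagreement_fails(self):
        res = self._make_results([12, 12], [0.5, -0.5], [0.01, 0.01])
        db = from_pairs([("L", "R")], source="s")
        (s,) = summarize_interactions(res, db)
        assert not s.significant

    def test_weak_ligand_fold_change_fails(self):
        res = self._make_results([12, 12], [0.10, 0.3], [0.01, 0.01])
        db = from_pairs([("L", "R")], source="s")
        (s,) = summarize_interactions(res, db)
        assert not s.significant


class TestRanking:
    def test_sort_by_effects_then_degs(self):
        s = [_summary([15, 15], [1, 1], [0, 0], degs=100, name="a"),
             _summary([12, 12], [1, 1], [0, 0], degs=50, name="b"),
             _summary([12, 12], [1, 1], [0, 0], degs=80, name="c"),
             _summary([3, 3], [1, 1], [0, 0], degs=10, name="d")]
        assert [x.receptor for x in rank_interactions(s)] == ["a", "c", "b", "d"]

    def test_stability_on_equal_keys(self):
        s = [_summary([5, 5], [1, 1], [0, 0], degs=10, name=n) for n in "zyx"]
        assert [x.receptor for x in rank_interactions(s)] == list("zyx")

    def test_single_element(self):
        s = [_summary([5, 5], [1, 1], [0, 0])]
        assert rank_interactions(s) == s


class TestResponseMatrix:
    def test_entries_from_bonferroni_p_and_lfc(self):
        tt = pd.DataFrame({"gene": ["g1"], "chisq": [9.0], "df": [2], "p": [0.01],
                           "log2fc": [2.0], "status": ["ok"], "fdr": [0.01]})
        m = build_response_matrix({("R", "T"): tt})
        # single-gene family: bonferroni p = raw p; -log10(0.01) * 2 = 4
        assert m.scores.loc[("R", "T"), "g1"] == pytest.approx(4.0)

    def test_padj_one_gives_zero_and_degenerate_gives_zero(self):
        tt = pd.DataFrame({"gene": ["g1", "g2"], "chisq": [0, 0], "df": [2, 0],
                           "p": [1.0, 1.0], "log2fc": [2.0, 2.0],
                           "status": ["ok", "degenerate"], "fdr": [1.0, np.nan]})
        m = build_response_matrix({("R", "T"): tt})
        assert (m.scores.loc[("R", "T")] == 0).all()
        assert ("R", "T") in m.zero_rows

    def test_entries_odd_under_lfc_sign_flip(self):
        rng = np.random.default_rng(0)
        tt = pd.DataFrame({"gene": [f"g{i}" for i in range(10)],
                           "chisq": 5.0, "df": 2,
                           "p": rng.uniform(1e-6, 1, 10),
                           "log2fc": rng.normal(size=10), "status": "ok",
                           "fdr": 0.5})
        flipped = tt.assign(log2fc=-tt.log2fc)
        m1 = build_response_matrix({("R", "T"): tt})
        m2 = build_response_matrix({("R", "T"): flipped})
        np.testing.assert_allclose(m1.scores.to_numpy(), -m2.scores.to_numpy())

    def test_block_diagonal_support_for_disjoint_effects(self):
        tables = {}
        for i in range(3):
            genes = [f"g{j:02d}" for j in range(12)]
            p = np.ones(12)
            lfc = np.zeros(12)
            p[4 * i: 4 * i + 4] = 1e-6
            lfc[4 * i: 4 * i + 4] = 2.0
            tables[(f"R{i}", "T")] = pd.DataFrame(
                {"gene": genes, "chisq": 1.0, "df": 2, "p": p, "log2fc": lfc,
                 "status": "ok", "fdr": p})
        m = build_response_matrix(tables)
        support = (m.scores.to_numpy() != 0)
        for i in range(3):
            row = support[list(m.scores.index).index((f"R{i}", "T"))]
            assert row[4 * i: 4 * i + 4].all() and row.sum() == 4


class TestEmbedding:
    def test_kneepoint_matches_independent_max_distance_computation(self):
        cumvar = [0.5, 0.8, 0.9, 0.95, 0.98, 1.0]
        # independent arithmetic: perpendicular distance to the chord
        v = np.asarray(cumvar)
        x = np.arange(len(v))
        best, besti = -1.0, 0
        for i in range(len(v)):
            num = abs((v[-1] - v[0]) * (x[i] - x[0]) - (x[-1] - x[0]) * (v[i] - v[0]))
            d = num / np.hypot(x[-1] - x[0], v[-1] - v[0])
            if d > best:
                best, besti = d, i
        assert kneepoint(cumvar) == besti + 1 == 2

    def test_kneepoint_degenerate_curves(self):
        assert kneepoint([1.0]) == 1
        assert kneepoint([0.6, 1.0]) == 1

    def _matrix(self, rows):
        genes = [f"g{j}" for j in range(20)]
        return build_response_matrix({
            (f"R{i}", "T"): pd.DataFrame({
                "gene": genes, "chisq": 1.0, "df": 2,
                "p": np.where(np.asarray(r) != 0, 1e-8, 1.0),
                "log2fc": r, "status": "ok", "fdr": 1.0})
            for i, r in enumerate(rows)})

    def test_dc1_separates_two_clusters(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(8):
            base = np.zeros(20)
            if i < 4:
                base[:8] = 2.0 + rng.normal(0, 0.05, 8)
            else:
                base[12:] = -2.0 + rng.normal(0, 0.05, 8)
            rows.append(base)
        m = embed_responses(self._matrix(rows))
        signs = np.sign(m.dc1.to_numpy())
        assert len(set(signs[:4])) == 1 and len(set(signs[4:])) == 1
        assert signs[0] != signs[4]

    def test_duplicated_rows_share_dc1_coordinate(self):
        rng = np.random.default_rng(2)
        base = [rng.normal(0, 1, 20) for _ in range(4)]
        rows = base + [base[0].copy()]  # exact duplicate of row 0
        m = embed_responses(self._matrix(rows))
        assert m.dc1.iloc[0] == pytest.approx(m.dc1.iloc[4], abs=1e-8)

    def test_too_few_rows_skips_dc1(self):
        m = embed_responses(self._matrix([np.ones(20), 2 * np.ones(20)]))
        assert m.dc1 is None


def test_contrast_name():
    assert contrast_name(("CINhigh", "CINlow")) == "CINhigh-vs-CINlow"
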