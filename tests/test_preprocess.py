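import numpy as np
import pandas as pd
import pytest

import elbp
from elbp import (
    GeneSetCollection,
    LabeledExpression,
    LigandReceptorTable,
    enrich_pathways,
    find_degs,
    normalize_log,
    qc_filter_cells,
    select_communication_pathways,
)

from oracles import enumeration_overrep_p


def _expr(counts, types, mito=None):
    counts = np.asarray(counts)
    cells = [f"c{i}" for i in range(counts.shape[1])]
    genes = [f"g{i}" for i in range(counts.shape[0])]
    return LabeledExpression(
        counts=counts,
        gene_ids=genes,
        cell_ids=cells,
        cell_type=pd.Series(types, index=cells),
        mito_fraction=None if mito is None else pd.Series(mito, index=cells),
    )


class TestQcFilter:
    def test_boundary_semantics(self):
        # cells: UMI 150 (drop), UMI 200 at mito 0.35 (keep), UMI 500 mito 0.5 (drop)
        expr = _expr(
            [[150, 200, 500]], ["A", "A", "A"], mito=[0.0, 0.35, 0.5]
        )
        kept = qc_filter_cells(expr, min_umi=200, max_mito=0.35)
        assert list(kept.cell_ids) == ["c1"]

    def test_permissive_thresholds_identity_and_idempotence(self, tiny_expr):
        out = qc_filter_cells(tiny_expr, min_umi=0, max_mito=1.0)
        assert list(out.cell_ids) == list(tiny_expr.cell_ids)
        once = qc_filter_cells(tiny_expr, min_umi=5, max_mito=1.0)
        twice = qc_filter_cells(once, min_umi=5, max_mito=1.0)
        assert list(once.cell_ids) == list(twice.cell_ids)

    def test_monotone_in_min_umi(self, tiny_expr):
        sizes = [
            qc_filter_cells(tiny_expr, min_umi=u, max_mito=1.0).n_cells
            for u in (0, 2, 5, 8)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_all_removed_is_error(self):
        expr = _expr([[10, 20]], ["A", "A"])
        with pytest.raises(ValueError, match="threshold"):
            qc_filter_cells(expr, min_umi=1000)

    def test_input_not_mutated(self, tiny_expr):
        before = tiny_expr.counts.copy()
        qc_filter_cells(tiny_expr, min_umi=5, max_mito=1.0)
        assert np.array_equal(tiny_expr.counts, before)


class TestNormalizeLog:
    def test_closed_form_single_gene(self):
        expr = _expr([[10000], [0]], ["A"])
        norm = normalize_log(expr)
        assert norm.iloc[0, 0] == pytest.approx(np.log1p(10000))

    def test_scale_invariance(self):
        a = _expr([[3], [7]], ["A"])
        b = _expr([[6], [14]], ["A"])
        assert np.allclose(normalize_log(a).to_numpy(), normalize_log(b).to_numpy())

    def test_equal_counts_equal_values(self):
        expr = _expr([[2, 2], [2, 2]], ["A", "A"])
        norm = normalize_log(expr).to_numpy()
        assert np.allclose(norm, norm[0, 0])

    def test_zero_cell_error_names_cell(self):
        expr = _expr([[1, 0]], ["A", "A"])
        with pytest.raises(ValueError, match="c1"):
            normalize_log(expr)


class TestFindDegs:
    def test_separated_gene_detected(self):
        rng = np.random.default_rng(0)
        n = 40
        counts = rng.poisson(2.0, size=(5, 2 * n))
        counts[0, :n] += 20  # gene g0 only high in type A
        expr = _expr(counts, ["A"] * n + ["B"] * n)
        degs = find_degs(expr, "A")
        assert degs["gene"].iloc[0] == "g0"
        assert degs["p_adj"].iloc[0] < 1e-6
        # sorted by p, adjusted >= raw
        assert (degs["p_adj"] >= degs["p"]).all()
        assert degs["p"].is_monotonic_increasing

    def test_degenerate_group_errors(self):
        expr = _expr([[1, 2]], ["A", "B"])
        with pytest.raises(ValueError, match="2 cells"):
            find_degs(expr, "A")
        with pytest.raises(KeyError):
            find_degs(_expr([[1, 2, 3, 4]], ["A", "A", "B", "B"]), "Z")

    def test_family_wise_error_on_permuted_null(self):
        """On label-permuted null data the FWER stays near the nominal 5%."""
        rng = np.random.default_rng(42)
        counts = rng.poisson(2.0, size=(40, 60))
        any_hit = 0
        for _ in range(100):
            types = rng.permutation(["A"] * 30 + ["B"] * 30)
            expr = _expr(counts, types)
            if len(find_degs(expr, "A")) > 0:
                any_hit += 1
        # binomial(100, 0.05) upper bound; Bonferroni is conservative
        assert any_hit <= 12


class TestEnrichPathways:
    def test_forced_hypergeometric_value(self):
        universe = [f"g{i}" for i in range(10)]
        degs = universe[:5]
        sets = GeneSetCollection(sets={"S": set(degs)}, descriptions={"S": ""})
        out = enrich_pathways(degs, sets, universe)
        assert out["p"].iloc[0] == pytest.approx(1 / 252)

    def test_disjoint_set_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        sets = GeneSetCollection(sets={"S": {"g8", "g9"}}, descriptions={"S": ""})
        out = enrich_pathways(["g0", "g1"], sets, universe, alpha=1.01)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_bh_adjustment_closed_form(self):
        # p = (0.01, 0.02) over two tests -> p_adj = (0.02, 0.02)
        universe = [f"g{i}" for i in range(12)]
        sets = GeneSetCollection(
            sets={"S1": set(universe[:3]), "S2": set(universe[:6])},
            descriptions={},
        )
        out = enrich_pathways(universe[:6], sets, universe, alpha=1.01)
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        assert np.allclose(out["p_adj"].to_numpy(), expected)
        assert (out["p_adj"] >= out["p"] - 1e-12).all()

    def test_empty_degs_empty_result(self):
        sets = GeneSetCollection(sets={"S": {"a"}}, descriptions={})
        assert enrich_pathways([], sets, ["a", "b"]).empty

    @pytest.mark.parametrize("set_size,n_degs", [(3, 4), (5, 5), (7, 3)])
    def test_matches_enumeration_oracle(self, set_size, n_degs):
        """Hypergeometric p equals subset-enumeration p on small universes."""
        rng = np.random.default_rng(set_size * 10 + n_degs)
        universe = [f"g{i}" for i in range(12)]
        members = set(rng.choice(universe, size=set_size, replace=False))
        degs = list(rng.choice(universe, size=n_degs, replace=False))
        sets = GeneSetCollection(sets={"S": members}, descriptions={})
        out = enrich_pathways(degs, sets, universe, alpha=1.01)
        oracle = enumeration_overrep_p(universe, members, degs)
        assert out["p"].iloc[0] == pytest.approx(oracle, rel=1e-9)


class TestSelectCommunicationPathways:
    @staticmethod
    def _enriched():
        return pd.DataFrame(
            {
                "pathway": ["P1", "P2"],
                "members": [["A", "B"], ["C", "D"]],
                "overlap": [["A", "B"], ["C", "D"]],
                "p": [0.001, 0.002],
                "p_adj": [0.002, 0.004],
            }
        )

    def test_pathway_with_ligand_kept_without_dropped(self):
        lr = LigandReceptorTable(
            pairs=pd.DataFrame({"ligand": ["A"], "receptor": ["Z"]})
        )
        out = select_communication_pathways(self._enriched(), lr)
        assert list(out["pathway"]) == ["P1"]

    def test_empty_lr_selects_nothing(self):
        lr = LigandReceptorTable(
            pairs=pd.DataFrame({"ligand": [], "receptor": []})
        )
        assert select_communication_pathways(self._enriched(), lr).empty
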