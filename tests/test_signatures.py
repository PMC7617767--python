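import numpy as np
import pandas as pd
import pytest

from vmsig.io_formats import DEResultTable, GeneSet
from vmsig.signatures import (
    ClusterExpressionStats,
    DerivationConfig,
    EmptyGeneSetError,
    derive_concordant,
    derive_core,
    derive_top_up,
    map_orthologs,
    refine_by_cluster_stats,
    subtract_gene_set,
)
from vmsig.synthetic_data import DeQuartetSpec, gen_de_quartet


def de(name, rows):
    """rows: list of (gene, log2fc, pvalue, fdr)"""
    return DEResultTable(
        name, pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue", "fdr"])
    )


class TestDeriveTopUp:
    def test_cardinality(self, small_de_table):
        cfg = DerivationConfig(top_n=100)
        out = derive_top_up(small_de_table, cfg)
        qualifying = small_de_table.data.query("fdr < 0.05 and log2fc > 0")
        assert len(qualifying) > 100
        assert len(out) == 100

    def test_sorted_by_fold_change(self):
        t = de("t", [("a", 2.0, 1e-4, 1e-3), ("b", 1.0, 1e-4, 1e-3), ("c", 3.0, 1e-4, 1e-3)])
        out = derive_top_up(t, DerivationConfig(top_n=2))
        assert out.members == {"c", "a"}

    def test_no_qualifying_gene_raises(self):
        t = de("t", [("a", 2.0, 0.5, 0.6), ("b", -1.0, 0.001, 0.01)])
        with pytest.raises(EmptyGeneSetError):
            derive_top_up(t, DerivationConfig())

    def test_fewer_than_top_n_warns(self, caplog):
        t = de("t", [("a", 2.0, 1e-4, 1e-3)])
        with caplog.at_level("WARNING"):
            out = derive_top_up(t, DerivationConfig(top_n=5))
        assert out.members == {"a"}
        assert "qualify" in caplog.text


class TestDeriveConcordant:
    def test_opposite_signs_included(self):
        up = de("up", [("G", 2.0, 1e-4, 0.01)])
        down = de("dn", [("G", -1.0, 1e-4, 0.01)])
        assert derive_concordant(up, down).members == {"G"}

    def test_same_sign_excluded(self):
        up = de("up", [("G", 2.0, 1e-4, 0.01), ("H", 1.0, 1e-4, 0.01)])
        down = de("dn", [("G", 1.0, 1e-4, 0.01), ("H", -1.0, 1e-4, 0.01)])
        assert derive_concordant(up, down).members == {"H"}

    def test_non_significant_down_excluded(self):
        up = de("up", [("G", 2.0, 1e-4, 0.01), ("H", 1.0, 1e-4, 0.01)])
        down = de("dn", [("G", -1.0, 0.15, 0.2), ("H", -1.0, 1e-4, 0.01)])
        assert derive_concordant(up, down).members == {"H"}

    def test_empty_intersection_raises(self):
        up = de("up", [("G", 2.0, 1e-4, 0.01)])
        down = de("dn", [("G", 1.0, 1e-4, 0.01)])
        with pytest.raises(EmptyGeneSetError):
            derive_concordant(up, down)


class TestDeriveCore:
    def _tables(self, genes_aux):
        """genes_aux: dict gene -> (aux1_lfc, aux2_lfc, rank_lfc, rank_fdr)"""
        aux1 = de("a1", [(g, v[0], 1e-6, 1e-6) for g, v in genes_aux.items()])
        aux2 = de("a2", [(g, v[1], 1e-6, 1e-6) for g, v in genes_aux.items()])
        rank = de("rk", [(g, v[2], v[3] / 2, v[3]) for g, v in genes_aux.items()])
        return aux1, aux2, rank

    def test_top_k_by_rank_fold_change(self):
        lfcs = {f"g{i}": (1.0, 1.0, lfc, 1e-8)
                for i, lfc in enumerate([5, 4, 3, 2, 1.5, 1])}
        aux1, aux2, rank = self._tables(lfcs)
        conc = GeneSet("c", frozenset(lfcs))
        out = derive_core(conc, aux1, aux2, rank, DerivationConfig(core_k=5))
        assert out.members == {"g0", "g1", "g2", "g3", "g4"}

    def test_aux_boundary_strict(self):
        lfcs = {"edge": (0.5, 1.0, 3.0, 1e-8), "ok": (0.6, 1.0, 2.0, 1e-8)}
        aux1, aux2, rank = self._tables(lfcs)
        out = derive_core(GeneSet("c", frozenset(lfcs)), aux1, aux2, rank)
        assert out.members == {"ok"}

    def test_missing_gene_fails_filter(self, caplog):
        lfcs = {"ok": (1.0, 1.0, 2.0, 1e-8)}
        aux1, aux2, rank = self._tables(lfcs)
        conc = GeneSet("c", frozenset({"ok", "absent"}))
        with caplog.at_level("WARNING"):
            out = derive_core(conc, aux1, aux2, rank)
        assert out.members == {"ok"}
        assert "absent" in caplog.text

    def test_fdr_boundary_strict(self):
        lfcs = {"sig": (1.0, 1.0, 2.0, 1e-8), "notsig": (1.0, 1.0, 3.0, 1e-4)}
        aux1, aux2, rank = self._tables(lfcs)
        out = derive_core(GeneSet("c", frozenset(lfcs)), aux1, aux2, rank)
        assert out.members == {"sig"}

    def test_zero_survivors_raises(self):
        lfcs = {"g": (0.1, 1.0, 2.0, 1e-8)}
        aux1, aux2, rank = self._tables(lfcs)
        with pytest.raises(EmptyGeneSetError):
            derive_core(GeneSet("c", frozenset(lfcs)), aux1, aux2, rank)


class TestSetAlgebra:
    def test_subtract(self, gene_set_factory):
        out = subtract_gene_set(gene_set_factory("b", "A", "B", "C"),
                                gene_set_factory("r", "B"), "diff")
        assert out.members == {"A", "C"}
        assert out.name == "diff"

    def test_subtract_nothing_is_identity(self, gene_set_factory):
        out = subtract_gene_set(gene_set_factory("b", "A"), frozenset(), "same")
        assert out.members == {"A"}

    def test_subtract_all_raises(self, gene_set_factory):
        with pytest.raises(EmptyGeneSetError):
            subtract_gene_set(gene_set_factory("b", "A"), gene_set_factory("r", "A"), "x")


class TestRefineByClusterStats:
    def stats(self, rows):
        return ClusterExpressionStats(pd.DataFrame(
            rows, columns=["gene", "log2fc_target_vs_background", "pct_expressed_background"]))

    def test_rule_and_boundaries(self, gene_set_factory):
        st = self.stats([("keep", 0.8, 10.0), ("pct_edge", 0.8, 30.0),
                         ("lfc_edge", 0.5, 5.0)])
        out = refine_by_cluster_stats(
            gene_set_factory("b", "keep", "pct_edge", "lfc_edge"), st)
        assert out.members == {"keep"}

    def test_missing_genes_dropped_with_log(self, gene_set_factory, caplog):
        st = self.stats([("keep", 0.8, 10.0)])
        with caplog.at_level("WARNING"):
            out = refine_by_cluster_stats(gene_set_factory("b", "keep", "absent"), st)
        assert out.members == {"keep"}
        assert "absent from stats" in caplog.text


class TestMapOrthologs:
    def test_identity_and_unmapped(self, gene_set_factory, caplog):
        with caplog.at_level("WARNING"):
            out = map_orthologs(gene_set_factory("m", "Foxc2", "Xyz1"),
                                {"Foxc2": "FOXC2"})
        assert out.members == {"FOXC2"}
        assert "unmapped" in caplog.text

    def test_many_to_one_collapses(self, gene_set_factory):
        out = map_orthologs(gene_set_factory("m", "a", "b"), {"a": "T", "b": "T"})
        assert out.members == {"T"}

    def test_one_to_many_expands(self, gene_set_factory):
        out = map_orthologs(gene_set_factory("m", "a"), {"a": ["T1", "T2"]})
        assert out.members == {"T1", "T2"}

    def test_nothing_mapped_raises(self, gene_set_factory):
        with pytest.raises(EmptyGeneSetError):
            map_orthologs(gene_set_factory("m", "a"), {"b": "T"})


@pytest.fixture(scope="module")
def quartet():
    return gen_de_quartet(DeQuartetSpec(seed=0))


class TestPipelineProperties:
    """Structural invariants of the derivation pipeline on synthetic data."""

    def test_outputs_are_subsets_of_inputs(self, quartet, small_de_table):
        top = derive_top_up(small_de_table, DerivationConfig())
        assert top.members <= set(small_de_table.genes)
        conc = derive_concordant(quartet.oe_up, quartet.kd_down)
        assert conc.members <= set(quartet.oe_up.genes)

    def test_core_nested_in_concordant(self, quartet):
        conc = derive_concordant(quartet.oe_up, quartet.kd_down)
        core = derive_core(conc, quartet.aux1, quartet.aux2, quartet.aux2)
        assert core.members <= conc.members

    def test_loosening_alpha_grows_concordant(self, quartet):
        strict = derive_concordant(quartet.oe_up, quartet.kd_down,
                                   DerivationConfig(alpha_sig=0.01))
        loose = derive_concordant(quartet.oe_up, quartet.kd_down,
                                  DerivationConfig(alpha_sig=0.2))
        assert strict.members <= loose.members

    def test_raising_core_k_grows_core(self, quartet):
        conc = derive_concordant(quartet.oe_up, quartet.kd_down)
        k3 = derive_core(conc, quartet.aux1, quartet.aux2, quartet.aux2,
                         DerivationConfig(core_k=3))
        k5 = derive_core(conc, quartet.aux1, quartet.aux2, quartet.aux2,
                         DerivationConfig(core_k=5))
        assert k3.members <= k5.members

    def test_planted_core_recovered_exactly(self, quartet):
        conc = derive_concordant(quartet.oe_up, quartet.kd_down)
        core = derive_core(conc, quartet.aux1, quartet.aux2, quartet.aux2)
        assert core.members == quartet.core_genes
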