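import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from vmsig.io_formats import CountMatrix, GeneSet
from vmsig.scoring import CellScore, aucell_score
from vmsig.endo_pipeline import (
    CellAnnotation,
    ScConfig,
    classify_endo_high,
    classify_tumor_clusters,
    fraction_above_cutoff,
    lognormalize,
    pseudo_bulk,
    qc_filter,
    rank_markers,
)
from vmsig.synthetic_data import ScSpec, gen_sc_dataset


def ann_frame(rows):
    return CellAnnotation(pd.DataFrame(
        rows, columns=["cell", "sample", "cluster", "n_features", "mito_pct",
                       "celltag_positive"]))


@pytest.fixture
def qc_fixture():
    """Five cells spanning every cell-level QC rule boundary."""
    cells = ["c1", "c2", "c3", "c4", "c5"]
    counts = CountMatrix(np.ones((3, 5), dtype=int), ["g1", "g2", "g3"], cells)
    ann = ann_frame([
        ("c1", "A", "k", 150, 1.0, False),    # below min features
        ("c2", "A", "k", 200, 12.0, False),   # mito too high
        ("c3", "A", "k", 5000, 5.0, False),   # passes
        ("c4", "A", "k", 9000, 5.0, False),   # passes (inclusive upper bound)
        ("c5", "A", "k", 9500, 5.0, False),   # above max features
    ])
    return counts, ann


class TestQcFilter:
    def test_cell_rules_leave_exactly_two(self, qc_fixture):
        counts, ann = qc_fixture
        out, out_ann = qc_filter(counts, ann, ScConfig(min_cells_per_feature=1))
        assert list(out.cell_ids) == ["c3", "c4"]
        assert len(out_ann) == 2

    def test_feature_detected_in_five_cells_kept(self):
        # gene g1 detected in exactly 5 cells of sample A: boundary inclusive
        counts = np.zeros((2, 6), dtype=int)
        counts[0, :5] = 1  # g1 in 5 cells
        counts[1, 0] = 1   # g2 in 1 cell
        cm = CountMatrix(counts, ["g1", "g2"], [f"c{i}" for i in range(6)])
        ann = ann_frame([(f"c{i}", "A", "k", 500, 1.0, False) for i in range(6)])
        out, _ = qc_filter(cm, ann, ScConfig())
        assert list(out.gene_ids) == ["g1"]

    def test_feature_survives_via_one_sample(self):
        # detected in 5 cells of sample A but only 1 of sample B -> kept
        counts = np.zeros((2, 10), dtype=int)
        counts[0, :5] = 1      # sample A cells
        counts[0, 5] = 1       # one sample B cell
        counts[1, :] = 1       # control gene everywhere
        cm = CountMatrix(counts, ["g1", "g2"], [f"c{i}" for i in range(10)])
        ann = ann_frame([(f"c{i}", "A" if i < 5 else "B", "k", 500, 1.0, False)
                         for i in range(10)])
        out, _ = qc_filter(cm, ann, ScConfig())
        assert "g1" in list(out.gene_ids)

    def test_all_zero_feature_dropped(self):
        counts = np.zeros((2, 6), dtype=int)
        counts[0, :] = 2
        cm = CountMatrix(counts, ["g1", "g2"], [f"c{i}" for i in range(6)])
        ann = ann_frame([(f"c{i}", "A", "k", 500, 1.0, False) for i in range(6)])
        out, _ = qc_filter(cm, ann, ScConfig())
        assert "g2" not in list(out.gene_ids)

    def test_idempotent(self):
        ds = gen_sc_dataset(ScSpec(seed=1, n_genes=300, n_tumor=150,
                                   n_endothelial=40, n_fibroblast=40,
                                   endothelial_signature_size=30,
                                   foxc2_program_size=15))
        # feature-count bounds scaled to the 300-gene universe
        cfg = ScConfig(min_features=30, max_features=290)
        once_cm, once_ann = qc_filter(ds.counts, ds.annotation, cfg)
        twice_cm, twice_ann = qc_filter(once_cm, once_ann, cfg)
        assert list(twice_cm.cell_ids) == list(once_cm.cell_ids)
        assert list(twice_cm.gene_ids) == list(once_cm.gene_ids)

    def test_missing_annotation_rejected(self, qc_fixture):
        counts, ann = qc_fixture
        short = CellAnnotation(ann.data.iloc[:3])
        with pytest.raises(ValueError, match="missing cells"):
            qc_filter(counts, short)


class TestLognormalize:
    def test_zero_preserved_and_arithmetic(self):
        counts = CountMatrix(np.array([[10, 0], [0, 5]]), ["g1", "g2"], ["c1", "c2"])
        out = lognormalize(counts, ScConfig(norm_scale=100))
        assert out.values.loc["g2", "c1"] == 0.0
        assert out.values.loc["g1", "c1"] == pytest.approx(np.log(1 + 100))
        assert out.value_scale == "log"

    def test_depth_invariance(self):
        a = CountMatrix(np.array([[4], [6]]), ["g1", "g2"], ["c"])
        b = CountMatrix(np.array([[8], [12]]), ["g1", "g2"], ["c"])
        va = lognormalize(a).values
        vb = lognormalize(b).values
        assert np.allclose(va.to_numpy(), vb.to_numpy())

    def test_zero_total_cell_named_in_error(self):
        counts = CountMatrix(np.array([[1, 0]]), ["g1"], ["good", "empty"])
        with pytest.raises(ValueError, match="empty"):
            lognormalize(counts)


class TestClassifyTumorClusters:
    def _ann(self, positives, size=10):
        return ann_frame([(f"c{i}", "A", "k", 500, 1.0, i < positives)
                          for i in range(size)])

    def test_above_threshold_is_tumor(self):
        assert classify_tumor_clusters(self._ann(3))["k"] == "tumor"

    def test_exact_threshold_is_non_tumor(self):
        assert classify_tumor_clusters(self._ann(2))["k"] == "non_tumor"

    def test_zero_positive_is_non_tumor(self):
        assert classify_tumor_clusters(self._ann(0))["k"] == "non_tumor"


class TestClassifyEndoHigh:
    def _scores(self, values, cells=None):
        cells = cells or [f"c{i:03d}" for i in range(len(values))]
        return CellScore(pd.Series(values, index=cells, dtype=float),
                         max_rank=10, signature_name="s",
                         n_signature_in_universe=5)

    def test_order_statistic(self):
        scores = self._scores(list(np.arange(1, 101) / 100.0))
        labels, threshold = classify_endo_high(scores)
        selected = {c for c, v in labels.items() if v == "endo_high"}
        assert selected == {f"c{i:03d}" for i in range(95, 100)}
        assert threshold == pytest.approx(0.96)

    def test_ceiling_arithmetic(self):
        scores = self._scores(list(np.linspace(0, 1, 20)))
        labels, _ = classify_endo_high(scores)
        assert sum(v == "endo_high" for v in labels.values()) == 1

    def test_all_equal_takes_identifier_first(self, caplog):
        scores = self._scores([0.5] * 40)
        with caplog.at_level("WARNING"):
            labels, _ = classify_endo_high(scores)
        selected = sorted(c for c, v in labels.items() if v == "endo_high")
        assert selected == ["c000", "c001"]
        assert "tie" in caplog.text.lower()

    def test_within_subset(self):
        scores = self._scores(list(np.linspace(0, 1, 40)))
        subset = [f"c{i:03d}" for i in range(20)]
        labels, _ = classify_endo_high(scores, within=subset)
        assert set(labels) == set(subset)


class TestFractionAboveCutoff:
    def _pair(self):
        scores = CellScore(pd.Series([0.1, 0.2, 0.3], index=["a", "b", "c"]),
                           max_rank=5, signature_name="s", n_signature_in_universe=3)
        ann = ann_frame([("a", "S1", "k", 500, 1.0, False),
                         ("b", "S1", "k", 500, 1.0, False),
                         ("c", "S1", "k", 500, 1.0, False)])
        return scores, ann

    def test_counting(self):
        scores, ann = self._pair()
        out = fraction_above_cutoff(scores, ann, 0.15)
        assert out.loc[0, "fraction"] == pytest.approx(2 / 3)

    def test_cutoff_one_gives_zero(self):
        scores, ann = self._pair()
        assert fraction_above_cutoff(scores, ann, 1.0)["fraction"].iloc[0] == 0.0

    def test_monotone_in_cutoff(self):
        scores, ann = self._pair()
        fracs = [fraction_above_cutoff(scores, ann, c)["fraction"].iloc[0]
                 for c in np.linspace(0, 1, 11)]
        assert (np.diff(fracs) <= 0).all()


class TestRankMarkers:
    def test_fold_change_arithmetic(self):
        # mean linearised rates 3 vs 1 with pseudocount 1 -> log2(4/2) = 1
        vals = np.log1p(np.array([[3.0, 3.0, 1.0, 1.0]]))
        expr = make_matrix(vals, genes=["g"], samples=list("abcd"), scale="log")
        labels = {"a": "endo_high", "b": "endo_high", "c": "rest", "d": "rest"}
        res = rank_markers(expr, labels, pseudocount_rate=1.0)
        assert res.table.loc[0, "log2fc"] == pytest.approx(1.0)

    def test_flat_gene_no_effect(self):
        vals = np.log1p(np.array([[2.0] * 6, [1, 2, 3, 1, 2, 3]]))
        expr = make_matrix(vals, genes=["flat", "var"],
                           samples=[f"c{i}" for i in range(6)], scale="log")
        labels = {f"c{i}": ("endo_high" if i < 3 else "rest") for i in range(6)}
        res = rank_markers(expr, labels, pseudocount_rate=1.0)
        flat = res.table.set_index("gene").loc["flat"]
        assert flat["log2fc"] == 0.0
        assert flat["p"] > 0.9

    def test_label_swap_negates_metrics(self):
        rng = np.random.default_rng(7)
        vals = np.log1p(rng.poisson(2.0, size=(5, 10)).astype(float))
        expr = make_matrix(vals, scale="log")
        labels = {f"s{j}": ("endo_high" if j < 4 else "rest") for j in range(10)}
        swapped = {c: ("rest" if v == "endo_high" else "endo_high")
                   for c, v in labels.items()}
        a = rank_markers(expr, labels).ranked.series.sort_index()
        b = rank_markers(expr, swapped).ranked.series.sort_index()
        assert np.allclose(a.to_numpy(), -b.to_numpy())

    def test_empty_group_rejected(self):
        expr = make_matrix([[1.0, 2.0]], scale="log")
        with pytest.raises(ValueError, match="non-empty"):
            rank_markers(expr, {"s0": "rest", "s1": "rest"})


class TestPseudoBulk:
    def _data(self):
        counts = CountMatrix(np.array([[2, 3, 7], [1, 0, 4]]),
                             ["g1", "g2"], ["c1", "c2", "c3"])
        ann = ann_frame([("c1", "S1", "endo", 500, 1.0, False),
                         ("c2", "S1", "endo", 500, 1.0, False),
                         ("c3", "S2", "endo", 500, 1.0, False)])
        return counts, ann

    def test_sums_within_sample(self):
        counts, ann = self._data()
        pb = pseudo_bulk(counts, ann, "endo")
        assert pb.values.loc["g1", "S1"] == 5  # 2 + 3
        assert pb.values.loc["g1", "S2"] == 7

    def test_total_counts_conserved(self):
        counts, ann = self._data()
        pb = pseudo_bulk(counts, ann, "endo")
        assert pb.values.to_numpy().sum() == counts.counts.sum()

    def test_single_cell_per_sample_is_identity(self):
        counts, ann = self._data()
        sub_ann = CellAnnotation(ann.data[ann.data.cell != "c2"])
        sub = counts.subset(cells=["c1", "c3"])
        pb = pseudo_bulk(sub, sub_ann, "endo")
        assert pb.values["S1"].tolist() == [2, 1]
        assert pb.values["S2"].tolist() == [7, 4]

    def test_unknown_cluster_rejected(self):
        counts, ann = self._data()
        with pytest.raises(ValueError, match="no cells"):
            pseudo_bulk(counts, ann, "nope")
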