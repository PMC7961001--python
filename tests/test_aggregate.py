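"""Significance matrix, hierarchical clustering, recurrent features."""

import numpy as np
import pandas as pd
import pytest

from hallmarksurv.aggregate import (
    Dendrogram,
    SignificanceMatrix,
    hierarchical_cluster,
    recurrent_features,
    significance_matrix,
)
from hallmarksurv.containers import GeneSet, GeneSetCollection
from hallmarksurv.errors import EstimationError
from hallmarksurv.survival import CoxFitResult, CutoffScanResult


def fake_scan(feature, significant, evaluable=True, p=0.01):
    fit = None
    if evaluable:
        fit = CoxFitResult(hr=2.0, ci_low=1.2, ci_high=3.3, p=p,
                           n_low=10, n_high=10, events_low=5, events_high=8)
    return CutoffScanResult(
        feature_id=feature,
        cutoffs=np.array([1.0]),
        p_values=np.array([p]),
        q_values=np.array([p]),
        best_cutoff=1.0 if evaluable else None,
        best_fit=fit,
        significant=significant,
        evaluable=evaluable,
        n_samples=20,
    )


def sets_of(**kwargs):
    return GeneSetCollection(
        tuple(GeneSet(name, "d", tuple(genes)) for name, genes in kwargs.items())
    )


class TestSignificanceMatrix:
    def test_no_significant_genes_all_zero(self):
        scans = {"T1": {"g1": fake_scan("g1", False), "g2": fake_scan("g2", False)}}
        matrix = significance_matrix(scans, sets_of(A=["g1", "g2"]))
        assert matrix.percent.loc["A", "T1"] == 0.0

    def test_one_of_four_is_25_percent(self):
        scans = {
            "T1": {
                "g1": fake_scan("g1", True),
                "g2": fake_scan("g2", False),
                "g3": fake_scan("g3", False),
                "g4": fake_scan("g4", False),
            }
        }
        matrix = significance_matrix(scans, sets_of(A=["g1", "g2", "g3", "g4"]))
        assert matrix.percent.loc["A", "T1"] == 25.0
        assert matrix.numerator.loc["A", "T1"] == 1
        assert matrix.denominator.loc["A", "T1"] == 4

    def test_shared_gene_counts_in_both_hallmarks(self):
        scans = {"T1": {"g1": fake_scan("g1", True), "g2": fake_scan("g2", False),
                        "g3": fake_scan("g3", False)}}
        matrix = significance_matrix(
            scans, sets_of(A=["g1", "g2"], B=["g1", "g3"])
        )
        assert matrix.numerator.loc["A", "T1"] == 1
        assert matrix.numerator.loc["B", "T1"] == 1

    def test_unscanned_hallmark_is_missing_not_zero(self):
        scans = {"T1": {"g1": fake_scan("g1", True)}}
        matrix = significance_matrix(scans, sets_of(A=["g1"], B=["zz"]))
        assert np.isnan(matrix.percent.loc["B", "T1"])
        assert matrix.percent.loc["A", "T1"] == 100.0

    def test_non_evaluable_scans_excluded_from_denominator(self):
        scans = {"T1": {"g1": fake_scan("g1", True),
                        "g2": fake_scan("g2", False, evaluable=False)}}
        matrix = significance_matrix(scans, sets_of(A=["g1", "g2"]))
        assert matrix.denominator.loc["A", "T1"] == 1

    def test_invariant_to_orderings(self):
        scans = {
            "T1": {"g1": fake_scan("g1", True), "g2": fake_scan("g2", False)},
            "T2": {"g2": fake_scan("g2", True), "g1": fake_scan("g1", False)},
        }
        a = significance_matrix(scans, sets_of(A=["g1", "g2"]))
        reordered = {"T2": scans["T2"], "T1": scans["T1"]}
        b = significance_matrix(reordered, sets_of(A=["g2", "g1"]))
        pd.testing.assert_frame_equal(a.percent, b.percent)


def matrix_from(frame: pd.DataFrame) -> SignificanceMatrix:
    return SignificanceMatrix(
        percent=frame, numerator=frame.copy(), denominator=frame.notna().astype(float)
    )


class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_zero(self):
        frame = pd.DataFrame(
            [[10.0, 20.0], [10.0, 20.0], [90.0, 5.0]],
            index=["a", "b", "c"], columns=["T1", "T2"],
        )
        dendro = hierarchical_cluster(matrix_from(frame))
        first = dendro.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == 0.0

    def test_three_points_average_linkage_heights(self):
        frame = pd.DataFrame([[0.0], [1.0], [5.0]], index=["a", "b", "c"], columns=["T"])
        dendro = hierarchical_cluster(matrix_from(frame), linkage="average")
        heights = dendro.linkage[:, 2]
        np.testing.assert_allclose(heights, [1.0, 4.5])

    def test_duplicated_column_scales_heights_sqrt2(self):
        rng = np.random.default_rng(6)
        base = pd.DataFrame(rng.uniform(0, 100, size=(5, 3)),
                            index=list("abcde"), columns=["T1", "T2", "T3"])
        doubled = pd.concat([base, base.add_suffix("_copy", axis=1)], axis=1)
        d1 = hierarchical_cluster(matrix_from(base))
        d2 = hierarchical_cluster(matrix_from(doubled))
        np.testing.assert_allclose(
            d2.linkage[:, 2], np.sqrt(2) * d1.linkage[:, 2], rtol=1e-12
        )
        np.testing.assert_array_equal(d1.linkage[:, :2], d2.linkage[:, :2])

    @pytest.mark.parametrize("linkage", ["average", "complete"])
    def test_heights_non_decreasing(self, linkage):
        rng = np.random.default_rng(7)
        frame = pd.DataFrame(rng.uniform(0, 100, size=(8, 4)))
        frame.index = [f"h{i}" for i in range(8)]
        dendro = hierarchical_cluster(matrix_from(frame), linkage=linkage)
        heights = dendro.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_missing_cells_imputed_with_warning(self, caplog):
        frame = pd.DataFrame(
            [[10.0, np.nan], [10.0, 0.0], [50.0, 60.0]],
            index=["a", "b", "c"], columns=["T1", "T2"],
        )
        with caplog.at_level("WARNING"):
            dendro = hierarchical_cluster(matrix_from(frame))
        assert "imputing" in caplog.text
        # NaN treated as 0: rows a and b become identical
        assert dendro.linkage[0, 2] == 0.0

    def test_tumor_axis_clusters_columns(self):
        frame = pd.DataFrame(
            [[1.0, 1.0, 50.0], [2.0, 2.0, 60.0]],
            index=["a", "b"], columns=["T1", "T2", "T3"],
        )
        dendro = hierarchical_cluster(matrix_from(frame), axis="tumors")
        assert dendro.labels == ("T1", "T2", "T3")
        assert {int(dendro.linkage[0, 0]), int(dendro.linkage[0, 1])} == {0, 1}

    def test_newick_roundtrip_through_dendropy(self):
        import dendropy

        frame = pd.DataFrame(
            [[0.0], [1.0], [5.0]], index=["a", "b", "c"], columns=["T"]
        )
        dendro = hierarchical_cluster(matrix_from(frame))
        tree = dendropy.Tree.get(data=dendro.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {"a", "b", "c"}


class TestRecurrentFeatures:
    @staticmethod
    def scans_with(sig_counts: dict[str, int], n_tumors: int = 12):
        scans = {}
        for t in range(n_tumors):
            tumor = f"T{t:02d}"
            scans[tumor] = {
                gene: fake_scan(gene, significant=t < count)
                for gene, count in sig_counts.items()
            }
        return scans

    def test_below_threshold_excluded(self):
        scans = self.scans_with({"g1": 3})
        assert "g1" not in recurrent_features(scans, min_tumors=10).index

    def test_boundary_included(self):
        scans = self.scans_with({"g1": 10, "g2": 12})
        table = recurrent_features(scans, min_tumors=10)
        assert list(table.index) == ["g2", "g1"]
        assert table.loc["g1", "n_significant"] == 10

    def test_monotone_in_min_tumors(self):
        scans = self.scans_with({"g1": 4, "g2": 8, "g3": 11})
        sizes = [len(recurrent_features(scans, min_tumors=k)) for k in (2, 6, 10)]
        assert sizes == sorted(sizes, reverse=True)

    def test_too_few_tumors_is_error(self):
        scans = self.scans_with({"g1": 2}, n_tumors=3)
        with pytest.raises(EstimationError):
            recurrent_features(scans, min_tumors=10)

    def test_planted_pan_prognostic_gene_ranks_first(self):
        # one gene significant in 11 of 12 simulated tumor scans, others sporadic
        rng = np.random.default_rng(13)
        scans = {}
        for t in range(12):
            tumor = f"T{t:02d}"
            per_gene = {"planted": fake_scan("planted", significant=t < 11, p=1e-6)}
            for g in range(10):
                per_gene[f"noise{g}"] = fake_scan(
                    f"noise{g}", significant=rng.uniform() < 0.2, p=0.05
                )
            scans[tumor] = per_gene
        table = recurrent_features(scans, min_tumors=10)
        assert table.index[0] == "planted"
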