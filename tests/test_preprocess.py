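"""QC boundaries, normalization contract, clustering and subsampling."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from stmia.io import CountMatrix
from stmia.preprocess import (
    ClusterAssignment,
    QCThresholds,
    apply_qc,
    balanced_subsample,
    cluster_hierarchical,
    filter_cells,
    filter_genes,
    filter_spots,
    normalize,
    select_variable_genes,
)
from stmia.simulate import generate_st

from conftest import small_params

TH = QCThresholds()


def _matrix_with_detected(detected_counts, n_genes=300, unit_kind="spot"):
    """Units detecting exactly the requested numbers of genes (1 count each)."""
    counts = np.zeros((n_genes, len(detected_counts)), dtype=int)
    for j, d in enumerate(detected_counts):
        counts[:d, j] = 1
    return CountMatrix(
        [f"g{i}" for i in range(n_genes)],
        [f"u{j}" for j in range(len(detected_counts))],
        counts,
        unit_kind,
    )


class TestSpotFilter:
    def test_boundary_at_200_detected_genes(self):
        cm = _matrix_with_detected([199, 200, 250])
        out = filter_spots(cm, TH)
        assert out.unit_ids == ["u1", "u2"]

    def test_identity_and_idempotence(self):
        cm = _matrix_with_detected([220, 260])
        once = filter_spots(cm, TH)
        assert once.unit_ids == cm.unit_ids
        twice = filter_spots(once, TH)
        assert twice.unit_ids == once.unit_ids
        assert np.array_equal(twice.counts, once.counts)

    def test_empty_result_is_an_error(self):
        cm = _matrix_with_detected([10, 20])
        with pytest.raises(ValueError, match="removed every unit"):
            filter_spots(cm, TH)

    def test_wrong_unit_kind_rejected(self):
        cm = _matrix_with_detected([250], unit_kind="cell")
        with pytest.raises(ValueError, match="spot"):
            filter_spots(cm, TH)


class TestCellFilter:
    def _cell_matrix(self, mito_fracs, detected=300, n_genes=400):
        # one MT gene; its count sets the unit's mitochondrial fraction
        counts = np.zeros((n_genes, len(mito_fracs)), dtype=int)
        gene_ids = ["MT-X"] + [f"g{i}" for i in range(n_genes - 1)]
        for j, f in enumerate(mito_fracs):
            counts[1 : detected, j] = 1
            rest = detected - 1
            counts[0, j] = round(f / (1 - f) * rest) if f < 1 else rest
        return CountMatrix(gene_ids, [f"c{j}" for j in range(len(mito_fracs))], counts, "cell")

    def test_mito_boundary_is_strict(self):
        # exactly 20% stays ("exceeded 20%"), above goes
        cm = self._cell_matrix([0.05, 0.20, 0.25], detected=301)
        out = filter_cells(cm, TH)
        kept = set(out.unit_ids)
        assert kept == {"c0", "c1"}

    def test_low_gene_cell_removed_despite_low_mito(self):
        cm = _matrix_with_detected([150, 300], unit_kind="cell")
        # add an MT gene so the mito criterion is active
        counts = np.vstack([np.ones(2, dtype=int), cm.counts])
        cm2 = CountMatrix(["MT-X"] + cm.gene_ids, cm.unit_ids, counts, "cell")
        out = filter_cells(cm2, TH)
        assert out.unit_ids == ["u1"]

    def test_no_mt_genes_warns_and_skips_mito(self):
        cm = _matrix_with_detected([300, 400], unit_kind="cell")
        with pytest.warns(UserWarning, match="mitochondrial"):
            out = filter_cells(cm, TH)
        assert out.n_units == 2


class TestGeneFilter:
    def test_boundary_at_three_cells(self):
        counts = np.array(
            [
                [1, 1, 1, 0],  # 3 cells -> keep
                [1, 1, 0, 0],  # 2 cells -> drop
                [0, 0, 0, 0],  # all-zero -> drop
                [2, 3, 4, 5],  # keep
            ]
        )
        cm = CountMatrix(["a", "b", "c", "d"], list("wxyz"), counts, "cell")
        out = filter_genes(cm, TH)
        assert out.gene_ids == ["a", "d"]
        again = filter_genes(out, TH)
        assert again.gene_ids == out.gene_ids

    def test_filters_commute_on_generator_output(self, st_small):
        cm = st_small[0]
        a = filter_genes(filter_spots(cm, TH), TH)
        b = filter_spots(filter_genes(cm, TH), TH)
        assert a.gene_ids == b.gene_ids and a.unit_ids == b.unit_ids
        assert np.array_equal(a.counts, b.counts)


class TestNormalize:
    def test_single_unit_scale_factor_one(self):
        cm = CountMatrix(["a", "b"], ["u"], np.array([[3], [5]]), "spot")
        nm = normalize(cm)
        assert nm.scale_target == 8
        assert np.allclose(nm.values[:, 0], np.log2(1 + np.array([3, 5])))

    def test_two_units_median_scaling(self):
        # totals 100 and 300 -> median 200 -> factors 2 and 2/3
        counts = np.array([[100, 0], [0, 300]])
        cm = CountMatrix(["a", "b"], ["u", "v"], counts, "spot")
        nm = normalize(cm)
        assert nm.scale_target == 200
        assert np.isclose(nm.values[0, 0], np.log2(1 + 200))
        assert np.isclose(nm.values[1, 1], np.log2(1 + 200))
        assert nm.values[0, 1] == 0 and nm.values[1, 0] == 0

    def test_rescaled_totals_reproduce_scale_target(self, st_small):
        nm = normalize(apply_qc(st_small[0], TH))
        totals = nm.linear().sum(axis=0)
        assert np.allclose(totals, nm.scale_target, rtol=1e-6)

    def test_zero_total_unit_rejected(self):
        cm = CountMatrix(["a"], ["u", "v"], np.array([[5, 0]]), "spot")
        with pytest.raises(ValueError, match="zero total"):
            normalize(cm)


class TestVariableGenes:
    def test_constant_gene_never_selected(self):
        values = np.array([[1.0, 1.0, 1.0], [0.0, 2.0, 1.0]])
        from stmia.preprocess import NormalizedMatrix

        nm = NormalizedMatrix(["const", "var"], list("abc"), values, 10.0)
        gs = select_variable_genes(nm, 1)
        assert gs.genes == frozenset({"var"})

    def test_n_top_equal_n_genes_selects_all(self, st_small):
        nm = normalize(st_small[0])
        gs = select_variable_genes(nm, nm.n_genes)
        assert gs.genes == frozenset(nm.gene_ids)

    def test_planted_markers_enriched_in_top_decile(self, st_small):
        cm, _, truth = st_small
        nm = normalize(apply_qc(cm, TH))
        n_top = nm.n_genes // 10
        top = select_variable_genes(nm, n_top).genes
        planted = set().union(*(s.genes for s in truth.marker_sets))
        planted &= set(nm.gene_ids)
        frac_in_top = len(top & planted) / len(planted)
        assert frac_in_top > len(top) / nm.n_genes * 3  # >3x background rate


class TestClustering:
    def test_k_extremes(self, st_small):
        nm = normalize(apply_qc(st_small[0], TH))
        genes = select_variable_genes(nm, 50)
        one = cluster_hierarchical(nm, genes, 1)
        assert one.k == 1 and set(one.labels) == {0}
        n = nm.n_units
        singles = cluster_hierarchical(nm, genes, n)
        assert singles.k == n and len(set(singles.labels)) == n
        with pytest.raises(ValueError, match="out of range"):
            cluster_hierarchical(nm, genes, n + 1)

    def test_recovers_planted_regions(self):
        aris = []
        for seed in range(3):
            cm, _, truth = generate_st(small_params(seed=seed, units_per_group=100))
            nm = normalize(apply_qc(cm, TH))
            ca = cluster_hierarchical(nm, select_variable_genes(nm, 100), 3)
            planted = truth.group_label.loc[nm.unit_ids].to_numpy()
            aris.append(adjusted_rand_score(planted, ca.labels))
        assert min(aris) >= 0.9

    def test_permutation_equivariance(self, st_small, rng):
        from stmia.preprocess import NormalizedMatrix

        nm = normalize(apply_qc(st_small[0], TH))
        genes = select_variable_genes(nm, 80)
        ca = cluster_hierarchical(nm, genes, 3)
        perm = rng.permutation(nm.n_units)
        nm2 = NormalizedMatrix(
            nm.gene_ids,
            [nm.unit_ids[i] for i in perm],
            nm.values[:, perm],
            nm.scale_target,
        )
        ca2 = cluster_hierarchical(nm2, genes, 3)
        lab1 = dict(zip(ca.unit_ids, ca.labels))
        lab2 = dict(zip(ca2.unit_ids, ca2.labels))
        # same partition: labels agree unit-by-unit after size-based renumbering
        assert all(lab1[u] == lab2[u] for u in nm.unit_ids)

    def test_labels_renumbered_by_size(self, st_small):
        nm = normalize(apply_qc(st_small[0], TH))
        ca = cluster_hierarchical(nm, select_variable_genes(nm, 80), 3)
        sizes = np.bincount(ca.labels)
        assert (np.diff(sizes) <= 0).all()


class TestBalancedSubsample:
    def _ca(self):
        ids = [f"u{i}" for i in range(10)]
        return ClusterAssignment(ids, np.array([0] * 6 + [1] * 4), 2)

    def test_whole_group_when_exact(self):
        out = balanced_subsample(self._ca(), 4, seed=0)
        assert out[-4:] == ["u6", "u7", "u8", "u9"]
        assert len(out) == 8

    def test_length_and_determinism(self):
        a = balanced_subsample(self._ca(), 3, seed=42)
        b = balanced_subsample(self._ca(), 3, seed=42)
        assert a == b and len(a) == 6
        c = balanced_subsample(self._ca(), 3, seed=43)
        assert len(c) == 6

    def test_undersized_group_error_names_group(self):
        with pytest.raises(ValueError, match="cluster 1"):
            balanced_subsample(self._ca(), 5, seed=0)
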