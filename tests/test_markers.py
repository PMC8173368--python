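"""Bimodal LRT, fold changes and the one-vs-rest marker table."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from stmia.markers import bimod_lrt, find_all_markers, log_fold_change, marker_sets
from stmia.preprocess import ClusterAssignment, QCThresholds, apply_qc, normalize
from stmia.simulate import generate_sc

from conftest import small_params


def oracle_bimod(x, y):
    """Direct likelihood evaluation of the zero-inflated normal LRT.

    Kept deliberately naive (explicit loops over scipy logpdf calls) so it is
    an independent check on the vectorized sufficient-statistics path.
    """

    def loglik(v):
        v = np.asarray(v, float)
        pos = v[v > 0]
        n, m = len(v), len(pos)
        pi = min(max(m / n, 1e-5), 1 - 1e-5)
        ll = (n - m) * np.log(1 - pi) + m * np.log(pi)
        if m:
            mu = pos.mean()
            sd = pos.std(ddof=1) if m > 1 else 1.0
            if not sd > 1e-6:
                sd = 1.0
            ll += sum(stats.norm.logpdf(val, mu, sd) for val in pos)
        return ll

    both = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    stat = max(2 * (loglik(x) + loglik(y) - loglik(both)), 0.0)
    return stat, stats.chi2.sf(stat, df=3)


class TestBimodLRT:
    def test_identical_samples_give_null_result(self):
        x = [0.0, 1.5, 2.0, 0.0, 1.0]
        stat, p = bimod_lrt(x, x)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_all_zero_groups_degenerate(self):
        assert bimod_lrt([0, 0, 0], [0, 0, 0]) == (0.0, 1.0)

    def test_matches_direct_likelihood_oracle(self):
        x = [0.0, 1.2, 1.4, 0.0, 1.3]
        y = [2.5, 2.6, 2.4, 2.5, 0.0]
        stat, p = bimod_lrt(x, y)
        ostat, op = oracle_bimod(x, y)
        assert stat == pytest.approx(ostat, abs=1e-8)
        assert p == pytest.approx(op, abs=1e-8)

    @given(
        st.lists(
            st.one_of(st.just(0.0), st.floats(0.1, 8.0, allow_nan=False)),
            min_size=2,
            max_size=15,
        ),
        st.lists(
            st.one_of(st.just(0.0), st.floats(0.1, 8.0, allow_nan=False)),
            min_size=2,
            max_size=15,
        ),
    )
    def test_symmetric_and_nonnegative(self, x, y):
        s1, p1 = bimod_lrt(x, y)
        s2, p2 = bimod_lrt(y, x)
        assert s1 == pytest.approx(s2, abs=1e-9)
        assert p1 == pytest.approx(p2, abs=1e-9)
        assert s1 >= 0.0
        assert 0.0 <= p1 <= 1.0
        ostat, _ = oracle_bimod(x, y)
        assert s1 == pytest.approx(ostat, abs=1e-7)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            bimod_lrt([], [1.0])


class TestLogFoldChange:
    def test_identical_is_zero(self):
        assert log_fold_change([1, 2, 0], [1, 2, 0]) == pytest.approx(0.0)

    def test_antisymmetric(self):
        x, y = [0.0, 2.0, 3.0], [1.0, 1.0, 0.0]
        assert log_fold_change(x, y) == pytest.approx(-log_fold_change(y, x))

    def test_forced_by_formula(self):
        # linear means 3 vs 1 -> ln((3+1)/(1+1)) = ln 2
        x = [np.log2(1 + 3.0)] * 4
        y = [np.log2(1 + 1.0)] * 4
        assert log_fold_change(x, y) == pytest.approx(np.log(2.0))


@pytest.fixture(scope="module")
def sc_marker_run():
    params = small_params(
        seed=11,
        units_per_group=150,
        phase_frac={"G1": 1.0, "S": 0.0, "G2M": 0.0},
        frac_low_quality=0.0,
    )
    cm, truth = generate_sc(params)
    nm = normalize(apply_qc(cm, QCThresholds()))
    labels = truth.group_label.loc[nm.unit_ids].to_numpy()
    names = sorted(set(labels))
    ca = ClusterAssignment(
        list(nm.unit_ids), np.array([names.index(l) for l in labels]), len(names)
    )
    table = find_all_markers(nm, ca)
    return nm, ca, table, truth, names


class TestFindAllMarkers:
    def test_planted_markers_recovered(self, sc_marker_run):
        """High recall of the planted markers with bounded contamination.

        Recall of planted markers should be essentially complete.  Precision
        is bounded away from 1 by design of the procedure: pre-test gating on
        |logFC| enriches the tested null genes for inflated effects, so the
        realized false-discovery proportion exceeds BH's nominal level.
        """
        nm, ca, table, truth, names = sc_marker_run
        sets = marker_sets(table)
        planted = {s.name: s.genes & set(nm.gene_ids) for s in truth.marker_sets}
        for i, name in enumerate(names):
            got = sets[i].genes
            want = planted[name]
            recall = len(got & want) / len(want)
            precision = len(got & want) / len(got)
            assert recall >= 0.95
            assert precision >= 0.6

    def test_min_pct_gate_excludes_rare_genes(self, sc_marker_run):
        nm, ca, table, *_ = sc_marker_run
        rare = table[np.maximum(table.pct_in, table.pct_out) < 0.01]
        assert rare.empty

    def test_logfc_gate_enforced(self, sc_marker_run):
        table = sc_marker_run[2]
        assert (table.log_fc.abs() >= 0.1).all()

    def test_bh_adjustment_monotone_and_dominates_p(self, sc_marker_run):
        table = sc_marker_run[2]
        assert (table.p_adj >= table.p_value - 1e-15).all()
        for _, sub in table.groupby("cluster"):
            s = sub.sort_values("p_value")
            assert (np.diff(s.p_adj.to_numpy()) >= -1e-12).all()

    def test_deterministic(self, sc_marker_run):
        nm, ca, table, *_ = sc_marker_run
        again = find_all_markers(nm, ca)
        assert table.equals(again)

    def test_singleton_cluster_skipped_with_warning(self):
        rng = np.random.default_rng(0)
        values = rng.gamma(1.0, 1.0, size=(20, 7))
        from stmia.preprocess import NormalizedMatrix

        nm = NormalizedMatrix(
            [f"g{i}" for i in range(20)], [f"u{j}" for j in range(7)], values, 10.0
        )
        ca = ClusterAssignment(list(nm.unit_ids), np.array([0, 0, 0, 1, 1, 1, 2]), 3)
        with pytest.warns(UserWarning, match="fewer than 2"):
            table = find_all_markers(nm, ca, min_pct=0.0, logfc_threshold=0.0)
        assert 2 not in set(table.cluster)

    def test_needs_two_clusters(self, sc_marker_run):
        nm = sc_marker_run[0]
        ca = ClusterAssignment(list(nm.unit_ids), np.zeros(nm.n_units, dtype=int), 1)
        with pytest.raises(ValueError, match="2 clusters"):
            find_all_markers(nm, ca)


class TestMarkerSets:
    def test_no_significant_rows_gives_empty_sets(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "gene": ["a", "b"],
                "cluster": [0, 1],
                "log_fc": [0.5, 0.3],
                "p_value": [0.5, 0.9],
                "p_adj": [0.8, 0.9],
                "pct_in": [0.5, 0.5],
                "pct_out": [0.5, 0.5],
            }
        )
        with pytest.warns(UserWarning, match="no significant"):
            sets = marker_sets(table)
        assert all(len(s) == 0 for s in sets.values())

    def test_direction_up_excludes_negative_lfc(self, sc_marker_run):
        table = sc_marker_run[2]
        sets = marker_sets(table, direction="up")
        for cluster, s in sets.items():
            sub = table[(table.cluster == cluster) & table.gene.isin(sorted(s.genes))]
            assert (sub.log_fc > 0).all()
            assert (sub.p_adj < 0.05).all()
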