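import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from aktsubtypes import (
    CohortConfig,
    ConsensusParams,
    build_consensus,
    consensus_cdf_summary,
    generate_cohort,
    median_center,
    select_panel,
    silhouette_filter,
    subset_to_panel,
    survival_k_scan,
)
from aktsubtypes.consensus import ConsensusResult, _silhouette_on_dissimilarity

from conftest import make_matrix


def _panel_matrix(cohort):
    centered = median_center(cohort.expression)
    return subset_to_panel(centered, select_panel(centered, list(cohort.truth_panel)))


def _make_result(consensus, ids, labels, sil, k):
    return ConsensusResult(
        k=k,
        sample_ids=tuple(ids),
        consensus=consensus,
        labels=pd.Series(list(labels), index=ids),
        silhouette=pd.Series(sil, index=ids),
    )


def _block_consensus(sizes, within=1.0, between=0.0):
    n = sum(sizes)
    c = np.full((n, n), between, dtype=float)
    start = 0
    labels = []
    for b, s in enumerate(sizes, start=1):
        c[start:start + s, start:start + s] = within
        labels += [b] * s
        start += s
    np.fill_diagonal(c, 1.0)
    return c, labels


class TestBuildConsensus:
    def test_single_full_run_gives_binary_comembership(self, small_panel_matrix):
        r = build_consensus(
            small_panel_matrix, 3, ConsensusParams(n_iter=1, subsample_frac=1.0, seed=2)
        )
        vals = r.consensus
        assert np.isin(vals, [0.0, 1.0]).all()
        # a 0/1 co-membership matrix is an equivalence relation: equal rows
        for i in range(vals.shape[0]):
            same = vals[i] == 1.0
            assert np.allclose(vals[same][:, same], 1.0)

    def test_well_separated_blobs_saturate_consensus(self):
        cohort = generate_cohort(
            CohortConfig(n_samples=40, n_genes=200, k_true=2, effect_size=6.0,
                         noise_sd=0.5, seed=4, term_plant={})
        )
        m = _panel_matrix(cohort)
        r = build_consensus(m, 2, ConsensusParams(n_iter=200, seed=0))
        truth = cohort.truth_labels.to_numpy()
        same = truth[:, None] == truth[None, :]
        off = ~np.eye(len(truth), dtype=bool)
        assert r.consensus[same & off].min() >= 0.95
        assert r.consensus[~same].max() <= 0.05

    def test_matrix_invariants(self, small_panel_matrix, fast_params):
        r = build_consensus(small_panel_matrix, 3, fast_params)
        c = r.consensus
        assert np.allclose(c, c.T)
        assert c.min() >= 0.0 and c.max() <= 1.0
        assert np.allclose(np.diag(c), 1.0)
        assert set(r.labels.unique()) == {1, 2, 3}

    def test_deterministic_given_seed(self, small_panel_matrix, fast_params):
        a = build_consensus(small_panel_matrix, 3, fast_params)
        b = build_consensus(small_panel_matrix, 3, fast_params)
        assert np.array_equal(a.consensus, b.consensus)
        assert a.labels.equals(b.labels)

    def test_permutation_equivariance_on_saturated_consensus(self):
        """On well-separated data the consensus is binary, so reordering
        samples must reorder the consensus matrix exactly."""
        cohort = generate_cohort(
            CohortConfig(n_samples=30, n_genes=150, k_true=2, effect_size=6.0,
                         seed=8, term_plant={})
        )
        m = _panel_matrix(cohort)
        perm = np.random.default_rng(0).permutation(m.n_samples)
        m_perm = type(m)(m.data.iloc[:, perm], centered=True)
        p = ConsensusParams(n_iter=150, seed=1)
        r1 = build_consensus(m, 2, p)
        r2 = build_consensus(m_perm, 2, p)
        assert np.array_equal(r1.consensus[np.ix_(perm, perm)], r2.consensus)

    def test_recovers_planted_labels(self, small_cohort, small_panel_matrix):
        r = build_consensus(small_panel_matrix, 3, ConsensusParams(n_iter=200, seed=0))
        ari = adjusted_rand_score(small_cohort.truth_labels.to_numpy(), r.labels.to_numpy())
        assert ari >= 0.9

    def test_too_few_samples_rejected(self, fast_params):
        m = make_matrix(np.random.default_rng(0).normal(size=(5, 2)), centered=True)
        with pytest.raises(ValueError, match="at least"):
            build_consensus(m, 3, fast_params)


class TestCdfSummary:
    def test_ideal_binary_consensus_area_is_zero_proportion(self):
        c, labels = _block_consensus([4, 4, 4])
        r = _make_result(c, [f"s{i}" for i in range(12)], labels,
                                  np.ones(12), 3)
        n_off = 12 * 11 // 2
        n_zero = n_off - 3 * (4 * 3 // 2)
        assert r.cdf_area() == pytest.approx(n_zero / n_off)

    def test_selects_k_where_consensus_turns_binary(self):
        """Blurry at k=2, perfectly binary at k=3, negligible gain beyond."""
        results = []
        c2, l2 = _block_consensus([8, 4], within=0.7, between=0.3)
        results.append(_make_result(c2, [f"s{i}" for i in range(12)], l2,
                                             np.ones(12), 2))
        c3, l3 = _block_consensus([4, 4, 4])
        results.append(_make_result(c3, [f"s{i}" for i in range(12)], l3,
                                             np.ones(12), 3))
        c4, l4 = _block_consensus([4, 4, 2, 2])
        c4[8:10, 10:12] = c4[10:12, 8:10] = 0.45  # split block stays ambiguous
        results.append(_make_result(c4, [f"s{i}" for i in range(12)], l4,
                                             np.ones(12), 4))
        table = consensus_cdf_summary(results, delta_threshold=0.15)
        assert table.attrs["suggested_k"] == 3
        assert table["cdf_area"].is_monotonic_increasing

    def test_area_nondecreasing_in_k_on_synthetic_cohort(self, small_panel_matrix):
        rs = [
            build_consensus(small_panel_matrix, k, ConsensusParams(n_iter=100, seed=3))
            for k in (2, 3, 4, 5)
        ]
        table = consensus_cdf_summary(rs)
        assert table["cdf_area"].is_monotonic_increasing

    def test_requires_two_ks(self, small_panel_matrix, fast_params):
        r = build_consensus(small_panel_matrix, 2, fast_params)
        with pytest.raises(ValueError):
            consensus_cdf_summary([r])


class TestSilhouette:
    def test_hand_computed_two_cluster_toy(self):
        # d(1,2)=d(3,4)=1, all cross distances 10 -> s = (10-1)/10 for all
        d = np.array([
            [0, 1, 10, 10],
            [1, 0, 10, 10],
            [10, 10, 0, 1],
            [10, 10, 1, 0],
        ], dtype=float)
        s = _silhouette_on_dissimilarity(d, np.array([1, 1, 2, 2]))
        assert np.allclose(s, 0.9)

    def test_boundary_sample_dropped(self):
        # sample 0 equidistant between both clusters: a == b -> s = 0 -> dropped
        c = np.array([
            [1.0, 0.5, 0.5, 0.5],
            [0.5, 1.0, 1.0, 0.0],
            [0.5, 1.0, 1.0, 0.0],
            [0.5, 0.0, 0.0, 1.0],
        ])
        # cluster 1 = {0,1,2}, cluster 2 = {3}; for sample 0: a = 0.5, b = 0.5
        r = _make_result(c, ["s0", "s1", "s2", "s3"], [1, 1, 1, 2],
                                  _silhouette_on_dissimilarity(
                                      1 - c + np.diag(np.diag(c) - 1), np.array([1, 1, 1, 2])),
                                  2)
        kept, dropped = silhouette_filter(r)
        assert "s0" in dropped
        assert "s3" in dropped  # singleton cluster gets s = 0

    def test_separated_blobs_all_kept(self, small_panel_matrix):
        r = build_consensus(small_panel_matrix, 3, ConsensusParams(n_iter=200, seed=1))
        kept, dropped = silhouette_filter(r)
        assert len(dropped) == 0
        assert r.silhouette.min() > 0.9

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError, match="single cluster"):
            _silhouette_on_dissimilarity(np.zeros((3, 3)), np.array([1, 1, 1]))


class TestSurvivalKScan:
    def test_single_pair_correction_factor_one(self, small_cohort, small_panel_matrix):
        r = build_consensus(small_panel_matrix, 2, ConsensusParams(n_iter=150, seed=0))
        scan = survival_k_scan([r], small_cohort.clinical)
        from aktsubtypes import logrank

        kept, _ = silhouette_filter(r)
        labels = r.labels.loc[kept]
        clin = small_cohort.clinical.set_index("sample_id").loc[labels.index]
        a = clin[labels.to_numpy() == 1]
        b = clin[labels.to_numpy() == 2]
        _, raw_p = logrank(a["os_years"], a["event"], b["os_years"], b["event"])
        assert scan.loc[0, "min_corrected_p"] == pytest.approx(raw_p)
        assert scan.loc[0, "n_pairs"] == 1

    def test_distinct_hazards_favor_true_k(self, small_cohort, small_panel_matrix):
        rs = [
            build_consensus(small_panel_matrix, k, ConsensusParams(n_iter=150, seed=2))
            for k in (2, 3)
        ]
        scan = survival_k_scan(rs, small_cohort.clinical).set_index("k")
        assert scan.loc[3, "min_corrected_p"] <= 1.0
        assert scan.loc[3, "n_pairs"] == 3
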