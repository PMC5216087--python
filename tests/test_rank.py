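"""Feature ranking (RFIS / AUC / t-test / FDR) and correlation clustering."""

import numpy as np
import pytest
import scipy.stats

from breedlip import (BootstrapScheme, assign_clusters, correlation_clusters,
                      rank_features)
from breedlip.rank import rank_with_report

from conftest import tiny_matrix

SCHEME = BootstrapScheme(n_bootstraps=8, ntree=60, seed=3)


def welch_p(a, b):
    """Closed-form Welch t-test for the oracle check."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return 2 * scipy.stats.t.sf(abs(t), df)


class TestRankFeatures:
    def test_welch_p_matches_closed_form(self):
        a = [4.1, 5.2, 3.9, 4.8, 5.0, 4.4]  # fixed 6-vs-6 toy vectors
        b = [6.0, 6.3, 5.1, 6.8, 5.9, 6.2]
        X = np.array([a + b]).T
        y = ["g1"] * 6 + ["g2"] * 6
        ranked = rank_features(tiny_matrix(X), y, SCHEME, classes=("g2", "g1"))
        assert ranked[0].p_value == pytest.approx(welch_p(a, b), rel=1e-10)
        assert ranked[0].direction == "decreased"  # g1 lower than g2

    def test_single_planted_feature_ranks_first_everywhere(self, rng):
        X = rng.normal(size=(24, 80), scale=0.5)
        y = np.array(["a", "b"] * 12)
        X[y == "b", 17] += 4.0
        ranked = rank_features(tiny_matrix(X), y, SCHEME, classes=("a", "b"))
        top = ranked[0]
        assert top.name == tiny_matrix(X).feature_names[17]
        assert top.rfis == max(f.rfis for f in ranked)
        assert top.p_value == min(f.p_value for f in ranked)
        assert top.uni_auc == max(f.uni_auc for f in ranked)
        assert top.direction == "elevated"

    def test_fdr_null_control(self):
        hits = []
        for rep in range(20):
            local = np.random.default_rng(rep).normal(size=(20, 120))
            ranked = rank_features(
                tiny_matrix(local), ["a", "b"] * 10,
                BootstrapScheme(n_bootstraps=2, ntree=10, seed=rep))
            hits.append(np.mean([f.q_value < 0.05 for f in ranked]))
        # binomial bound: fraction with q<0.05 should stay near/below alpha
        assert np.mean(hits) <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / (20 * 120))

    def test_q_at_least_p_and_auc_folded(self, rng):
        X = rng.normal(size=(16, 50))
        ranked = rank_features(tiny_matrix(X), ["a", "b"] * 8, SCHEME)
        for f in ranked:
            assert f.q_value >= f.p_value - 1e-15
            assert f.uni_auc >= 0.5

    def test_zero_variance_feature_flagged(self, rng):
        X = rng.normal(size=(12, 5))
        X[:, 2] = 7.0
        ranked = rank_features(tiny_matrix(X), ["a", "b"] * 6, SCHEME)
        flagged = [f for f in ranked if f.degenerate]
        assert len(flagged) == 1
        assert flagged[0].p_value == 1.0 and flagged[0].rfis == 0.0

    def test_null_rfis_centred_near_zero(self, rng):
        X = rng.normal(size=(20, 100))
        ranked = rank_features(tiny_matrix(X), ["a", "b"] * 10, SCHEME)
        vals = np.array([f.rfis for f in ranked])
        assert abs(vals.mean()) < 3 * vals.std() / np.sqrt(len(vals)) + 1e-4

    def test_report_shares_forests_with_ranking(self, rng):
        X = rng.normal(size=(20, 40))
        y = ["a", "b"] * 10
        ranked, report = rank_with_report(tiny_matrix(X), y, SCHEME)
        lone = rank_features(tiny_matrix(X), y, SCHEME)
        assert [f.rfis for f in ranked] == [f.rfis for f in lone]
        assert report.n_bootstraps == SCHEME.n_bootstraps


class TestCorrelationClusters:
    def test_scaled_copy_same_cluster(self, rng):
        base = rng.normal(size=20)
        X = np.column_stack([base, 2.0 * base, rng.normal(size=20)])
        m = tiny_matrix(X)
        clusters = correlation_clusters(m)
        by_feature = {f: c.cluster_id for c in clusters for f in c.members}
        names = m.feature_names
        assert by_feature[names[0]] == by_feature[names[1]]
        assert by_feature[names[2]] != by_feature[names[0]]

    def test_independent_noise_mostly_singletons(self):
        X = np.random.default_rng(0).normal(size=(96, 40))
        clusters = correlation_clusters(tiny_matrix(X))
        assert max(len(c.members) for c in clusters) <= 2  # rare chance edges
        assert np.mean([len(c.members) == 1 for c in clusters]) > 0.9

    def test_chained_adduct_series_single_linkage(self, rng):
        # a ~ b strongly, b ~ c strongly, a ~ c weaker: one chained cluster
        lat = rng.normal(size=50)
        a = lat + rng.normal(scale=0.3, size=50)
        b = lat + rng.normal(scale=0.3, size=50)
        c = b + rng.normal(scale=0.3, size=50)
        clusters = correlation_clusters(tiny_matrix(np.column_stack([a, b, c])))
        assert len(clusters) == 1
        assert len(clusters[0].members) == 3

    def test_adduct_series_recreation_one_cluster_of_four(self, rng):
        # re-creation of a published top cluster: three phosphatidylcholine
        # ions plus the 13C isotopologue of one of them, all driven by one
        # compound family, cluster together at |r| > 0.8
        lat = rng.normal(scale=0.45, size=84)
        cols, mzs = [], [720.5525, 748.5836, 749.5871, 776.6158]
        for _ in mzs:
            cols.append(2 ** (15 + lat + rng.normal(scale=0.15, size=84)))
        cols.append(2 ** rng.normal(15, 0.5, size=84))  # unrelated feature
        m = tiny_matrix(np.column_stack(cols), mz=mzs + [500.25],
                        rt=[372, 398, 399, 424, 100])
        clusters = correlation_clusters(m.log2(), threshold=0.8)
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 4]

    def test_invariant_to_feature_order_and_affine_rescale(self, rng):
        lat = rng.normal(size=30)
        X = np.column_stack([lat + rng.normal(scale=0.2, size=30)
                             for _ in range(3)] + [rng.normal(size=30)])
        m1 = tiny_matrix(X)
        perm = [2, 0, 3, 1]
        m2 = tiny_matrix(5.0 * X[:, perm] + 3.0,
                         mz=[m1.mz[j] for j in perm],
                         rt=[m1.rt[j] for j in perm])
        c1 = {frozenset(c.members) for c in correlation_clusters(m1)}
        c2 = {frozenset(c.members) for c in correlation_clusters(m2)}
        assert c1 == c2

    def test_constant_feature_excluded_with_warning(self, rng, caplog):
        X = rng.normal(size=(15, 3))
        X[:, 1] = 4.2
        m = tiny_matrix(X)
        with caplog.at_level("WARNING"):
            clusters = correlation_clusters(m)
        members = {f for c in clusters for f in c.members}
        assert m.feature_names[1] not in members
        assert "constant" in caplog.text

    def test_candidate_order_defines_seed_feature(self, rng):
        base = rng.normal(size=25)
        X = np.column_stack([base + rng.normal(scale=0.1, size=25),
                             base + rng.normal(scale=0.1, size=25)])
        m = tiny_matrix(X)
        ranked_order = [m.feature_names[1], m.feature_names[0]]
        clusters = correlation_clusters(m, candidates=ranked_order)
        assert clusters[0].seed_feature == m.feature_names[1]

    def test_assign_clusters_annotates_ranked(self, rng):
        base = rng.normal(size=30)
        X = np.column_stack([base, base * 3, rng.normal(size=30)])
        m = tiny_matrix(X)
        ranked = rank_features(m, ["a", "b"] * 15, SCHEME)
        clusters = correlation_clusters(m)
        assign_clusters(ranked, clusters)
        ids = {f.name: f.cluster_id for f in ranked}
        assert ids[m.feature_names[0]] == ids[m.feature_names[1]]

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            correlation_clusters(tiny_matrix(np.eye(3)), threshold=1.5)
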