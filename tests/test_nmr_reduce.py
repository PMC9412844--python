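import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import adjusted_rand_score

from kcmnet.errors import ValidationError
from kcmnet.nmr_reduce import (
    AgglomerationMap,
    agglomerate_features,
    pool_agglomerates,
    select_cophenetic_threshold,
    select_informative_buckets,
)

from conftest import make_table


class TestSelection:
    def _signal_data(self, rng, n=200, noise_feats=50, sd=0.1):
        y = rng.integers(0, 2, size=n)
        signal = y + rng.normal(0, sd, size=n)
        X = np.column_stack([signal, rng.normal(size=(n, noise_feats))])
        ids = ["signal"] + [f"noise{i}" for i in range(noise_feats)]
        return make_table(X, ids, omics="metabolome_nmr", units="intensity"), y

    def test_constant_feature_never_kept(self, rng):
        t, y = self._signal_data(rng, n=60, noise_feats=5)
        vals = t.values.copy()
        vals["flat"] = 3.14
        t2 = make_table(vals.to_numpy(), list(vals.columns),
                        list(vals.index), omics="metabolome_nmr")
        res = select_informative_buckets(t2, y, seed=0)
        assert "flat" not in res.kept_feature_ids
        assert res.optimizer_trace["n_constant_dropped"] == 1

    def test_signal_feature_recovered_across_seeds(self, rng):
        hits = 0
        for seed in range(10):
            t, y = self._signal_data(np.random.default_rng(seed))
            res = select_informative_buckets(t, y, seed=seed)
            hits += "signal" in res.kept_feature_ids
        assert hits >= 9

    def test_permuted_labels_keep_no_more_features(self):
        kept_true, kept_perm = [], []
        for seed in range(8):
            local = np.random.default_rng(seed)
            t, y = self._signal_data(local)
            res_t = select_informative_buckets(t, y, seed=seed)
            res_p = select_informative_buckets(t, local.permutation(y), seed=seed)
            kept_true.append(len(res_t.kept_feature_ids))
            kept_perm.append(len(res_p.kept_feature_ids))
        assert np.mean(kept_perm) <= np.mean(kept_true)

    def test_feature_order_invariance(self, rng):
        t, y = self._signal_data(rng, n=80, noise_feats=10)
        res = select_informative_buckets(t, y, seed=3)
        perm = list(rng.permutation(t.feature_ids))
        res_p = select_informative_buckets(t.subset_features(perm), y, seed=3)
        assert set(res.kept_feature_ids) == set(res_p.kept_feature_ids)

    def test_small_class_suggests_fewer_folds(self, rng):
        t, _ = self._signal_data(rng, n=20, noise_feats=3)
        y = np.array([0] * 17 + [1] * 3)
        with pytest.raises(ValidationError, match="folds"):
            select_informative_buckets(t, y, folds=5)

    def test_single_class_rejected(self, rng):
        t, _ = self._signal_data(rng, n=20, noise_feats=3)
        with pytest.raises(ValidationError, match="2 classes"):
            select_informative_buckets(t, np.zeros(20))


def cut_has_singletons(Z, h):
    labels = fcluster(Z, t=h, criterion="distance")
    _, sizes = np.unique(labels, return_counts=True)
    return sizes.min() == 1


class TestCopheneticThreshold:
    def test_two_features_merge_height_returned(self):
        Z = np.array([[0.0, 1.0, 0.3, 2.0]])
        assert select_cophenetic_threshold(Z) == pytest.approx(0.3)

    def test_identical_features_give_zero(self, rng):
        row = rng.normal(size=10)
        X = np.column_stack([row, row, row])
        t = make_table(X, omics="metabolome_nmr")
        amap = agglomerate_features(t, cut="auto")
        assert amap.cut_height == pytest.approx(0.0, abs=1e-12)
        assert len(amap.pooled_ids) == 1

    def test_matches_exhaustive_cut_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 21))
            pts = rng.normal(size=(n, 4))
            Z = linkage(pts, method="average")
            got = select_cophenetic_threshold(Z)
            # oracle: exhaustively cut at every merge height, pick the
            # smallest without singleton clusters
            oracle = None
            for h in sorted(np.unique(Z[:, 2])):
                if not cut_has_singletons(Z, h):
                    oracle = h
                    break
            assert got == pytest.approx(oracle)

    def test_cap_returned_with_warning_when_no_cut_below(self):
        Z = np.array([[0.0, 1.0, 0.95, 2.0]])
        with pytest.warns(UserWarning, match="cap"):
            assert select_cophenetic_threshold(Z, cap=0.7) == 0.7


class TestAgglomeration:
    def test_identical_pair_single_cluster_any_cut(self, rng):
        row = rng.normal(size=12)
        t = make_table(np.column_stack([row, row]), omics="metabolome_nmr")
        amap = agglomerate_features(t, cut=0.0)
        assert len(amap.pooled_ids) == 1

    def test_independent_features_stay_apart_at_07(self, rng):
        # sample r ~ 0 => distance ~ 1 > 0.7
        X = rng.normal(size=(200, 2))
        t = make_table(X, omics="metabolome_nmr")
        amap = agglomerate_features(t, cut=0.7)
        assert len(amap.pooled_ids) == 2

    def test_zero_variance_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 2] = 1.0
        with pytest.raises(ValidationError, match="zero-variance"):
            agglomerate_features(make_table(X, omics="metabolome_nmr"))

    def test_planted_blocks_recovered(self):
        # three 4-bucket molecule blocks plus two unrelated buckets; the
        # unrelated buckets would stay singletons at any low cut, so the
        # no-singleton rule drives the auto cut up to the 0.7 cap, at which
        # the planted blocks are recovered exactly
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            base = rng.normal(size=(100, 3))
            cols, truth = [], []
            for b in range(3):
                for _ in range(4):
                    cols.append(base[:, b] + rng.normal(0, 0.15, size=100))
                    truth.append(b)
            for extra in range(2):
                cols.append(rng.normal(size=100))
                truth.append(3 + extra)
            t = make_table(np.column_stack(cols), omics="metabolome_nmr")
            with pytest.warns(UserWarning, match="cap"):
                amap = agglomerate_features(t, cut="auto", cap=0.7)
            assert amap.cut_height == 0.7
            found = [amap.cluster_of[f] for f in t.feature_ids]
            hits += adjusted_rand_score(truth, found) == 1.0
        assert hits >= 19

    def test_map_roundtrips_through_json(self, tmp_path, rng):
        t = make_table(rng.normal(size=(30, 6)), omics="metabolome_nmr")
        amap = agglomerate_features(t, cut=0.9)
        path = tmp_path / "map.json"
        amap.to_json(path)
        back = AgglomerationMap.from_json(path)
        assert back.members == amap.members
        assert back.cut_height == amap.cut_height


class TestPooling:
    def test_singleton_cluster_identity(self, rng):
        t = make_table(rng.normal(size=(8, 1)), ["b1"], omics="metabolome_nmr")
        amap = AgglomerationMap({"b1": 1}, 0.0, {1: "agg_1"})
        pooled = pool_agglomerates(t, amap)
        assert np.allclose(pooled.values["agg_1"], t.values["b1"])
        assert pooled.feature_type["agg_1"] == "metabolome_nmr"
        assert pooled.units["agg_1"] == "pooled_intensity"

    def test_median_of_three(self):
        t = make_table(np.array([[1.0, 2.0, 9.0]]), ["a", "b", "c"],
                       omics="metabolome_nmr")
        amap = AgglomerationMap({"a": 1, "b": 1, "c": 1}, 0.5, {1: "agg_1"})
        assert pool_agglomerates(t, amap).values.iloc[0, 0] == 2.0

    def test_matches_bruteforce_sorted_middle(self, rng):
        X = rng.normal(size=(15, 9))
        t = make_table(X, omics="metabolome_nmr")
        labels = rng.integers(1, 4, size=9)
        while len(set(labels)) < 3:
            labels = rng.integers(1, 4, size=9)
        amap = AgglomerationMap(dict(zip(t.feature_ids, labels.tolist())), 0.5,
                                {c: f"agg_{c}" for c in sorted(set(labels))})
        pooled = pool_agglomerates(t, amap)
        for c in sorted(set(labels)):
            members = [j for j, lab in enumerate(labels) if lab == c]
            for i in range(15):
                vals = sorted(X[i, j] for j in members)
                k = len(vals)
                mid = vals[k // 2] if k % 2 else (vals[k // 2 - 1] + vals[k // 2]) / 2
                assert pooled.values.loc[t.sample_ids[i], f"agg_{c}"] == pytest.approx(mid)

    def test_feature_missing_from_map_rejected(self, rng):
        t = make_table(rng.normal(size=(5, 2)), ["a", "b"], omics="metabolome_nmr")
        amap = AgglomerationMap({"a": 1}, 0.0, {1: "agg_1"})
        with pytest.raises(ValidationError, match="missing"):
            pool_agglomerates(t, amap)


class TestReductionGuarantee:
    def test_pooled_features_mutually_distant(self):
        """After agglomeration at the 0.7 cut, pooled spectral features do
        not correlate above the cut's implied bound (r = 0.3) in >= 90% of
        seeds, so no giant spectral component can form downstream."""
        ok = 0
        seeds = 10
        for seed in range(seeds):
            rng = np.random.default_rng(seed)
            base = rng.normal(size=(150, 4))
            cols = [base[:, b] + rng.normal(0, 0.2, size=150)
                    for b in range(4) for _ in range(3)]
            t = make_table(np.column_stack(cols), omics="metabolome_nmr")
            amap = agglomerate_features(t, cut="auto", cap=0.7)
            pooled = pool_agglomerates(t, amap)
            r = np.corrcoef(pooled.values.to_numpy(), rowvar=False)
            off = r[np.triu_indices_from(r, k=1)]
            ok += np.all(off <= 1 - amap.cut_height + 0.05)
        assert ok >= 0.9 * seeds
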