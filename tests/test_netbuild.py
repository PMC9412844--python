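import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kcmnet.errors import ValidationError
from kcmnet.netbuild import (
    ThresholdPolicy,
    apply_group_policy,
    build_network,
    min_significant_threshold,
    soft_threshold_power,
    spearman_matrix,
    spearman_pvalue_t,
)
from kcmnet.synthdata import SimConfig, simulate_cohort
from kcmnet.tables_io import merge_tables

from conftest import make_table


def brute_force_spearman(X):
    """Rank columns (average ranks for ties), then Pearson."""
    ranks = np.column_stack([stats.rankdata(X[:, j]) for j in range(X.shape[1])])
    return np.corrcoef(ranks, rowvar=False)


class TestSpearmanMatrix:
    def test_monotone_cubic_gives_unit_correlation(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        t = make_table(np.column_stack([x, x ** 3]))
        rho = spearman_matrix(t)
        assert rho.iloc[0, 1] == pytest.approx(1.0)

    def test_reversed_order_gives_minus_one(self):
        x = np.arange(6.0)
        t = make_table(np.column_stack([x, x[::-1]]))
        assert spearman_matrix(t).iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_bruteforce(self, rng):
        X = rng.normal(size=(30, 10))
        rho = spearman_matrix(make_table(X)).to_numpy()
        assert np.allclose(rho, brute_force_spearman(X), atol=1e-12)

    def test_zero_variance_feature_correlations_zeroed(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            rho = spearman_matrix(make_table(X))
        assert (rho.iloc[1, [0, 2]] == 0).all()
        assert rho.iloc[1, 1] == 1.0

    def test_missing_values_hard_error(self, rng):
        X = rng.normal(size=(5, 3))
        X[2, 1] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            spearman_matrix(make_table(X))

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValidationError, match="3 samples"):
            spearman_matrix(make_table(rng.normal(size=(2, 4))))


class TestMinSignificantThreshold:
    def test_strictly_decreasing_in_n(self):
        values = [min_significant_threshold(n, 0.05) for n in range(5, 201)]
        assert all(a > b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("n", [5, 10, 30, 90, 200])
    def test_matches_grid_scan_oracle(self, n):
        # brute-force: smallest rho on a 1e-6 grid with p < alpha
        alpha = 0.05
        grid = np.arange(1e-6, 1.0, 1e-6)
        tstat = grid * np.sqrt((n - 2) / (1 - grid ** 2))
        p = 2 * stats.t.sf(tstat, df=n - 2)
        oracle = grid[np.argmax(p < alpha)]
        assert min_significant_threshold(n, alpha) == pytest.approx(oracle, abs=2e-6)

    @pytest.mark.parametrize("n", [5, 30, 90])
    def test_brackets_alpha(self, n):
        rho = min_significant_threshold(n, 0.05)
        assert spearman_pvalue_t(rho + 1e-4, n) < 0.05
        assert spearman_pvalue_t(rho - 1e-4, n) >= 0.05

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            min_significant_threshold(3, 0.05)

    def test_exact_permutation_null_small_n(self):
        # n=5: the exact two-sided null of Spearman rho is discrete; the
        # returned value must be achievable and have tail mass < alpha
        from kcmnet.netbuild import spearman_null_exact
        t = min_significant_threshold(5, 0.05, method="exact")
        null = np.abs(spearman_null_exact(5))
        assert np.sum(null >= t - 1e-12) / null.size < 0.05


class TestBuildNetwork:
    def _corr(self, mat, ids=None):
        ids = ids or [f"f{i}" for i in range(len(mat))]
        return pd.DataFrame(np.asarray(mat, dtype=float), index=ids, columns=ids)

    def test_triangle_from_uniform_correlations(self):
        m = np.full((3, 3), 0.8)
        np.fill_diagonal(m, 1.0)
        net = build_network(self._corr(m), 0.7, {f"f{i}": "microbiome" for i in range(3)})
        assert net.n_edges == 3

    def test_threshold_one_gives_no_edges(self):
        m = np.ones((4, 4))
        with pytest.warns(UserWarning):
            net = build_network(self._corr(m), 1.0, {})
        assert net.n_edges == 0 and net.n_nodes == 4

    def test_edge_count_matches_double_loop(self, rng):
        X = rng.normal(size=(25, 20))
        rho = spearman_matrix(make_table(X))
        net = build_network(rho, 0.5, {}, mode="signed")
        expected = 0
        m = rho.to_numpy()
        for i in range(20):
            for j in range(i + 1, 20):
                if m[i, j] > 0.5:
                    expected += 1
        assert net.n_edges == expected

    def test_strict_inequality_at_threshold(self):
        m = np.array([[1.0, 0.5], [0.5, 1.0]])
        net = build_network(self._corr(m), 0.5, {})
        assert net.n_edges == 0

    def test_absolute_mode_links_anticorrelations(self):
        m = np.array([[1.0, -0.9], [-0.9, 1.0]])
        assert build_network(self._corr(m), 0.7, {}, mode="signed").n_edges == 0
        assert build_network(self._corr(m), 0.7, {}, mode="absolute").n_edges == 1

    def test_monotonic_in_threshold(self, rng):
        X = rng.normal(size=(15, 12))
        rho = spearman_matrix(make_table(X))
        e_soft = build_network(rho, 0.2, {}).edges
        e_hard = build_network(rho, 0.6, {}).edges
        assert e_hard <= e_soft

    def test_invariant_to_strictly_increasing_transforms(self, rng):
        X = rng.lognormal(size=(20, 8))
        base = build_network(spearman_matrix(make_table(X)), 0.3, {}).edges
        Y = X.copy()
        Y[:, 0] = np.exp(Y[:, 0])
        Y[:, 3] = Y[:, 3] ** 3
        Y[:, 5] = 2 * Y[:, 5] + 7
        trans = build_network(spearman_matrix(make_table(Y)), 0.3, {}).edges
        assert base == trans

    def test_adjacency_matrix_binary_symmetric_zero_diagonal(self, rng):
        X = rng.normal(size=(20, 9))
        net = build_network(spearman_matrix(make_table(X)), 0.3, {})
        a = net.adjacency_matrix(order=net.nodes)
        assert set(np.unique(a)) <= {0, 1}
        assert (a == a.T).all()
        assert np.trace(a) == 0
        assert a.sum() == 2 * net.n_edges

    def test_invariant_to_sample_order(self, rng):
        X = rng.normal(size=(18, 6))
        t = make_table(X)
        perm = rng.permutation(t.sample_ids)
        shuffled = t.subset_samples(list(perm))
        assert build_network(spearman_matrix(t), 0.3, {}).edges == \
            build_network(spearman_matrix(shuffled), 0.3, {}).edges


class TestGroupPolicy:
    def _cohort(self, n_per_cell, seed=0):
        cfg = SimConfig(seed=seed, n_subjects_per_cell=n_per_cell, n_taxa=10,
                        n_vocs=6, n_buckets=8, n_rare_taxa=1, n_rare_vocs=1,
                        molecule_blocks=[[0, 1], [2, 3]], consortia=[])
        return simulate_cohort(cfg)

    def test_t0_by_sex_te_by_sex_and_arm(self):
        t0, te, design, _ = self._cohort(20)  # 40 F + 40 M subjects
        nets0 = apply_group_policy(t0, design)
        assert sorted(nets0) == ["T0_F", "T0_M"]
        assert all(n.provenance.t == 0.5 for n in nets0.values())
        assert all(n.provenance.n_samples == 40 for n in nets0.values())
        netse = apply_group_policy(te, design)
        assert sorted(netse) == ["Te_F_A", "Te_F_P", "Te_M_A", "Te_M_P"]
        assert all(n.provenance.t == 0.7 for n in netse.values())
        assert all(n.provenance.n_samples == 20 for n in netse.values())

    def test_significance_policy_records_consistent_threshold(self):
        t0, te, design, _ = self._cohort(10)
        pol = {"Te": ThresholdPolicy(kind="significance", alpha=0.05)}
        nets = apply_group_policy(te, design, policies=pol)
        for net in nets.values():
            assert net.provenance.t == pytest.approx(
                min_significant_threshold(net.provenance.n_samples, 0.05))
            assert net.provenance.policy == "significance"

    def test_single_arm_at_te_warns(self):
        t0, te, design, _ = self._cohort(10)
        arm_a = [s for s in te.sample_ids if design.loc[s, "arm"] == "A"]
        with pytest.warns(UserWarning, match="one intervention arm"):
            nets = apply_group_policy(te.subset_samples(arm_a), design)
        assert sorted(nets) == ["Te_F_A", "Te_M_A"]

    def test_tiny_group_rejected(self):
        t0, te, design, _ = self._cohort(1)
        with pytest.raises(ValidationError, match="at least 4"):
            apply_group_policy(te, design)


class TestSoftThreshold:
    def _scale_free_corr(self, rng, n=60):
        # hub-and-spoke weights whose connectivity follows a power law
        deg = np.round(((np.arange(1, n + 1)) ** -1.2) * 50).astype(int) + 1
        g = np.zeros((n, n))
        for i in range(n):
            targets = rng.choice([j for j in range(n) if j != i],
                                 size=min(deg[i], n - 1), replace=False)
            g[i, targets] = 0.9
        g = np.maximum(g, g.T)
        np.fill_diagonal(g, 1.0)
        ids = [f"f{i}" for i in range(n)]
        return pd.DataFrame(g, index=ids, columns=ids)

    def test_powerlaw_connectivity_fits_at_beta_one(self, rng):
        corr = self._scale_free_corr(rng)
        res = soft_threshold_power(corr, powers=[1], rsq_target=0.0)
        assert res.fit_table.loc[0, "rsq"] >= 0.8

    def test_connectivity_never_increases_with_beta(self, rng):
        X = rng.normal(size=(20, 15))
        corr = spearman_matrix(make_table(X))
        res = soft_threshold_power(corr, powers=range(1, 8), rsq_target=2.0)
        ks = res.fit_table["mean_k"].to_numpy()
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_single_power_grid_returns_it(self, rng):
        corr = spearman_matrix(make_table(rng.normal(size=(12, 8))))
        assert soft_threshold_power(corr, powers=[6]).power == 6

    def test_zero_offdiagonal_rejected(self):
        ids = ["a", "b"]
        corr = pd.DataFrame(np.eye(2), index=ids, columns=ids)
        with pytest.raises(ValidationError):
            soft_threshold_power(corr)
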