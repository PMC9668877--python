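"""Network construction, soft-threshold selection, TOM, clustering, MEs."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from methnet import network as net
from methnet.containers import MethylationMatrix, ValidationError


def residual_matrix(values, probes=None):
    arr = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i:08d}" for i in range(arr.shape[0])]
    samples = [f"S{j}" for j in range(arr.shape[1])]
    return MethylationMatrix(
        pd.DataFrame(arr, index=probes, columns=samples), scale="residual"
    )


def planted_blocks(rng, n_modules=3, size=15, n_background=0, n_samples=97, noise_sd=1 / 3):
    """Factor-model residuals with known block structure."""
    rows, labels = [], []
    for k in range(1, n_modules + 1):
        f = rng.standard_normal(n_samples)
        lam = rng.uniform(0.7, 1.0, size=size) * rng.choice([-1, 1], size=size)
        rows.append(np.outer(lam, f) + rng.normal(0, noise_sd, (size, n_samples)))
        labels += [k] * size
    if n_background:
        rows.append(rng.standard_normal((n_background, n_samples)))
        labels += [0] * n_background
    return residual_matrix(np.vstack(rows)), np.array(labels)


class TestAdjacency:
    def test_perfect_correlation_gives_unit_adjacency(self, rng):
        base = rng.standard_normal(10)
        mat = residual_matrix(np.vstack([base, 2 * base + 1, -base]))
        for power in (1, 4, 9):
            a = net.adjacency(mat, power=power).to_numpy()
            off = a[np.triu_indices_from(a, k=1)]
            assert np.allclose(off, 1.0, atol=1e-10)

    def test_power_transform_of_known_correlation(self):
        # two probes engineered to correlate exactly 0.5
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 0.0, 0.0, -1.0])
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(np.sqrt(0.5))
        a = net.adjacency(residual_matrix(np.vstack([x, y])), power=2).to_numpy()
        assert a[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_matches_elementwise_oracle(self, rng):
        mat = residual_matrix(rng.standard_normal((5, 30)))
        power = 6
        a = net.adjacency(mat, power=power).to_numpy()
        X = mat.values.to_numpy()
        for i in range(5):
            for j in range(5):
                expect = 0.0 if i == j else abs(np.corrcoef(X[i], X[j])[0, 1]) ** power
                assert a[i, j] == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_probe_named(self, rng):
        vals = rng.standard_normal((3, 10))
        vals[1] = 0.0
        with pytest.raises(ValidationError, match="cg00000001"):
            net.adjacency(residual_matrix(vals))


class TestScaleFreeFit:
    def adjacency_with_connectivities(self, k_target):
        """Rank-1 adjacency whose row sums approximate the target ks."""
        u = np.sqrt(np.asarray(k_target) / np.sqrt(np.sum(k_target)))
        A = np.outer(u, u)
        np.fill_diagonal(A, 0.0)
        A = np.clip(A, 0.0, 1.0)
        ids = [f"cg{i:08d}" for i in range(len(u))]
        return pd.DataFrame(A, index=ids, columns=ids)

    def test_power_law_connectivities_fit_well(self, rng):
        # p(k) ~ k^-2 discretized over a decade
        k = (rng.pareto(2.0, size=2000) + 1.0) * 0.05
        r2, adj_r2, _ = net.scale_free_fit(self.adjacency_with_connectivities(k))
        assert r2 > 0.95
        assert adj_r2 > 0.95

    def test_identical_connectivities_zero_with_warning(self):
        A = np.full((30, 30), 0.5)
        np.fill_diagonal(A, 0.0)
        ids = [f"cg{i:08d}" for i in range(30)]
        with pytest.warns(UserWarning, match="identical"):
            r2, adj_r2, mean_k = net.scale_free_fit(pd.DataFrame(A, index=ids, columns=ids))
        assert r2 == 0.0 and adj_r2 == 0.0
        assert mean_k == pytest.approx(29 * 0.5)

    def test_positive_slope_truncated_to_zero(self, rng):
        # frequency increasing with k (anti-scale-free): more mass at high k
        k = 5.0 - (rng.pareto(2.0, size=2000) + 1.0) * 0.05
        k = k[k > 0]
        r2, adj_r2, _ = net.scale_free_fit(self.adjacency_with_connectivities(k))
        assert r2 == 0.0 and adj_r2 == 0.0


class TestPickSoftThreshold:
    def test_vacuous_threshold_returns_lowest_power(self, rng):
        mat, _ = planted_blocks(rng, n_modules=2, n_background=20)
        scan = net.pick_soft_threshold(mat, powers=(2, 3, 4), r2_min=0.0)
        assert scan.chosen_power == 2
        assert scan.passed

    def test_choice_consistent_with_scan_table(self, rng):
        mat, _ = planted_blocks(rng, n_modules=3, size=20, n_background=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scan = net.pick_soft_threshold(mat, powers=tuple(range(1, 13)), r2_min=0.5)
        crit = scan.table["adjusted_r2"]
        passing = scan.table.loc[crit > 0.5, "power"]
        if scan.passed:
            assert scan.chosen_power == passing.iloc[0]
        else:
            assert scan.chosen_power == scan.table.loc[crit.idxmax(), "power"]

    def test_no_pass_falls_back_to_argmax_with_warning(self, rng):
        mat = residual_matrix(rng.standard_normal((30, 20)))
        with pytest.warns(UserWarning, match="argmax"):
            scan = net.pick_soft_threshold(mat, powers=(1, 2), r2_min=0.999)
        assert not scan.passed
        assert scan.chosen_power in (1, 2)

    def test_unsorted_powers_rejected(self, rng):
        mat, _ = planted_blocks(rng, n_modules=1)
        with pytest.raises(ValidationError):
            net.pick_soft_threshold(mat, powers=(5, 2))


class TestTOM:
    def frame(self, A):
        ids = [f"cg{i:08d}" for i in range(A.shape[0])]
        return pd.DataFrame(A, index=ids, columns=ids)

    def test_empty_network_maximal_dissimilarity(self):
        d = net.tom_dissimilarity(self.frame(np.zeros((4, 4)))).to_numpy()
        off = d[np.triu_indices_from(d, k=1)]
        assert np.allclose(off, 1.0)
        assert np.allclose(np.diag(d), 0.0)

    def test_matches_triple_sum_oracle(self, rng):
        A = rng.uniform(0, 0.9, size=(4, 4))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        d = net.tom_dissimilarity(self.frame(A)).to_numpy()
        k = A.sum(axis=1)
        for i in range(4):
            for j in range(4):
                if i == j:
                    assert d[i, j] == 0.0
                    continue
                l_ij = sum(A[i, u] * A[u, j] for u in range(4))
                tom = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
                assert d[i, j] == pytest.approx(1 - tom, abs=1e-12)

    def test_unit_triangle_fully_overlapping(self):
        A = 1.0 - np.eye(3)
        d = net.tom_dissimilarity(self.frame(A)).to_numpy()
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_entries_stay_in_unit_interval(self, rng):
        A = rng.uniform(0, 1, size=(30, 30))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        d = net.tom_dissimilarity(self.frame(A)).to_numpy()
        assert d.min() >= 0.0 and d.max() <= 1.0
        assert np.allclose(d, d.T)

    def test_invalid_adjacency_rejected(self):
        with pytest.raises(ValidationError):
            net.tom_dissimilarity(self.frame(np.full((3, 3), 1.5)))


class TestClusterModules:
    def block_dissimilarity(self, sizes, within=0.05, between=0.95):
        n = sum(sizes)
        d = np.full((n, n), between)
        start = 0
        for s in sizes:
            d[start : start + s, start : start + s] = within
            start += s
        np.fill_diagonal(d, 0.0)
        ids = [f"cg{i:08d}" for i in range(n)]
        return pd.DataFrame(d, index=ids, columns=ids)

    def test_three_planted_blocks_recovered_exactly(self):
        d = self.block_dissimilarity([15, 15, 15])
        modules = net.cluster_modules(d, min_size=10, cut_height=0.5)
        truth = np.repeat([1, 2, 3], 15)
        assert adjusted_rand_score(truth, modules.labels) == 1.0
        assert modules.n_modules == 3

    def test_small_cluster_unassigned(self):
        d = self.block_dissimilarity([5, 30])
        modules = net.cluster_modules(d, min_size=10, cut_height=0.5)
        assert (modules.labels.iloc[:5] == 0).all()
        assert (modules.labels.iloc[5:] > 0).all()

    def test_all_distant_gives_zero_modules(self):
        n = 20
        d = pd.DataFrame(
            1.0 - np.eye(n),
            index=[f"cg{i:08d}" for i in range(n)],
            columns=[f"cg{i:08d}" for i in range(n)],
        )
        modules = net.cluster_modules(d, min_size=5, cut_height=0.5)
        assert modules.n_modules == 0

    def test_min_size_below_two_rejected(self):
        with pytest.raises(ValidationError):
            net.cluster_modules(self.block_dissimilarity([10]), min_size=1)

    def test_labels_ordered_by_decreasing_size(self):
        d = self.block_dissimilarity([12, 25, 18])
        modules = net.cluster_modules(d, min_size=10, cut_height=0.5)
        sizes = modules.labels.value_counts()
        assert sizes[1] == 25 and sizes[2] == 18 and sizes[3] == 12

    def test_probe_order_invariance(self, rng):
        mat, truth = planted_blocks(rng, n_modules=3, size=15, n_background=30)
        perm = rng.permutation(mat.n_probes)
        mat_perm = MethylationMatrix(mat.values.iloc[perm], scale="residual")
        adj1 = net.adjacency(mat, power=6)
        adj2 = net.adjacency(mat_perm, power=6)
        m1 = net.cluster_modules(net.tom_dissimilarity(adj1))
        m2 = net.cluster_modules(net.tom_dissimilarity(adj2))
        aligned = m2.labels.loc[m1.labels.index]
        assert adjusted_rand_score(m1.labels, aligned) == 1.0


class TestModuleEigengenes:
    def test_identical_probes_reproduce_profile(self, rng):
        profile = rng.standard_normal(40)
        mat = residual_matrix(np.tile(profile, (5, 1)))
        labels = pd.Series(1, index=mat.probe_ids)
        ms = net.module_eigengenes(mat, labels)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert ms.variance_explained["ME1"] == pytest.approx(1.0)
        assert np.allclose(ms.eigengenes["ME1"], z, atol=1e-8)

    def test_anticorrelated_pair_sign_convention(self, rng):
        x = rng.standard_normal(30)
        mat = residual_matrix(np.vstack([x, -2 * x + 3]))
        labels = pd.Series(1, index=mat.probe_ids)
        ms = net.module_eigengenes(mat, labels)
        assert ms.variance_explained["ME1"] == pytest.approx(1.0)
        # sign fixed by nonnegative correlation with the mean profile
        mean_profile = ((x - x.mean()) / x.std(ddof=1) + ((-2 * x + 3) - (-2 * x + 3).mean()) / (-2 * x + 3).std(ddof=1)) / 2
        r = np.corrcoef(ms.eigengenes["ME1"], mean_profile)[0, 1]
        assert r >= 0 or np.isnan(r)

    def test_matches_svd_oracle(self, rng):
        mat = residual_matrix(rng.standard_normal((12, 50)))
        labels = pd.Series(1, index=mat.probe_ids)
        ms = net.module_eigengenes(mat, labels)
        X = mat.values.to_numpy()
        Xz = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
        U, S, Vt = np.linalg.svd(Xz.T, full_matrices=False)
        oracle = U[:, 0] * S[0]
        if np.corrcoef(oracle, Xz.mean(axis=0))[0, 1] < 0:
            oracle = -oracle
        oracle = oracle / oracle.std(ddof=1)
        assert np.allclose(ms.eigengenes["ME1"], oracle, atol=1e-8)
        assert ms.variance_explained["ME1"] == pytest.approx(S[0] ** 2 / np.sum(S**2))

    def test_unit_variance_and_bounds(self, rng):
        mat, truth = planted_blocks(rng, n_modules=3)
        labels = pd.Series(truth, index=mat.probe_ids)
        ms = net.module_eigengenes(mat, labels)
        assert np.allclose(ms.eigengenes.std(ddof=1), 1.0, atol=1e-8)
        assert ((ms.variance_explained > 0) & (ms.variance_explained <= 1)).all()

    def test_constant_probe_rejected(self):
        vals = np.vstack([np.ones(20), np.random.default_rng(0).standard_normal(20)])
        mat = residual_matrix(vals)
        with pytest.raises(ValidationError, match="constant"):
            net.module_eigengenes(mat, pd.Series(1, index=mat.probe_ids))


class TestPipelineRecovery:
    def test_planted_modules_recovered_through_full_chain(self, rng):
        mat, truth = planted_blocks(rng, n_modules=4, size=15, n_background=300)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scan, modules = net.build_network_modules(mat, power=6)
        assert adjusted_rand_score(truth, modules.labels) >= 0.9
        assert modules.n_modules == 4

    def test_color_aliases(self):
        assert net.module_color(0) == "grey"
        assert net.module_color(1) != net.module_color(2)
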