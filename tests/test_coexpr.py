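"""Network construction contracts: adjacency, scale-free fit, TOM, tree cut,
eigengenes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from regionrank import coexpr


def _frame(x):
    return pd.DataFrame(x, index=[f"g{i}" for i in range(np.asarray(x).shape[0])])


class TestAdjacency:
    def test_perfect_correlation_gives_one_any_beta(self):
        x = np.vstack([np.arange(6.0), 2 * np.arange(6.0) + 1])
        for beta in (1, 6, 12):
            a = coexpr.soft_threshold_adjacency(_frame(x), beta=beta)
            assert a.iloc[0, 1] == pytest.approx(1.0)

    def test_half_correlation_beta_six(self):
        # |0.5|^6 = 0.015625, checked through a pair constructed to cor 0.5
        rng = np.random.default_rng(0)
        n = 100000
        z = rng.standard_normal(n)
        x = np.vstack([z, 0.5 * z + np.sqrt(0.75) * rng.standard_normal(n)])
        a = coexpr.soft_threshold_adjacency(_frame(x), beta=6)
        assert a.iloc[0, 1] == pytest.approx(0.015625, rel=0.05)
        # and exactly on a hand value
        assert 0.5**6 == 0.015625

    def test_beta_one_is_absolute_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 30))
        a = coexpr.soft_threshold_adjacency(_frame(x), beta=1)
        np.testing.assert_allclose(
            a.to_numpy() - np.eye(10), np.abs(np.corrcoef(x)) - np.eye(10), atol=1e-12
        )

    def test_constant_probeset_warns_and_zeroes(self):
        x = np.vstack([np.ones(8), np.random.default_rng(2).normal(size=8)])
        with pytest.warns(UserWarning, match="constant"):
            a = coexpr.soft_threshold_adjacency(_frame(x))
        assert a.iloc[0, 1] == 0.0
        assert a.iloc[0, 0] == 1.0


class TestScaleFreeFit:
    def test_planted_power_law_scores_high(self):
        # construct adjacency whose connectivities follow a discretized power law
        rng = np.random.default_rng(3)
        n = 400
        k_target = np.round(5 * (1 - rng.random(n)) ** (-1 / 1.5)).clip(1, 200)
        a = np.zeros((n, n))
        # star-like attachment: node i gets k_target[i] unit edges (approximately)
        order = np.argsort(-k_target)
        stubs = []
        for i in order:
            need = int(k_target[i])
            for j in rng.choice(n, size=need, replace=False):
                if j != i:
                    a[i, j] = a[j, i] = 1.0
        np.fill_diagonal(a, 1.0)
        r2 = coexpr.scale_free_fit_index(a)
        assert r2 >= 0.95

    def test_r_squared_in_unit_interval(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 20))
        a = coexpr.soft_threshold_adjacency(_frame(x))
        assert 0.0 <= coexpr.scale_free_fit_index(a) <= 1.0

    def test_matches_two_covariate_least_squares_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(50, 25))
        a = coexpr.soft_threshold_adjacency(_frame(x))
        arr = a.to_numpy()
        k = arr.sum(axis=1) - 1.0
        edges = np.linspace(k.min(), k.max(), 11)
        idx = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
        km, fr = [], []
        for b in range(10):
            mask = idx == b
            if mask.any():
                km.append(k[mask].mean())
                fr.append(mask.mean())
        km, fr = np.array(km), np.array(fr)
        ok = (fr > 0) & (km > 0)
        y = np.log10(fr[ok])
        X = np.column_stack([np.ones(ok.sum()), np.log10(km[ok]), km[ok]])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r2_oracle = 1 - ((y - X @ beta) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert coexpr.scale_free_fit_index(a) == pytest.approx(r2_oracle, abs=1e-10)

    def test_degenerate_equal_connectivities_error(self):
        a = np.ones((12, 12))
        with pytest.raises(ValueError, match="equal"):
            coexpr.scale_free_fit_index(a)


def oracle_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop reference implementation of the topological overlap."""
    n = a.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return out


class TestTopologicalOverlap:
    def test_identical_rows_full_overlap(self):
        a = np.ones((4, 4))
        tom = coexpr.topological_overlap(pd.DataFrame(a))
        assert tom.iloc[0, 1] == pytest.approx(1.0)

    def test_disconnected_pair_zero(self):
        a = np.eye(4)
        tom = coexpr.topological_overlap(pd.DataFrame(a))
        assert tom.iloc[0, 1] == 0.0

    def test_matches_triple_loop_oracle_on_random_matrices(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = 5
            a = rng.random((n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            tom = coexpr.topological_overlap(pd.DataFrame(a)).to_numpy()
            np.testing.assert_allclose(tom, oracle_tom(a), atol=1e-12)

    def test_zero_adjacency_iff_zero_tom_without_shared_neighbors(self):
        a = np.eye(6)
        a[0, 1] = a[1, 0] = 0.9  # isolated pair, no shared neighbors
        tom = coexpr.topological_overlap(pd.DataFrame(a)).to_numpy()
        assert tom[0, 1] > 0 and tom[2, 3] == 0.0


class TestClusterModules:
    def test_two_planted_blocks_recovered_exactly(self, two_block_matrix):
        m, truth = two_block_matrix
        tom = coexpr.topological_overlap(coexpr.soft_threshold_adjacency(m))
        asg = coexpr.cluster_modules(tom, min_module_size=30)
        labels = asg.labels.tolist()
        assert len(set(labels) - {"grey"}) == 2
        assert adjusted_rand_score(truth, labels) >= 0.95

    def test_pure_noise_goes_grey(self):
        rng = np.random.default_rng(7)
        m = _frame(rng.normal(size=(200, 30)))
        tom = coexpr.topological_overlap(coexpr.soft_threshold_adjacency(m))
        asg = coexpr.cluster_modules(tom, min_module_size=30)
        assert (asg.labels == "grey").mean() > 0.5

    def test_module_size_floor_holds(self, two_block_matrix):
        m, _ = two_block_matrix
        tom = coexpr.topological_overlap(coexpr.soft_threshold_adjacency(m))
        for size in (10, 30, 60):
            asg = coexpr.cluster_modules(tom, min_module_size=size)
            for mod, genes in asg.module_sets().items():
                assert len(genes) >= size

    def test_invariant_to_input_order(self, two_block_matrix):
        m, _ = two_block_matrix
        tom = coexpr.topological_overlap(coexpr.soft_threshold_adjacency(m))
        asg1 = coexpr.cluster_modules(tom, 30)
        perm = np.random.default_rng(8).permutation(len(m))
        tom2 = tom.iloc[perm, perm]
        asg2 = coexpr.cluster_modules(tom2, 30)
        sets1 = {frozenset(v) for v in asg1.module_sets().values()}
        sets2 = {frozenset(v) for v in asg2.module_sets().values()}
        assert sets1 == sets2

    def test_fewer_genes_than_floor_warns_all_grey(self):
        rng = np.random.default_rng(9)
        m = _frame(rng.normal(size=(5, 10)))
        tom = coexpr.topological_overlap(coexpr.soft_threshold_adjacency(m))
        with pytest.warns(UserWarning):
            asg = coexpr.cluster_modules(tom, min_module_size=30)
        assert (asg.labels == "grey").all()


class TestEigengene:
    def test_identical_genes_give_common_profile_full_variance(self):
        rng = np.random.default_rng(10)
        profile = rng.normal(size=12)
        m = _frame(np.tile(profile, (5, 1)) + 0.0)
        asg = coexpr.ModuleAssignment(pd.Series("turquoise", index=m.index))
        eg, ve = coexpr.module_eigengene(m, asg)
        assert ve["turquoise"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        r = np.corrcoef(eg.loc["turquoise"], z)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_matches_svd_oracle(self, two_block_matrix):
        m, _ = two_block_matrix
        asg = coexpr.ModuleAssignment(
            pd.Series(["turquoise"] * 50 + ["blue"] * 50, index=m.index)
        )
        eg, ve = coexpr.module_eigengene(m, asg)
        for mod, genes in asg.module_sets().items():
            x = m.loc[genes].to_numpy()
            z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
            _, s, vt = np.linalg.svd(z, full_matrices=False)
            v = vt[0]
            dot = abs(np.dot(eg.loc[mod].to_numpy(), v))
            assert dot == pytest.approx(1.0, abs=1e-10)  # same direction up to sign
            assert ve[mod] == pytest.approx(s[0] ** 2 / (s**2).sum(), abs=1e-12)

    def test_sign_orientation_stable_under_global_flip(self):
        rng = np.random.default_rng(11)
        lat = rng.standard_normal(20)
        x = lat[None, :] + 0.3 * rng.standard_normal((8, 20))
        m = _frame(x)
        asg = coexpr.ModuleAssignment(pd.Series("turquoise", index=m.index))
        eg1, _ = coexpr.module_eigengene(m, asg)
        eg2, _ = coexpr.module_eigengene(-m, asg)
        # orientation rule ties the sign to the mean profile, which flips too
        np.testing.assert_allclose(
            eg1.loc["turquoise"].to_numpy(), -eg2.loc["turquoise"].to_numpy(), atol=1e-10
        )

    def test_zero_variance_module_errors(self):
        m = _frame(np.ones((3, 8)))
        asg = coexpr.ModuleAssignment(pd.Series("turquoise", index=m.index))
        with pytest.raises(ValueError, match="zero-variance"):
            coexpr.module_eigengene(m, asg)

    def test_planted_module_eigengene_tracks_latent(self, small_cohort):
        region = small_cohort.regions[0]
        m = small_cohort.expression[region]
        net = coexpr.build_network_modules(m, region=region)
        eg, _ = coexpr.module_eigengene(m, net.assignment)
        lat = small_cohort.truth["latents"][region]
        for mod in eg.index:
            best = max(
                abs(np.corrcoef(eg.loc[mod], lat.loc[t])[0, 1]) for t in lat.index
            )
            assert best >= 0.9
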