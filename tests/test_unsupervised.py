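import numpy as np
import pandas as pd
import pytest

from methbench import (
    MethylationMatrix,
    Phenotype,
    SimulationConfig,
    compare_svd_nmf,
    component_phenotype_r2,
    estimate_n_components,
    nmf_brunet,
    nndsvd_init,
    simulate_beta_matrix,
    svd_decompose,
)
from methbench.datatypes import Decomposition


def _beta_matrix(arr):
    arr = np.asarray(arr, dtype=float)
    ids = [f"cg{i:03d}" for i in range(arr.shape[0])]
    cols = [f"S{i:03d}" for i in range(arr.shape[1])]
    return MethylationMatrix(pd.DataFrame(arr, index=ids, columns=cols), "beta")


class TestSVD:
    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(0)
        m = _beta_matrix(rng.uniform(0.1, 0.9, (12, 6)))
        dec = svd_decompose(m, k=6)
        centered = m.values.to_numpy() - m.values.to_numpy().mean(axis=1, keepdims=True)
        recon = dec.basis.to_numpy() @ dec.scores.to_numpy()
        assert np.max(np.abs(recon - centered)) < 1e-10

    def test_reconstruction_error_decreases_in_k(self):
        rng = np.random.default_rng(1)
        m = _beta_matrix(rng.uniform(0.1, 0.9, (30, 10)))
        centered = m.values.to_numpy() - m.values.to_numpy().mean(axis=1, keepdims=True)
        errs = []
        for k in (1, 3, 5, 8):
            dec = svd_decompose(m, k)
            errs.append(np.linalg.norm(centered - dec.basis.to_numpy() @ dec.scores.to_numpy()))
        assert np.all(np.diff(errs) < 0)

    def test_planted_rank_one_dominates(self):
        rng = np.random.default_rng(2)
        u = rng.uniform(-0.1, 0.1, 40)
        v = rng.normal(0, 1, 15)
        m = _beta_matrix(np.clip(0.5 + np.outer(u, v) + rng.normal(0, 1e-3, (40, 15)), 0.01, 0.99))
        dec = svd_decompose(m, 3)
        assert dec.singular_values[0] > 10 * dec.singular_values[1]

    def test_sample_permutation_permutes_scores(self):
        rng = np.random.default_rng(3)
        m = _beta_matrix(rng.uniform(0.1, 0.9, (20, 8)))
        perm = rng.permutation(8)
        mp = MethylationMatrix(m.values.iloc[:, perm], "beta")
        a = svd_decompose(m, 2).scores.to_numpy()
        b = svd_decompose(mp, 2).scores.to_numpy()
        # identical up to component sign
        for c in range(2):
            assert np.allclose(a[c, perm], b[c], atol=1e-10) or np.allclose(
                a[c, perm], -b[c], atol=1e-10
            )


class TestComponentCountEstimate:
    def test_pure_noise_gives_zero_components(self):
        rng = np.random.default_rng(4)
        hits = 0
        runs = 20
        for i in range(runs):
            m = _beta_matrix(rng.uniform(0.2, 0.8, (150, 25)))
            if estimate_n_components(m, n_permutations=30, seed=i) == 0:
                hits += 1
        assert hits >= runs - 2

    def test_planted_factor_detected(self):
        rng = np.random.default_rng(5)
        u = rng.uniform(-0.15, 0.15, 300)
        v = rng.normal(0, 1, 30)
        m = _beta_matrix(np.clip(0.5 + np.outer(u, v) + rng.normal(0, 0.02, (300, 30)), 0.01, 0.99))
        assert estimate_n_components(m, n_permutations=30, seed=0) >= 1

    def test_zero_quantile_is_permissive_upper_bound(self):
        rng = np.random.default_rng(6)
        m = _beta_matrix(rng.uniform(0.2, 0.8, (80, 15)))
        k0 = estimate_n_components(m, n_permutations=20, quantile=0.0, seed=1)
        k95 = estimate_n_components(m, n_permutations=20, quantile=0.95, seed=1)
        assert k0 >= k95


class TestNNDSVD:
    def test_rank_one_exact(self):
        rng = np.random.default_rng(7)
        u = rng.random(25)
        v = rng.random(10)
        w, h = nndsvd_init(np.outer(u, v), 1)
        assert np.max(np.abs(w @ h - np.outer(u, v))) < 1e-12

    def test_output_nonnegative_and_deterministic(self):
        rng = np.random.default_rng(8)
        V = rng.random((40, 12))
        w1, h1 = nndsvd_init(V, 4)
        w2, h2 = nndsvd_init(V, 4)
        assert np.all(w1 >= 0) and np.all(h1 >= 0)
        assert np.array_equal(w1, w2) and np.array_equal(h1, h2)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            nndsvd_init(np.array([[1.0, -0.1], [0.2, 0.3]]), 1)


class TestBrunetNMF:
    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(9)
        for i in range(5):
            V = rng.random((30, 12))
            dec = nmf_brunet(V, 3)
            assert np.all(np.diff(dec.objective_trace) <= 1e-8)

    def test_planted_factorization_recovered(self):
        rng = np.random.default_rng(10)
        W = rng.random((40, 2))
        H = rng.random((2, 15))
        V = W @ H
        dec = nmf_brunet(V, 2, max_iter=5000, tol=1e-12)
        assert dec.objective_trace[-1] < 1e-6 * np.abs(V).sum()

    def test_rank_one_matches_svd_reconstruction(self):
        rng = np.random.default_rng(11)
        V = np.outer(rng.random(20) + 0.1, rng.random(8) + 0.1)
        dec = nmf_brunet(V, 1, max_iter=3000, tol=1e-12)
        recon = dec.basis.to_numpy() @ dec.scores.to_numpy()
        u, s, vt = np.linalg.svd(V)
        svd_recon = s[0] * np.outer(u[:, 0], vt[0])
        assert np.max(np.abs(recon - svd_recon)) / np.max(V) < 1e-4

    def test_matches_sklearn_kl_objective(self):
        """Independent cross-check: our multiplicative updates reach a KL
        divergence comparable to sklearn's 'mu' solver from the same class
        of initialisations."""
        from sklearn.decomposition import NMF as SkNMF

        rng = np.random.default_rng(12)
        V = rng.random((60, 20)) + 0.05
        ours = nmf_brunet(V, 3, max_iter=2000, tol=1e-10)
        sk = SkNMF(
            n_components=3, solver="mu", beta_loss="kullback-leibler",
            init="nndsvda", max_iter=2000, tol=1e-10, random_state=0,
        )
        Ws = sk.fit_transform(V)
        from methbench.unsupervised import _kl_divergence

        sk_obj = _kl_divergence(V, Ws @ sk.components_)
        assert ours.objective_trace[-1] <= sk_obj * 1.05

    def test_m_valued_input_rejected(self):
        rng = np.random.default_rng(13)
        m = _beta_matrix(rng.uniform(0.2, 0.8, (10, 5)))
        from methbench import convert_measure

        with pytest.raises(ValueError):
            nmf_brunet(convert_measure(m, "M"), 2)

    def test_bit_reproducible(self):
        rng = np.random.default_rng(14)
        V = rng.random((25, 10))
        a = nmf_brunet(V, 2)
        b = nmf_brunet(V, 2)
        assert np.array_equal(a.basis.to_numpy(), b.basis.to_numpy())
        assert np.array_equal(a.scores.to_numpy(), b.scores.to_numpy())


class TestComponentR2:
    def _decomp(self, scores):
        scores = np.asarray(scores, dtype=float)
        cols = [f"S{i}" for i in range(scores.shape[1])]
        return Decomposition(
            "SVD",
            pd.DataFrame(np.zeros((3, scores.shape[0]))).T,
            pd.DataFrame(scores, columns=cols),
            scores.shape[0],
        )

    def _pheno(self, values):
        return Phenotype(
            pd.Series(values, index=[f"S{i}" for i in range(len(values))]), "continuous"
        )

    def test_exact_match_gives_one(self):
        y = [1.0, 2, 3, 4, 5]
        assoc = component_phenotype_r2(self._decomp([y]), self._pheno(y))
        assert assoc.r2[0] == pytest.approx(1.0)

    def test_orthogonal_score_gives_zero(self):
        y = [1.0, 2, 3, 4, 5]
        s = [1.0, -1, 0, -1, 1]  # orthogonal to centered y
        assoc = component_phenotype_r2(self._decomp([s]), self._pheno(y))
        assert assoc.r2[0] == pytest.approx(0.0, abs=1e-10)

    def test_average_of_best_two(self):
        rng = np.random.default_rng(15)
        y = np.array([10.0, 20, 30, 40, 50, 60])
        noise = rng.normal(0, 1, 6)

        def mix(r2):
            yc = (y - y.mean()) / y.std()
            nc = noise - noise.mean()
            nc = nc - (nc @ yc) / (yc @ yc) * yc
            nc /= np.linalg.norm(nc)
            return np.sqrt(r2) * yc / np.linalg.norm(yc) + np.sqrt(1 - r2) * nc

        scores = np.vstack([mix(0.9), mix(0.5), mix(0.1)])
        assoc = component_phenotype_r2(self._decomp(scores), self._pheno(y))
        assert np.allclose(np.sort(assoc.r2)[::-1], [0.9, 0.5, 0.1], atol=1e-8)
        assert assoc.best_two_mean == pytest.approx(0.7, abs=1e-8)

    def test_affine_transform_invariance(self):
        rng = np.random.default_rng(16)
        y = rng.uniform(25, 90, 12)
        s = rng.normal(0, 1, 12)
        a = component_phenotype_r2(self._decomp([s]), self._pheno(y)).r2[0]
        b = component_phenotype_r2(self._decomp([5 * s - 3]), self._pheno(y)).r2[0]
        assert a == pytest.approx(b)


class TestSVDvsNMF:
    def test_null_simulation_both_weak(self):
        cfg = SimulationConfig(n_features=800, n_true=0, n_per_group=40, seed=51)
        matrix, phenotype, _ = simulate_beta_matrix(cfg)
        res = compare_svd_nmf(matrix, phenotype, n_permutations=15, seed=1)
        assert res["svd_r2"].best_two_mean < 0.1
        assert res["nmf_r2"].best_two_mean < 0.1

    def test_diagnostic_simulation_nmf_at_least_svd(self):
        cfg = SimulationConfig(
            n_features=1500, n_true=400, target_effect_size=2.5, n_per_group=40, seed=53
        )
        matrix, phenotype, _ = simulate_beta_matrix(cfg)
        res = compare_svd_nmf(matrix, phenotype, n_permutations=15, seed=2)
        assert res["nmf_r2"].best_two_mean >= res["svd_r2"].best_two_mean

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_features=400, n_true=100, target_effect_size=2.0,
                               n_per_group=20, seed=55)
        matrix, phenotype, _ = simulate_beta_matrix(cfg)
        a = compare_svd_nmf(matrix, phenotype, n_permutations=12, seed=3)
        b = compare_svd_nmf(matrix, phenotype, n_permutations=12, seed=3)
        assert a["k"] == b["k"]
        assert a["nmf_r2"].best_two_mean == b["nmf_r2"].best_two_mean
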