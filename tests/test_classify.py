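import numpy as np
import pandas as pd
import pytest

from methbench import (
    MethylationMatrix,
    Phenotype,
    evaluate_cindex,
    fit_elastic_net,
    fit_spca_predictor,
    fit_svm_regression,
    run_classifier_comparison,
)
from methbench.classify import lambda_max


def _cont_study(n_features=60, n=40, signal=True, seed=0, noise=0.02):
    """One latent factor drives both a subset of CpGs and (optionally) the
    phenotype."""
    rng = np.random.default_rng(seed)
    factor = rng.normal(0, 1, n)
    loadings = np.zeros(n_features)
    loadings[: n_features // 3] = rng.uniform(0.05, 0.12, n_features // 3)
    x = 0.5 + np.outer(loadings, factor) + rng.normal(0, noise, (n_features, n))
    ids = [f"cg{i:03d}" for i in range(n_features)]
    cols = [f"S{i:03d}" for i in range(n)]
    matrix = MethylationMatrix(
        pd.DataFrame(np.clip(x, 1e-6, 1 - 1e-6), index=ids, columns=cols), "beta"
    )
    age = 55 + 15 * factor if signal else rng.uniform(25, 90, n)
    phenotype = Phenotype(pd.Series(age, index=cols), "continuous")
    return matrix, phenotype, factor


class TestCIndex:
    def test_perfect_prediction(self):
        assert evaluate_cindex([1.0, 2, 3, 4], np.array([10.0, 20, 30, 40])).c_index == 1.0

    def test_reversed_prediction(self):
        res = evaluate_cindex([4.0, 3, 2, 1], np.array([10.0, 20, 30, 40]))
        assert res.c_index == 0.0

    def test_four_point_worked_example(self):
        res = evaluate_cindex([1.0, 2, 4, 3], np.array([1.0, 2, 3, 4]))
        assert res.c_index == pytest.approx(5 / 6)
        assert res.n_comparable_pairs == 6

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(25, 90, 30)
        pred = rng.normal(0, 1, 30)
        a = evaluate_cindex(pred, y).c_index
        b = evaluate_cindex(np.exp(3 * pred) + 7, y).c_index
        assert a == pytest.approx(b)

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ValueError):
            evaluate_cindex([1.0, 2.0], np.array([50.0, 50.0]))

    def test_tied_predictions_count_half(self):
        res = evaluate_cindex([1.0, 1.0], np.array([10.0, 20.0]))
        assert res.c_index == pytest.approx(0.5)


class TestElasticNet:
    def test_lambda_above_max_zeroes_all_coefficients(self):
        matrix, phenotype, _ = _cont_study(seed=2)
        model = fit_elastic_net(matrix, phenotype, alpha=1.0, n_lambda=5)
        x = matrix.values.loc[model.feature_ids].to_numpy().T
        z = (x - model.params["center"]) / model.params["scale"]
        y = phenotype.values.to_numpy()
        lam_hi = lambda_max(z, y, 1.0)
        from sklearn.linear_model import ElasticNet

        m = ElasticNet(alpha=lam_hi * 1.0001, l1_ratio=1.0, tol=1e-10)
        m.fit(z, y)
        assert np.allclose(m.coef_, 0.0)
        # and well below lambda_max coefficients activate
        m2 = ElasticNet(alpha=lam_hi * 0.5, l1_ratio=1.0, tol=1e-10)
        m2.fit(z, y)
        assert np.any(m2.coef_ != 0)

    def test_univariate_lasso_soft_threshold(self):
        """With one standardized feature the lasso solution is the
        soft-thresholded OLS slope."""
        rng = np.random.default_rng(3)
        n = 400
        x = rng.normal(0, 1, n)
        x = (x - x.mean()) / x.std()
        y = 2.0 * x + rng.normal(0, 0.5, n)
        b_ols = float(x @ (y - y.mean())) / n
        lam = 0.7
        from sklearn.linear_model import ElasticNet

        m = ElasticNet(alpha=lam, l1_ratio=1.0, tol=1e-10)
        m.fit(x[:, None], y)
        expect = np.sign(b_ols) * max(abs(b_ols) - lam, 0.0)
        assert m.coef_[0] == pytest.approx(expect, abs=1e-6)

    def test_kkt_conditions_at_solution(self):
        matrix, phenotype, _ = _cont_study(n_features=30, seed=4)
        model = fit_elastic_net(matrix, phenotype, alpha=0.5, tol=1e-9)
        x = matrix.values.loc[model.feature_ids].to_numpy().T
        z = (x - model.params["center"]) / model.params["scale"]
        y = phenotype.values.to_numpy()
        beta = model.params["coef"]
        lam, alpha = model.tuning["lambda"], 0.5
        n = y.size
        resid = y - model.params["intercept"] - z @ beta
        grad = -z.T @ resid / n + lam * (1 - alpha) * beta
        active = beta != 0
        # active coordinates: gradient balances the l1 subgradient exactly
        assert np.allclose(grad[active], -lam * alpha * np.sign(beta[active]), atol=1e-7)
        # inactive: within the l1 tube
        assert np.all(np.abs(grad[~active]) <= lam * alpha + 1e-7)

    def test_grouping_effect_selects_more_correlated_truth(self):
        """The elastic net keeps groups of correlated informative features
        the lasso thins out."""
        rng = np.random.default_rng(5)
        n, n_truth, n_noise = 80, 50, 200
        factor = rng.normal(0, 1, n)
        truth_block = 0.5 + 0.08 * np.outer(np.ones(n_truth), factor)
        truth_block += rng.normal(0, 0.02, truth_block.shape)
        noise_block = rng.uniform(0.3, 0.7, (n_noise, n))
        values = np.clip(np.vstack([truth_block, noise_block]), 1e-6, 1 - 1e-6)
        ids = [f"cg{i:03d}" for i in range(n_truth + n_noise)]
        cols = [f"S{i:03d}" for i in range(n)]
        matrix = MethylationMatrix(pd.DataFrame(values, index=ids, columns=cols), "beta")
        phenotype = Phenotype(
            pd.Series(55 + 12 * factor + rng.normal(0, 3, n), index=cols), "continuous"
        )
        lasso = fit_elastic_net(matrix, phenotype, alpha=1.0, seed=1)
        elnet = fit_elastic_net(matrix, phenotype, alpha=0.05, seed=1)
        truth_ids = set(ids[:n_truth])

        def truth_hits(model):
            sel = {f for f, c in zip(model.feature_ids, model.params["coef"]) if c != 0}
            return len(sel & truth_ids)

        assert truth_hits(elnet) > truth_hits(lasso)

    def test_constant_phenotype_rejected(self):
        matrix, phenotype, _ = _cont_study(seed=6)
        flat = Phenotype(pd.Series(50.0, index=phenotype.sample_ids), "continuous")
        with pytest.raises(ValueError):
            fit_elastic_net(matrix, flat)


class TestSVM:
    def test_training_fit_respects_epsilon_tube(self):
        matrix, phenotype, _ = _cont_study(seed=7)
        model = fit_svm_regression(matrix, phenotype)
        pred = model.predict(matrix).to_numpy()
        y = phenotype.values.to_numpy()
        svr = model.params["svr"]
        # non-support points must lie strictly inside the epsilon tube
        non_sv = np.setdiff1d(np.arange(y.size), svr.support_)
        if non_sv.size:
            scaled_eps = 0.1 + 1e-6
            assert np.all(np.abs(pred[non_sv] - y[non_sv]) <= scaled_eps)

    def test_duplicated_samples_match_doubled_cost(self):
        """Duplicating every training sample doubles the total slack
        penalty, so it is equivalent to doubling the cost parameter."""
        matrix, phenotype, _ = _cont_study(n=20, seed=8)
        doubled_vals = pd.concat(
            [matrix.values, matrix.values.add_suffix("_dup", axis=1)], axis=1
        )
        doubled = MethylationMatrix(doubled_vals, "beta")
        dph = Phenotype(
            pd.concat([phenotype.values, phenotype.values.set_axis(doubled_vals.columns[20:])]),
            "continuous",
        )
        a = fit_svm_regression(matrix, phenotype, cost=2.0)
        b = fit_svm_regression(doubled, dph, cost=1.0)
        assert np.allclose(
            a.predict(matrix).to_numpy(), b.predict(matrix).to_numpy(), atol=1e-4
        )

    def test_monotone_single_feature_fixture(self):
        rng = np.random.default_rng(9)
        n = 200
        age = np.sort(rng.uniform(25, 90, n))
        x = 0.2 + 0.006 * (age - 25) + rng.normal(0, 0.01, n)
        ids = ["cg000"]
        cols = [f"S{i:03d}" for i in range(n)]
        matrix = MethylationMatrix(
            pd.DataFrame(np.clip(x, 1e-6, 1 - 1e-6)[None, :], index=ids, columns=cols), "beta"
        )
        phenotype = Phenotype(pd.Series(age, index=cols), "continuous")
        train = cols[::2]
        test = cols[1::2]
        model = fit_svm_regression(matrix.subset_samples(train), phenotype.subset(train))
        pred = model.predict(matrix.subset_samples(test))
        c = evaluate_cindex(pred.to_numpy(), phenotype.subset(test).values.to_numpy())
        assert c.c_index > 0.9


class TestSPCAPredictor:
    def test_one_factor_fixture_recovered(self):
        matrix, phenotype, _ = _cont_study(n_features=90, n=60, seed=10)
        train = list(matrix.sample_ids[:40])
        test = list(matrix.sample_ids[40:])
        model = fit_spca_predictor(
            matrix.subset_samples(train), phenotype.subset(train), n_components=1
        )
        pred = model.predict(matrix.subset_samples(test))
        c = evaluate_cindex(pred.to_numpy(), phenotype.subset(test).values.to_numpy())
        assert c.c_index > 0.95

    def test_extra_components_add_no_signal_on_one_factor_data(self):
        matrix, phenotype, _ = _cont_study(n_features=90, n=60, seed=11)
        train = list(matrix.sample_ids[:40])
        test = list(matrix.sample_ids[40:])
        cs = {}
        for m in (1, 3):
            model = fit_spca_predictor(
                matrix.subset_samples(train), phenotype.subset(train), n_components=m
            )
            pred = model.predict(matrix.subset_samples(test))
            cs[m] = evaluate_cindex(
                pred.to_numpy(), phenotype.subset(test).values.to_numpy()
            ).c_index
        assert cs[3] <= cs[1] + 0.02

    def test_seeded_threshold_choice_is_reproducible(self):
        matrix, phenotype, _ = _cont_study(seed=12)
        a = fit_spca_predictor(matrix, phenotype, 1, seed=5)
        b = fit_spca_predictor(matrix, phenotype, 1, seed=5)
        assert a.tuning["threshold"] == b.tuning["threshold"]

    def test_too_many_components_rejected(self):
        matrix, phenotype, _ = _cont_study(n=6, seed=13)
        with pytest.raises(ValueError):
            fit_spca_predictor(matrix, phenotype, n_components=6)


class TestComparisonHarness:
    def test_null_phenotype_hovers_at_half(self):
        matrix, phenotype, _ = _cont_study(n_features=120, n=60, signal=False, seed=14)
        table = run_classifier_comparison(matrix, phenotype, n_partitions=8, seed=3)
        med = table.median()
        assert np.all(np.abs(med - 0.5) < 0.12)

    def test_fixed_seed_reproduces_table(self):
        matrix, phenotype, _ = _cont_study(n_features=80, n=44, seed=15)
        a = run_classifier_comparison(matrix, phenotype, n_partitions=2, seed=4,
                                      methods=("SPCA-1", "LASSO"))
        b = run_classifier_comparison(matrix, phenotype, n_partitions=2, seed=4,
                                      methods=("SPCA-1", "LASSO"))
        pd.testing.assert_frame_equal(a, b)
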