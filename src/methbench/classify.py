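"""Phenotype prediction from methylation profiles and C-index evaluation.

Four predictor families are compared on a continuous (age-like) phenotype:

* **SPCA-1/2/3** — supervised principal components: CpGs are ranked by
  univariate regression significance, a feature-count threshold (10..5000)
  is tuned by internal 10-fold cross-validation, the thresholded centered
  submatrix is decomposed by SVD, and the phenotype is regressed on the
  leading 1-3 component scores.
* **LASSO / ELNET** — glmnet-style penalised regression minimising
  (1/2n)||y - b0 - Xb||^2 + lambda[(1-alpha)||b||_2^2/2 + alpha||b||_1],
  LASSO being the alpha = 1 special case and the Elastic Net run at
  alpha = 0.05; lambda is tuned by internal 10-fold cross-validation over
  a 100-point log-spaced path from lambda_max down to 1e-3 lambda_max.
* **SVM regression** — epsilon-insensitive support-vector regression with
  an RBF kernel, gamma = 3 and epsilon = 0.1 held fixed, cost C = 1.
  Gamma is applied to the *mean* squared difference over standardized
  features (i.e. the sklearn gamma is 3/p), so its value keeps the same
  meaning regardless of how many CpGs enter the kernel.

Predictors emit a continuous score; accuracy is the concordance (C-) index
between score and phenotype over all sample pairs with distinct phenotype
values (prediction ties count 1/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index as _lifelines_cindex
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.svm import SVR

from .association import linear_assoc
from .datatypes import MethylationMatrix, PartitionSet, Phenotype
from .ppv import compare_ppv, make_partitions
from .selection import _rank_by_significance

ELNET_ALPHA = 0.05
SVM_GAMMA = 3.0
SVM_EPSILON = 0.1
SVM_COST = 1.0
N_LAMBDA = 100
LAMBDA_MIN_RATIO = 1e-3
CV_FOLDS = 10
SPCA_MIN_FEATURES = 10
SPCA_MAX_FEATURES = 5000
PREFILTER_FEATURES = 5000


@dataclass
class PredictorModel:
    """A fitted phenotype predictor: feature set, parameters, tuning record."""

    method: str
    feature_ids: list
    params: dict
    tuning: dict = field(default_factory=dict)

    def predict(self, matrix: MethylationMatrix) -> pd.Series:
        """Score samples of ``matrix`` (which must contain the training
        features); deterministic."""
        x = matrix.values.loc[self.feature_ids].to_numpy().T  # samples x features
        p = self.params
        if self.method.startswith("SPCA"):
            comps = (x - p["center"]) @ p["loadings"]
            score = p["intercept"] + comps @ p["coef"]
        elif self.method in ("LASSO", "ELNET"):
            z = (x - p["center"]) / p["scale"]
            score = p["intercept"] + z @ p["coef"]
        elif self.method == "SVM":
            z = (x - p["center"]) / p["scale"]
            score = p["svr"].predict(z)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        return pd.Series(np.asarray(score, dtype=float), index=matrix.sample_ids)


@dataclass
class ConcordanceResult:
    c_index: float
    n_comparable_pairs: int


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _quantile_stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold assignment stratified by phenotype quantile, seeded."""
    rng = np.random.default_rng(seed)
    order = np.argsort(y + rng.normal(0, 1e-12, size=y.size))  # jitter breaks ties
    folds = np.empty(y.size, dtype=int)
    fold_cycle = np.arange(y.size) % n_folds
    # within each consecutive quantile block of n_folds samples, shuffle
    for start in range(0, y.size, n_folds):
        block = order[start : start + n_folds]
        folds[block] = rng.permutation(fold_cycle[start : start + n_folds])
    return folds


def _standardize_fit(x: np.ndarray):
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return center, scale


def _prefilter_by_variance(matrix: MethylationMatrix, n: int) -> list:
    variances = matrix.values.var(axis=1, ddof=1)
    order = variances.to_frame("var").reset_index(names="cpg").sort_values(
        by=["var", "cpg"], ascending=[False, True], kind="mergesort"
    )
    return list(order["cpg"].iloc[: min(n, len(order))])


# ---------------------------------------------------------------------------
# SPCA predictor
# ---------------------------------------------------------------------------

def _spca_fit_components(x: np.ndarray, y: np.ndarray, n_components: int):
    """Center features, SVD, regress y on the leading component scores."""
    center = x.mean(axis=0)
    xc = x - center
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    n_comp = min(n_components, int(np.sum(s > 1e-12 * s[0])) if s.size else 0)
    if n_comp == 0:
        raise ValueError("degenerate training matrix (rank 0 after centering)")
    loadings = vt[:n_comp].T  # features x n_comp
    comps = xc @ loadings  # = u * s
    design = np.column_stack([np.ones(y.size), comps])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return center, loadings, coef[0], coef[1:]


def _spca_threshold_grid(n_features: int) -> np.ndarray:
    hi = min(SPCA_MAX_FEATURES, n_features)
    if hi <= SPCA_MIN_FEATURES:
        return np.array([hi])
    grid = np.unique(
        np.round(np.geomspace(SPCA_MIN_FEATURES, hi, num=8)).astype(int)
    )
    return grid


def fit_spca_predictor(
    matrix: MethylationMatrix,
    phenotype: Phenotype,
    n_components: int = 1,
    cv_folds: int = CV_FOLDS,
    seed: int = 0,
) -> PredictorModel:
    """Supervised-PCA regression predictor with CV-tuned feature count."""
    models = fit_spca_family(matrix, phenotype, (n_components,), cv_folds, seed)
    return models[n_components]


def fit_spca_family(
    matrix: MethylationMatrix,
    phenotype: Phenotype,
    components=(1, 2, 3),
    cv_folds: int = CV_FOLDS,
    seed: int = 0,
) -> dict:
    """Fit SPCA predictors for several component counts in one pass,
    sharing the per-threshold cross-validated SVDs."""
    if phenotype.kind != "continuous":
        raise ValueError("SPCA predictor expects a continuous phenotype")
    max_comp = max(components)
    n = matrix.n_samples
    if max_comp > min(n - 1, matrix.n_features):
        raise ValueError("n_components exceeds the rank the data can support")
    y = phenotype.values.to_numpy(dtype=float)
    values_t = matrix.values.to_numpy().T  # samples x features
    feature_index = matrix.feature_ids
    grid = _spca_threshold_grid(matrix.n_features)
    folds = _quantile_stratified_folds(y, cv_folds, seed)
    cv_c = {m: np.zeros((grid.size, cv_folds)) for m in components}
    for f in range(cv_folds):
        tr, te = folds != f, folds == f
        if te.sum() < 2 or tr.sum() <= max_comp:
            continue
        sub_matrix = MethylationMatrix(
            pd.DataFrame(
                values_t[tr].T, index=feature_index, columns=matrix.sample_ids[tr]
            ),
            matrix.measure,
        )
        sub_ph = Phenotype(pd.Series(y[tr], index=matrix.sample_ids[tr]), "continuous")
        ranked_ids = _rank_by_significance(linear_assoc(sub_matrix, sub_ph)).index
        pos = feature_index.get_indexer(ranked_ids)
        for gi, thr in enumerate(grid):
            take = pos[: min(thr, pos.size)]
            x_tr = values_t[np.ix_(tr, take)]
            x_te = values_t[np.ix_(te, take)]
            try:
                center, loadings, b0, bw = _spca_fit_components(x_tr, y[tr], max_comp)
            except ValueError:
                continue
            comps_te = (x_te - center) @ loadings
            for m in components:
                mm = min(m, loadings.shape[1])
                # refit regression weights with the first mm components
                design = np.column_stack(
                    [np.ones(tr.sum()), (x_tr - center) @ loadings[:, :mm]]
                )
                coef, *_ = np.linalg.lstsq(design, y[tr], rcond=None)
                pred = coef[0] + comps_te[:, :mm] @ coef[1:]
                try:
                    cv_c[m][gi, f] = evaluate_cindex(pred, y[te]).c_index
                except ValueError:
                    cv_c[m][gi, f] = 0.5
    # full-training ranking for the final refit
    ranked_ids = _rank_by_significance(linear_assoc(matrix, phenotype)).index
    pos_full = feature_index.get_indexer(ranked_ids)
    models = {}
    for m in components:
        mean_c = cv_c[m].mean(axis=1)
        best = int(np.argmax(mean_c))  # argmax takes the first (smallest) on ties
        thr = int(grid[best])
        take = pos_full[: min(thr, pos_full.size)]
        x = values_t[:, take]
        center, loadings, b0, bw = _spca_fit_components(x, y, m)
        models[m] = PredictorModel(
            method=f"SPCA-{m}",
            feature_ids=list(feature_index[take]),
            params={"center": center, "loadings": loadings, "intercept": b0, "coef": bw},
            tuning={"threshold": thr, "cv_concordance": float(mean_c[best])},
        )
    return models


# ---------------------------------------------------------------------------
# Elastic net / LASSO
# ---------------------------------------------------------------------------

def lambda_max(x_std: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest lambda with an all-zero solution: max|x_j . y_c| / (n alpha)."""
    yc = y - y.mean()
    return float(np.max(np.abs(x_std.T @ yc)) / (x_std.shape[0] * alpha))


def fit_elastic_net(
    matrix: MethylationMatrix,
    phenotype: Phenotype,
    alpha: float = ELNET_ALPHA,
    cv_folds: int = CV_FOLDS,
    n_lambda: int = N_LAMBDA,
    lambda_min_ratio: float = LAMBDA_MIN_RATIO,
    seed: int = 0,
    prefilter: int | None = PREFILTER_FEATURES,
    tol: float = 1e-3,
) -> PredictorModel:
    """Elastic-net regression with lambda tuned by internal 10-fold CV.

    ``alpha`` is the L1 mixing weight (alpha = 1 is the LASSO).  Features
    are standardized internally; by default the ``prefilter`` most variable
    training CpGs enter the model.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if phenotype.kind != "continuous":
        raise ValueError("elastic net regression expects a continuous phenotype")
    y = phenotype.values.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    ids = (
        _prefilter_by_variance(matrix, prefilter)
        if prefilter is not None and matrix.n_features > prefilter
        else list(matrix.feature_ids)
    )
    x = matrix.values.loc[ids].to_numpy().T
    center, scale = _standardize_fit(x)
    z = (x - center) / scale
    lam_max = lambda_max(z, y, alpha)
    if lam_max <= 0:
        raise ValueError("all features are uncorrelated with the phenotype")
    path = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    folds = _quantile_stratified_folds(y, cv_folds, seed)
    sq_err = np.zeros(n_lambda)
    counts = np.zeros(n_lambda)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for f in range(cv_folds):
            tr, te = folds != f, folds == f
            if te.sum() == 0 or tr.sum() < 3:
                continue
            c_f, s_f = _standardize_fit(x[tr])
            z_tr = (x[tr] - c_f) / s_f
            y_tr = y[tr]
            _, coefs, _ = enet_path(
                z_tr, y_tr - y_tr.mean(), l1_ratio=alpha, alphas=path, tol=tol
            )
            pred = ((x[te] - c_f) / s_f) @ coefs + y_tr.mean()
            sq_err += ((pred - y[te][:, None]) ** 2).sum(axis=0)
            counts += te.sum()
        mse = sq_err / np.maximum(counts, 1)
        best = int(np.argmin(mse))
        lam = float(path[best])
        model = ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=True, tol=tol, max_iter=10_000
        )
        model.fit(z, y)
    return PredictorModel(
        method="LASSO" if alpha == 1 else "ELNET",
        feature_ids=ids,
        params={
            "center": center,
            "scale": scale,
            "coef": model.coef_,
            "intercept": float(model.intercept_),
        },
        tuning={"lambda": lam, "alpha": alpha, "cv_mse": float(mse[best])},
    )


# ---------------------------------------------------------------------------
# SVM regression
# ---------------------------------------------------------------------------

def fit_svm_regression(
    matrix: MethylationMatrix,
    phenotype: Phenotype,
    gamma: float = SVM_GAMMA,
    epsilon: float = SVM_EPSILON,
    cost: float = SVM_COST,
    prefilter: int | None = PREFILTER_FEATURES,
) -> PredictorModel:
    """Epsilon-insensitive RBF support-vector regression.

    gamma and epsilon are fixed (not tuned); gamma applies to the mean
    squared difference across standardized features, keeping the kernel
    width independent of the number of CpGs.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    y = phenotype.values.to_numpy(dtype=float)
    ids = (
        _prefilter_by_variance(matrix, prefilter)
        if prefilter is not None and matrix.n_features > prefilter
        else list(matrix.feature_ids)
    )
    x = matrix.values.loc[ids].to_numpy().T
    center, scale = _standardize_fit(x)
    z = (x - center) / scale
    svr = SVR(kernel="rbf", gamma=gamma / z.shape[1], epsilon=epsilon, C=cost)
    svr.fit(z, y)
    return PredictorModel(
        method="SVM",
        feature_ids=ids,
        params={"center": center, "scale": scale, "svr": svr},
        tuning={"gamma": gamma, "epsilon": epsilon, "C": cost},
    )


# ---------------------------------------------------------------------------
# C-index and the comparison harness
# ---------------------------------------------------------------------------

def evaluate_cindex(predictions, phenotype) -> ConcordanceResult:
    """Concordance index between predicted scores and a continuous outcome.

    Over all sample pairs with distinct phenotype values, a pair is
    concordant when the predictions order the same way; prediction ties
    count 1/2.
    """
    pred = np.asarray(predictions, dtype=float)
    y = np.asarray(
        phenotype.values if isinstance(phenotype, Phenotype) else phenotype, dtype=float
    )
    if pred.size != y.size:
        raise ValueError("length mismatch")
    _, tie_counts = np.unique(y, return_counts=True)
    n_pairs = y.size * (y.size - 1) // 2 - int(np.sum(tie_counts * (tie_counts - 1) // 2))
    if n_pairs == 0:
        raise ValueError("no comparable pairs: phenotype is constant")
    c = float(_lifelines_cindex(y, pred))
    return ConcordanceResult(c, n_pairs)


def run_classifier_comparison(
    matrix: MethylationMatrix,
    phenotype: Phenotype,
    partitions: PartitionSet | None = None,
    n_partitions: int = 50,
    seed: int = 0,
    methods=("SPCA-1", "SPCA-2", "SPCA-3", "LASSO", "ELNET", "SVM"),
) -> pd.DataFrame:
    """Fit every predictor on each training half and score the test half.

    Returns a partition x method table of test C-indices; see
    :func:`summarize_comparison` for medians and pairwise Wilcoxon tests.
    """
    if partitions is None:
        partitions = make_partitions(phenotype, n_partitions, seed)
    spca_wanted = sorted(int(m.split("-")[1]) for m in methods if m.startswith("SPCA"))
    rows = []
    for j, (train_ids, test_ids) in enumerate(partitions):
        train_m = matrix.subset_samples(train_ids)
        test_m = matrix.subset_samples(test_ids)
        train_ph = phenotype.subset(train_ids)
        test_y = phenotype.subset(test_ids).values.to_numpy(dtype=float)
        fitted = {}
        if spca_wanted:
            family = fit_spca_family(train_m, train_ph, tuple(spca_wanted), seed=seed + j)
            for m in spca_wanted:
                fitted[f"SPCA-{m}"] = family[m]
        if "LASSO" in methods:
            fitted["LASSO"] = fit_elastic_net(train_m, train_ph, alpha=1.0, seed=seed + j)
        if "ELNET" in methods:
            fitted["ELNET"] = fit_elastic_net(
                train_m, train_ph, alpha=ELNET_ALPHA, seed=seed + j
            )
        if "SVM" in methods:
            fitted["SVM"] = fit_svm_regression(train_m, train_ph)
        row = {}
        for name in methods:
            try:
                pred = fitted[name].predict(test_m)
                row[name] = evaluate_cindex(pred.to_numpy(), test_y).c_index
            except Exception as exc:
                raise RuntimeError(f"method {name}, partition {j} failed: {exc}") from exc
        rows.append(row)
    return pd.DataFrame(rows, index=pd.RangeIndex(len(rows), name="partition"))


def summarize_comparison(cindex_table: pd.DataFrame) -> dict:
    """Medians per method plus pairwise two-sided Wilcoxon rank-sum p-values."""
    methods = list(cindex_table.columns)
    medians = cindex_table.median().to_dict()
    pairwise = {}
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            cmp = compare_ppv(cindex_table[a].to_numpy(), cindex_table[b].to_numpy())
            pairwise[(a, b)] = cmp.p_value
    return {"medians": medians, "pairwise_wilcoxon_p": pairwise}
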