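"""Unsupervised modelling: SVD vs NNDSVD-initialised NMF.

Beta-valued methylation matrices are non-negative, which makes non-negative
matrix factorisation (NMF) a natural alternative to SVD/PCA.  To compare
the two fairly the NMF is made deterministic: it is initialised with
non-negative double SVD (NNDSVD, zeros left as zeros) and run with the
Brunet multiplicative updates minimising the generalised Kullback-Leibler
divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ].

The number of components is estimated by comparing the observed singular
values against those of matrices whose entries have been randomly permuted
(destroying all covariance while keeping the marginal distribution), and
each algorithm is scored by the R^2 of its component scores against the
phenotype, summarised as the average R^2 of the two best components.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import ComponentAssociation, Decomposition, MethylationMatrix, Phenotype

NMF_TOL = 1e-6
NMF_MAX_ITER = 2000
NMF_EPS = 1e-12


def svd_decompose(matrix: MethylationMatrix, k: int) -> Decomposition:
    """Thin SVD of the feature-centered matrix, components by decreasing
    singular value.  Components beyond the matrix rank carry (numerically)
    zero singular values."""
    if k > min(matrix.values.shape):
        raise ValueError("k exceeds matrix dimensions")
    x = matrix.values.to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    basis = pd.DataFrame(u[:, :k], index=matrix.feature_ids)
    scores = pd.DataFrame(s[:k, None] * vt[:k], columns=matrix.sample_ids)
    return Decomposition("SVD", basis, scores, k, singular_values=s[:k])


def estimate_n_components(
    matrix: MethylationMatrix,
    n_permutations: int = 50,
    quantile: float = 0.95,
    seed: int = 0,
) -> int:
    """Permutation estimate of the number of non-noise components.

    All matrix entries are permuted jointly ``n_permutations`` times; k is
    the number of *leading* observed singular values that exceed the given
    quantile of the rank-matched permuted singular values.
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations")
    x = matrix.values.to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    obs = np.linalg.svd(xc, compute_uv=False)
    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, obs.size))
    flat = x.ravel()
    for i in range(n_permutations):
        perm = rng.permutation(flat).reshape(x.shape)
        perm = perm - perm.mean(axis=1, keepdims=True)
        null[i] = np.linalg.svd(perm, compute_uv=False)
    thresh = np.quantile(null, quantile, axis=0)
    exceed = obs > thresh
    k = 0
    while k < exceed.size and exceed[k]:
        k += 1
    return k


def nndsvd_init(values: np.ndarray, k: int):
    """Non-negative double SVD initialisation (zeros variant).

    The leading singular triplet of a non-negative matrix is non-negative
    (up to sign) and is used directly; for later components the positive or
    negative section of each singular-vector pair — whichever has the
    larger norm product — is kept, scaled by the singular value.  Zeros are
    left at zero (no random fill), so the initialisation is deterministic.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("NNDSVD requires a non-negative matrix")
    if k > min(v.shape):
        raise ValueError("k exceeds matrix dimensions")
    u, s, vt = np.linalg.svd(v, full_matrices=False)
    w = np.zeros((v.shape[0], k))
    h = np.zeros((k, v.shape[1]))
    w[:, 0] = np.sqrt(s[0]) * np.abs(u[:, 0])
    h[0] = np.sqrt(s[0]) * np.abs(vt[0])
    for j in range(1, k):
        uj, vj = u[:, j], vt[j]
        up, un = np.maximum(uj, 0), np.maximum(-uj, 0)
        vp, vn = np.maximum(vj, 0), np.maximum(-vj, 0)
        norm_p = np.linalg.norm(up) * np.linalg.norm(vp)
        norm_n = np.linalg.norm(un) * np.linalg.norm(vn)
        if norm_p >= norm_n:
            if norm_p > 0:
                scale = np.sqrt(s[j] * norm_p)
                w[:, j] = scale * up / np.linalg.norm(up)
                h[j] = scale * vp / np.linalg.norm(vp)
        elif norm_n > 0:
            scale = np.sqrt(s[j] * norm_n)
            w[:, j] = scale * un / np.linalg.norm(un)
            h[j] = scale * vn / np.linalg.norm(vn)
    return w, h


def _kl_divergence(v: np.ndarray, wh: np.ndarray) -> float:
    wh = np.maximum(wh, NMF_EPS)
    mask = v > 0
    term = np.where(mask, v * np.log(np.where(mask, v, 1.0) / wh) - v, 0.0)
    return float(np.sum(term + wh))


def nmf_brunet(
    matrix,
    k: int,
    init=None,
    tol: float = NMF_TOL,
    max_iter: int = NMF_MAX_ITER,
) -> Decomposition:
    """Brunet-style NMF: multiplicative KL updates from an NNDSVD start.

    Accepts a beta-valued :class:`MethylationMatrix` or a raw non-negative
    array.  Stops when the relative objective change falls below ``tol`` or
    after ``max_iter`` iterations; the objective trace is recorded and is
    non-increasing.
    """
    if isinstance(matrix, MethylationMatrix):
        if matrix.measure != "beta":
            raise ValueError("NMF is defined for the non-negative beta measure only")
        v = matrix.values.to_numpy()
        feature_ids = matrix.feature_ids
        sample_ids = matrix.sample_ids
    else:
        v = np.asarray(matrix, dtype=float)
        feature_ids = pd.RangeIndex(v.shape[0])
        sample_ids = pd.RangeIndex(v.shape[1])
    if np.any(v < 0):
        raise ValueError("NMF requires a non-negative matrix")
    if np.any(v.sum(axis=1) == 0) or np.any(v.sum(axis=0) == 0):
        warnings.warn("zero rows/columns floored at a tiny epsilon")
        v = np.maximum(v, NMF_EPS)
    if init is None:
        w, h = nndsvd_init(v, k)
    else:
        w, h = (np.array(init[0], dtype=float), np.array(init[1], dtype=float))
    # zeros (and near-zeros) are absorbing under multiplicative updates,
    # locking the factors into the initial sparsity pattern; fill them with
    # the matrix mean — deterministic, so runs remain bit-reproducible
    fill = float(v.mean())
    w = np.where(w < NMF_EPS, fill, w)
    h = np.where(h < NMF_EPS, fill, h)
    trace = [_kl_divergence(v, w @ h)]
    for _ in range(max_iter):
        wh = np.maximum(w @ h, NMF_EPS)
        h *= (w.T @ (v / wh)) / np.maximum(w.sum(axis=0)[:, None], NMF_EPS)
        wh = np.maximum(w @ h, NMF_EPS)
        w *= ((v / wh) @ h.T) / np.maximum(h.sum(axis=1)[None, :], NMF_EPS)
        obj = _kl_divergence(v, w @ h)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            break
    return Decomposition(
        "NMF",
        pd.DataFrame(w, index=feature_ids),
        pd.DataFrame(h, columns=sample_ids),
        k,
        objective_trace=np.asarray(trace),
    )


def component_phenotype_r2(decomp: Decomposition, phenotype: Phenotype) -> ComponentAssociation:
    """Per-component R^2 of a simple linear regression against the
    phenotype (binary coded 0/1), summarised as the mean of the two
    largest (the single R^2 when k = 1)."""
    if decomp.k == 0 or decomp.scores.shape[0] == 0:
        raise ValueError("decomposition has no components")
    scores = decomp.scores.loc[:, phenotype.sample_ids].to_numpy()
    y = phenotype.values.to_numpy(dtype=float)
    yc = y - y.mean()
    y_ss = float(yc @ yc)
    r2 = np.zeros(scores.shape[0])
    for c in range(scores.shape[0]):
        sc = scores[c] - scores[c].mean()
        denom = float(sc @ sc) * y_ss
        r2[c] = (float(sc @ yc) ** 2) / denom if denom > 0 else 0.0
    best_two = np.sort(r2)[::-1][: min(2, r2.size)]
    return ComponentAssociation(r2, float(best_two.mean()))


def compare_svd_nmf(
    matrix: MethylationMatrix,
    phenotype: Phenotype,
    n_permutations: int = 50,
    seed: int = 0,
    k: int | None = None,
) -> dict:
    """Head-to-head SVD vs NMF at a shared component count.

    k comes from the permutation estimate unless given; a k of 0 falls
    back to 2 with a warning.  Returns the two decompositions and their
    phenotype associations.
    """
    if matrix.measure != "beta":
        raise ValueError("comparison is defined on the beta measure")
    if k is None:
        k = estimate_n_components(matrix, n_permutations, seed=seed)
    if k == 0:
        warnings.warn("permutation estimate found no components; falling back to k=2")
        k = 2
    svd = svd_decompose(matrix, k)
    nmf = nmf_brunet(matrix, k)
    return {
        "k": k,
        "svd": svd,
        "nmf": nmf,
        "svd_r2": component_phenotype_r2(svd, phenotype),
        "nmf_r2": component_phenotype_r2(nmf, phenotype),
    }
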