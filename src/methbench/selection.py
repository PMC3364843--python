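"""Feature-selection procedures compared by the benchmark.

Three ways of picking phenotype-associated CpGs from a training set:

* **WF** (without filtering): rank every CpG by supervised p-value, keep the
  top k (default 1,500).
* **VF** (variance filtering): restrict to the 5,000 most variable CpGs
  (unsupervised, computed before any phenotype is looked at), rank those by
  supervised p-value, keep the top k or however many reach p < 0.05 if that
  is fewer.
* **SPCA** (supervised principal components): take the 5,000 most
  significant CpGs, run an SVD of that centered submatrix, pick the
  component whose sample scores correlate best (absolute Pearson) with the
  phenotype, and rank CpGs by the absolute loading on that component.

Ties are broken everywhere by larger absolute statistic, then lexicographic
CpG ID, so all rankings are fully deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .association import linear_assoc, moderated_t, t_test_by_feature
from .datatypes import MethylationMatrix, Phenotype, RankedFeatureList

DEFAULT_K = 1500
DEFAULT_POOL = 5000
MAX_SPCA_COMPONENTS = 30


def compute_association(
    matrix: MethylationMatrix, phenotype: Phenotype, statistic: str
) -> pd.DataFrame:
    """Dispatch to the association statistic named by ``statistic``
    ("t", "moderated_t" or "linear")."""
    if statistic == "t":
        return t_test_by_feature(matrix, phenotype)
    if statistic == "moderated_t":
        return moderated_t(matrix, phenotype)
    if statistic == "linear":
        return linear_assoc(matrix, phenotype)
    raise ValueError(f"unknown statistic {statistic!r}")


def _rank_by_significance(assoc: pd.DataFrame) -> pd.DataFrame:
    """Order an association table by (p asc, |stat| desc, CpG ID asc),
    dropping unrankable (NaN-statistic) features."""
    valid = assoc[np.isfinite(assoc["stat"]) & np.isfinite(assoc["p"])].copy()
    valid["_abs_stat"] = valid["stat"].abs()
    valid["_cpg"] = valid.index
    valid = valid.sort_values(
        by=["p", "_abs_stat", "_cpg"], ascending=[True, False, True], kind="mergesort"
    )
    return valid.drop(columns=["_abs_stat", "_cpg"])


def select_wf(assoc: pd.DataFrame, k: int = DEFAULT_K) -> RankedFeatureList:
    """Without-filtering selection: top-k CpGs by supervised p-value."""
    ranked = _rank_by_significance(assoc)
    if k > len(ranked):
        warnings.warn(
            f"requested {k} features but only {len(ranked)} are rankable; truncating"
        )
        k = len(ranked)
    top = ranked.iloc[:k]
    return RankedFeatureList(
        list(top.index),
        top["p"].to_numpy(),
        top["direction"].to_numpy(),
        "WF",
    )


def select_vf(
    matrix: MethylationMatrix,
    phenotype: Phenotype,
    k: int = DEFAULT_K,
    n_variable: int = DEFAULT_POOL,
    statistic: str = "t",
    assoc: pd.DataFrame | None = None,
    p_cut: float = 0.05,
) -> RankedFeatureList:
    """Variance-filtering selection.

    Step I keeps the ``n_variable`` most variable CpGs (variance across all
    training samples, phenotype not consulted; ties by variance then CpG
    ID).  Step II ranks those by supervised p-value and retains
    min(k, number with p < ``p_cut``).

    A precomputed training association table can be passed to avoid
    recomputation; it is subset to the variance-filtered pool.
    """
    variances = matrix.values.var(axis=1, ddof=1)
    if matrix.n_features < n_variable:
        warnings.warn(
            f"only {matrix.n_features} features available for a variance pool of "
            f"{n_variable}; using all"
        )
        n_variable = matrix.n_features
    pool_order = variances.to_frame("var").reset_index(names="cpg").sort_values(
        by=["var", "cpg"], ascending=[False, True], kind="mergesort"
    )
    pool_ids = pool_order["cpg"].iloc[:n_variable]
    pooled = MethylationMatrix(matrix.values.loc[pool_ids], matrix.measure)
    if assoc is None:
        assoc = compute_association(pooled, phenotype, statistic)
    else:
        assoc = assoc.loc[assoc.index.intersection(pool_ids, sort=False)]
    ranked = _rank_by_significance(assoc)
    n_signif = int((ranked["p"] < p_cut).sum())
    n_keep = min(k, n_signif)
    top = ranked.iloc[:n_keep]
    return RankedFeatureList(
        list(top.index),
        top["p"].to_numpy(),
        top["direction"].to_numpy(),
        "VF",
    )


def select_spca(
    matrix: MethylationMatrix,
    phenotype: Phenotype,
    k: int = DEFAULT_K,
    n_top: int = DEFAULT_POOL,
    statistic: str = "t",
    assoc: pd.DataFrame | None = None,
    max_components: int = MAX_SPCA_COMPONENTS,
) -> RankedFeatureList:
    """Supervised-PCA selection.

    The ``n_top`` most significant CpGs are decomposed by SVD (features
    mean-centered across training samples); the component whose sample
    scores have the largest absolute Pearson correlation with the phenotype
    is chosen, and CpGs are ranked by absolute loading on it.  The
    direction of a CpG is sign(loading * correlation), which is invariant
    to the arbitrary sign of the singular vector.
    """
    if matrix.n_samples < 2:
        raise ValueError("SPCA needs at least 2 samples")
    if assoc is None:
        assoc = compute_association(matrix, phenotype, statistic)
    ranked = _rank_by_significance(assoc)
    top_ids = ranked.index[: min(n_top, len(ranked))]
    sub = matrix.values.loc[top_ids].to_numpy()
    centered = sub - sub.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if not np.any(s > 1e-12 * max(1.0, s[0] if s.size else 0.0)):
        raise ValueError("degenerate SVD: centered training matrix has rank 0")
    n_comp = min(matrix.n_samples - 1, max_components, int(np.sum(s > 1e-12 * s[0])))
    y = phenotype.values.to_numpy(dtype=float)
    yc = y - y.mean()
    y_norm = np.linalg.norm(yc)
    corrs = np.zeros(n_comp)
    for c in range(n_comp):
        scores = vt[c]
        sc = scores - scores.mean()
        denom = np.linalg.norm(sc) * y_norm
        corrs[c] = (sc @ yc) / denom if denom > 0 else 0.0
    best = int(np.argmax(np.abs(corrs)))
    loadings = u[:, best]
    frame = pd.DataFrame(
        {"cpg": top_ids, "abs_loading": np.abs(loadings), "loading": loadings}
    ).sort_values(by=["abs_loading", "cpg"], ascending=[False, True], kind="mergesort")
    top = frame.iloc[: min(k, len(frame))]
    direction = np.sign(top["loading"].to_numpy() * corrs[best])
    return RankedFeatureList(
        list(top["cpg"]),
        top["abs_loading"].to_numpy(),
        direction,
        "SPCA",
    )


def select_features(
    method: str,
    matrix: MethylationMatrix,
    phenotype: Phenotype,
    k: int = DEFAULT_K,
    statistic: str = "t",
    assoc: pd.DataFrame | None = None,
) -> RankedFeatureList:
    """Dispatch on method tag ("WF", "VF", "SPCA")."""
    if method == "WF":
        if assoc is None:
            assoc = compute_association(matrix, phenotype, statistic)
        return select_wf(assoc, k)
    if method == "VF":
        return select_vf(matrix, phenotype, k, statistic=statistic, assoc=assoc)
    if method == "SPCA":
        return select_spca(matrix, phenotype, k, statistic=statistic, assoc=assoc)
    raise ValueError(f"unknown selection method {method!r}")
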