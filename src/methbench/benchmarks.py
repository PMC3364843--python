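"""End-to-end benchmark scenarios on synthetic studies.

Each function defines one headline experiment of the comparison framework —
study conditions (feature count, signal strength, effect size, sample
sizes) are fixed here; only the RNG seed varies.  The same functions drive
the acceptance tests and the reproduction script, so reported numbers are
always recomputed from scratch.

Problem sizes mirror typical 27k beadarray studies scaled to desk size:
20,000 CpGs for feature-selection experiments (a quality-controlled 27k
array), 10,000 for the classifier comparison, and diagnostic/age effect
sizes and signal strengths spanning the ranges seen across blood and
epithelial-tissue cohorts (effect ~0.5-0.7 with thousands of associated
CpGs in blood; effect ~2.5 with strong signal in tissue).
"""

from __future__ import annotations

import numpy as np

from .association import fit_variance_prior
from .classify import run_classifier_comparison
from .ppv import compare_ppv, ppv_curve, small_sample_ppv
from .simulate import SimulationConfig, simulate_beta_matrix
from .unsupervised import compare_svd_nmf


def null_ppv_calibration(seed: int = 0, n_partitions: int = 50) -> dict:
    """Mean PPV on a 20,000-CpG no-signal study, n=50 per class.

    The analytic expectation under the true-positive rule (test p < 0.05,
    concordant direction) is 0.05 * 1/2 = 0.025.
    """
    cfg = SimulationConfig(n_features=20_000, n_true=0, n_per_group=50, seed=seed)
    matrix, phenotype, _ = simulate_beta_matrix(cfg)
    pm = ppv_curve(
        matrix, phenotype, method="WF", statistic="t",
        n_partitions=n_partitions, seed=seed + 1,
    )
    return {"mean_ppv": float(pm.values.mean().mean())}


def _measure_study(seed: int):
    cfg = SimulationConfig(
        n_features=10_000, n_true=2_000, target_effect_size=1.5,
        n_per_group=50, seed=seed,
    )
    return simulate_beta_matrix(cfg)


def small_sample_measure_comparison(
    seed: int = 0, n_per_class: int = 2, n_partitions: int = 50
) -> dict:
    """M-value vs beta-value PPV with 2 samples per class and moderated t."""
    matrix, phenotype, _ = _measure_study(seed)
    out = {}
    per_partition = {}
    for measure in ("beta", "M"):
        pm = small_sample_ppv(
            matrix, phenotype, n_per_class=n_per_class, measure=measure,
            n_partitions=n_partitions, seed=seed + 2,
        )
        out[f"mean_ppv_{measure}"] = float(pm.values.mean().mean())
        per_partition[measure] = pm.values.mean(axis=0).to_numpy()
    cmp = compare_ppv(per_partition["M"], per_partition["beta"], alternative="greater")
    out["wilcoxon_p_m_greater"] = cmp.p_value
    return out


def large_sample_measure_comparison(seed: int = 0, n_partitions: int = 50) -> dict:
    """M vs beta PPV at 50/50 partitions with the ordinary t."""
    matrix, phenotype, _ = _measure_study(seed)
    means = {}
    for measure in ("beta", "M"):
        pm = ppv_curve(
            matrix, phenotype, method="WF", measure=measure, statistic="t",
            n_partitions=n_partitions, seed=seed + 3,
        )
        means[measure] = float(pm.values.mean().mean())
    return {
        "mean_ppv_beta": means["beta"],
        "mean_ppv_m": means["M"],
        "abs_difference": abs(means["M"] - means["beta"]),
    }


def selection_method_comparison(
    seed: int = 0, n_partitions: int = 50, size: int = 1000
) -> dict:
    """WF / VF / SPCA at small effect size and large signal strength.

    4,000 of 20,000 CpGs carry a 0.6 effect riding on a shared latent
    factor (cell-composition-like correlated signal); the tri-modal
    baseline puts many truth CpGs near the extremes, where their variance
    is low and the variance filter discards them.
    """
    cfg = SimulationConfig(
        n_features=20_000, n_true=4_000, target_effect_size=0.6,
        n_per_group=50, shared_factor_sd=0.5, seed=seed,
    )
    matrix, phenotype, _ = simulate_beta_matrix(cfg)
    out = {}
    for method in ("WF", "VF", "SPCA"):
        pm = ppv_curve(
            matrix, phenotype, method=method, statistic="t", sizes=[size],
            n_partitions=n_partitions, seed=seed + 4,
        )
        out[f"mean_ppv_{method.lower()}"] = float(pm.values.loc[size].mean())
    return out


def large_effect_selection(seed: int = 0, n_partitions: int = 50, size: int = 200) -> dict:
    """All three selection methods on a strong diagnostic signal
    (effect 2.5, 2,500 of 10,000 CpGs, n=50 per class)."""
    cfg = SimulationConfig(
        n_features=10_000, n_true=2_500, target_effect_size=2.5,
        n_per_group=50, seed=seed,
    )
    matrix, phenotype, _ = simulate_beta_matrix(cfg)
    out = {}
    for method in ("WF", "VF", "SPCA"):
        pm = ppv_curve(
            matrix, phenotype, method=method, statistic="t", sizes=[size],
            n_partitions=n_partitions, seed=seed + 5,
        )
        out[f"mean_ppv_{method.lower()}"] = float(pm.values.loc[size].mean())
    return out


def classifier_benchmark(seed: int = 0, n_partitions: int = 50) -> dict:
    """Median test C-index of SPCA-1/2/3, LASSO, ELNET and SVM on an
    age-like study (effect 0.6 per phenotype SD, 300 of 10,000 CpGs,
    n=150)."""
    cfg = SimulationConfig(
        n_features=10_000, n_per_group=150, phenotype_type="continuous",
        n_true=300, target_effect_size=0.6, seed=seed,
    )
    matrix, phenotype, _ = simulate_beta_matrix(cfg)
    table = run_classifier_comparison(
        matrix, phenotype, n_partitions=n_partitions, seed=seed + 6
    )
    return {f"median_cindex_{m.lower().replace('-', '')}": float(table[m].median())
            for m in table.columns}


def unsupervised_benchmark(seed: int = 0, n_permutations: int = 30) -> dict:
    """Average-best-two phenotype R^2 of NMF vs SVD on a large-effect
    diagnostic study."""
    cfg = SimulationConfig(
        n_features=2_000, n_true=500, target_effect_size=2.5,
        n_per_group=50, seed=seed,
    )
    matrix, phenotype, _ = simulate_beta_matrix(cfg)
    res = compare_svd_nmf(matrix, phenotype, n_permutations=n_permutations, seed=seed + 7)
    return {
        "k": int(res["k"]),
        "svd_best_two_r2": float(res["svd_r2"].best_two_mean),
        "nmf_best_two_r2": float(res["nmf_r2"].best_two_mean),
    }


def variance_prior_recovery(
    seed: int = 0, d0: float = 4.0, s0_squared: float = 0.01,
    residual_df: int = 10, n_features: int = 50_000,
) -> dict:
    """Recover a known scaled-inverse-chi-square variance prior from
    simulated per-feature variances."""
    rng = np.random.default_rng(seed)
    sigma2 = d0 * s0_squared / rng.chisquare(d0, n_features)
    s2 = sigma2 * rng.chisquare(residual_df, n_features) / residual_df
    prior = fit_variance_prior(s2, residual_df)
    return {
        "true_d0": d0,
        "true_s0_squared": s0_squared,
        "recovered_d0": float(prior.d0),
        "recovered_s0_squared": float(prior.s0_squared),
    }
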