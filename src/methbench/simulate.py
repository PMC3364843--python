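"""Synthetic Infinium-style methylation data.

The generator emulates the statistical structure that the downstream
benchmarks assume of real beadarray data:

* beta values strictly inside (0, 1), drawn from per-entry beta
  distributions with a shared concentration ("precision"), so the variance
  is automatically maximal for CpGs whose mean is near 0.5 and suppressed
  near the extremes (the severe heteroscedasticity of the beta scale);
* a tri-modal baseline landscape of unmethylated, hemi-methylated and
  methylated CpGs, modelled as a Gaussian mixture on the log2-logit (M)
  scale;
* a configurable number of truly phenotype-associated CpGs ("signal
  strength") at a configurable effect size ("signal-to-noise ratio"),
  injected on the logit scale and calibrated so that the *beta-scale*
  pooled-SD effect size matches the requested target;
* a shared phenotype-linked latent factor carrying the associated signal:
  all truth CpGs track one continuous sample-level score (the phenotype
  plus within-group variation), the way cell-type composition or a shared
  biological programme drives many CpGs jointly in real tissue; its
  within-group spread is set by ``shared_factor_sd`` (the default 0 gives
  conditionally independent truth CpGs);
* optionally, raw methylated/unmethylated intensity pairs whose totals are
  lognormal with median >= 1,000, plus additive fluorescence noise.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import IntensityPair, MethylationMatrix, Phenotype, SyntheticTruth

#: clamp keeping per-entry beta *means* away from the boundary
MEAN_CLAMP = 1e-3
#: clamp keeping emitted beta *values* strictly inside (0, 1)
VALUE_CLAMP = 1e-9


def _expit2(x):
    """Inverse of the base-2 logit: 2^x / (2^x + 1)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-x[pos]))
    out[~pos] = np.exp2(x[~pos]) / (1.0 + np.exp2(x[~pos]))
    return out


def _logit2(p):
    p = np.asarray(p, dtype=float)
    return np.log2(p / (1.0 - p))


@dataclass
class BaselineMixture:
    """Gaussian mixture on the log2-logit scale describing the baseline
    (phenotype-independent) methylation landscape.

    The default mirrors the tri-modal Infinium landscape: 45% unmethylated
    CpGs centred at logit -3, 45% methylated at +3, 10% hemi-methylated at
    0, all with SD 0.5 on the logit scale.
    """

    weights: tuple = (0.45, 0.10, 0.45)
    logit_means: tuple = (-3.0, 0.0, 3.0)
    logit_sd: float = 0.5

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.logit_means):
            raise ValueError("weights and logit_means must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic methylation study.

    Parameters
    ----------
    n_features
        Number of CpGs.
    n_per_group
        Samples per phenotype class (binary) or total samples (continuous).
    phenotype_type
        ``"binary"`` (cancer/normal-like) or ``"continuous"`` (age-like).
    n_true
        Number of truly associated CpGs (the signal strength).
    target_effect_size
        Binary: target pooled-SD standardised mean difference (Cohen's d) on
        the beta scale.  Continuous: the standardised regression effect —
        methylation shift per phenotype SD, in units of the CpG's own noise
        SD (the regression analogue of Cohen's d, dimensionless and
        age-range-independent; the per-CpG methylation-phenotype
        correlation is effect/sqrt(1+effect^2)).
    precision
        Beta-distribution concentration; per-entry variance is
        mean*(1-mean)/(precision+1), so larger is less noisy.
    shared_factor_sd
        Within-group SD of the phenotype-linked latent factor carried by
        all truth CpGs, in units of the between-group separation (binary)
        or of one phenotype SD (continuous).  Models correlated signal
        structure (cell-composition-like); 0 switches it off.
    baseline_mixture
        Baseline landscape, see :class:`BaselineMixture`.
    continuous_range
        (low, high) of the uniform continuous phenotype; the default spans
        typical adult age ranges.
    seed
        RNG seed; identical configs with identical seeds give identical
        output.
    intensity_mode / intensity_median / intensity_sigma / intensity_noise_sd
        Lognormal total-intensity model for :func:`simulate_intensities`.
    """

    n_features: int = 10_000
    n_per_group: int = 50
    phenotype_type: str = "binary"
    n_true: int = 500
    target_effect_size: float = 1.0
    precision: float = 50.0
    shared_factor_sd: float = 0.0
    baseline_mixture: BaselineMixture = field(default_factory=BaselineMixture)
    continuous_range: tuple = (25.0, 90.0)
    seed: int = 0
    intensity_mode: bool = False
    intensity_median: float = 10_000.0
    intensity_sigma: float = 0.6
    intensity_noise_sd: float = 100.0

    def __post_init__(self) -> None:
        if self.n_true > self.n_features:
            raise ValueError("n_true must not exceed n_features")
        if self.target_effect_size < 0:
            raise ValueError("target_effect_size must be non-negative")
        if self.precision <= 2:
            raise ValueError("precision must exceed 2")
        if self.phenotype_type not in ("binary", "continuous"):
            raise ValueError("phenotype_type must be 'binary' or 'continuous'")
        if self.shared_factor_sd < 0:
            raise ValueError("shared_factor_sd must be non-negative")


class EffectCalibrationError(ValueError):
    """Requested effect size not attainable within (0, 1) for some CpGs."""


_LN2 = np.log(2.0)
# Gauss-Hermite nodes/weights for integrating over the latent-factor noise
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(21)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _group_beta_moments(logit_center, precision, logit_sd):
    """Mean and variance of a beta draw whose logit-scale mean is Gaussian.

    x | l ~ Beta(mean=expit2(l), concentration=precision) with
    l ~ N(logit_center, logit_sd^2); moments by Gauss-Hermite quadrature:

        E[x]   = E_l[mu(l)]
        Var[x] = E_l[mu(1-mu)]/(precision+1) + Var_l[mu(l)].
    """
    lc = np.asarray(logit_center, dtype=float)[..., None]
    sd = np.asarray(logit_sd, dtype=float)[..., None]
    mu = _expit2(lc + sd * _GH_NODES)
    e = np.sum(_GH_WEIGHTS * mu, axis=-1)
    e2 = np.sum(_GH_WEIGHTS * mu * mu, axis=-1)
    v_between = np.maximum(e2 - e * e, 0.0)
    v_within = np.sum(_GH_WEIGHTS * mu * (1.0 - mu), axis=-1) / (precision + 1.0)
    return e, v_within + v_between


def _analytic_cohens_d(logit_mean, delta, precision, factor_sd=0.0):
    """Beta-scale Cohen's d of a symmetric +/- delta/2 logit shift, with the
    shared latent factor contributing logit-scale noise of SD
    delta*factor_sd within each group."""
    factor_sd = np.asarray(factor_sd, dtype=float)
    noise_sd = np.broadcast_to(delta * factor_sd, np.broadcast_shapes(
        np.shape(logit_mean), np.shape(delta), factor_sd.shape
    ))
    lm = np.broadcast_to(np.asarray(logit_mean, dtype=float), noise_sd.shape)
    dd = np.broadcast_to(np.asarray(delta, dtype=float), noise_sd.shape)
    e0, v0 = _group_beta_moments(lm - dd / 2.0, precision, noise_sd)
    e1, v1 = _group_beta_moments(lm + dd / 2.0, precision, noise_sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (e1 - e0) / np.sqrt((v0 + v1) / 2.0)
    return np.where(np.asarray(dd) > 0, d, 0.0)


def _best_on_delta_grid(logit_means, tau, precision, delta_max, n_grid: int = 64):
    """Max analytic d (and its delta) over a grid of shifts per CpG."""
    frac = np.linspace(0.0, 1.0, n_grid)[None, :]
    deltas = delta_max[:, None] * frac
    tau_col = np.asarray(tau, dtype=float)
    if tau_col.ndim:
        tau_col = tau_col[:, None]
    d = _analytic_cohens_d(logit_means[:, None], deltas, precision, tau_col)
    best = np.argmax(d, axis=1)
    rows = np.arange(logit_means.size)
    return d[rows, best], deltas[rows, best]


def _calibrate_logit_shift(logit_means, target, precision, factor_sd=0.0, n_iter: int = 50):
    """Per-CpG logit shift (and shared-factor loading) matching the target
    beta-scale Cohen's d; vectorised bisection.

    The shared factor adds within-group variance proportional to the shift,
    which caps the attainable effect size of mid-range CpGs.  CpGs whose
    target exceeds that cap carry a reduced factor loading (the largest
    attainable), so large effects become progressively CpG-autonomous.

    Returns
    -------
    (delta, tau) : per-CpG logit shift and factor loading.
    """
    logit_means = np.asarray(logit_means, dtype=float)
    tau = np.full(logit_means.shape, float(factor_sd))
    if target == 0 or logit_means.size == 0:
        return np.zeros_like(logit_means), tau
    lo_bound = _logit2(MEAN_CLAMP)
    hi_bound = _logit2(1.0 - MEAN_CLAMP)
    delta_max = np.maximum(
        2.0 * np.minimum(logit_means - lo_bound, hi_bound - logit_means), 0.0
    )
    margin = 1.02 * target  # keep the crossing off the very top of the curve
    d_best, delta_best = _best_on_delta_grid(logit_means, tau, precision, delta_max)
    bad = d_best < margin
    if np.any(bad):
        d0_best, _ = _best_on_delta_grid(
            logit_means[bad], np.zeros(int(bad.sum())), precision, delta_max[bad]
        )
        hopeless = d0_best < target
        if np.any(hopeless):
            idx = int(np.argmax(hopeless))
            raise EffectCalibrationError(
                f"effect size {target} unattainable for CpG with baseline logit "
                f"mean {logit_means[bad][idx]:.3f} (max attainable "
                f"{d0_best[idx]:.3f}) at precision {precision}"
            )
        lo_t = np.zeros(int(bad.sum()))
        hi_t = tau[bad]
        for _ in range(30):
            mid_t = (lo_t + hi_t) / 2.0
            d_mid, _ = _best_on_delta_grid(logit_means[bad], mid_t, precision, delta_max[bad])
            ok = d_mid >= margin
            lo_t = np.where(ok, mid_t, lo_t)
            hi_t = np.where(ok, hi_t, mid_t)
        tau[bad] = lo_t
        d_best, delta_best = _best_on_delta_grid(logit_means, tau, precision, delta_max)
    # bisect delta on [0, argmax]: d is 0 at delta=0 and >= target at the top
    lo = np.zeros_like(logit_means)
    hi = delta_best
    for _ in range(n_iter):
        mid = (lo + hi) / 2.0
        too_small = _analytic_cohens_d(logit_means, mid, precision, tau) < target
        lo = np.where(too_small, mid, lo)
        hi = np.where(too_small, hi, mid)
    return (lo + hi) / 2.0, tau


def _draw_phenotype(config: SimulationConfig, rng: np.random.Generator) -> Phenotype:
    if config.phenotype_type == "binary":
        n = 2 * config.n_per_group
        sample_ids = pd.Index([f"S{i:04d}" for i in range(n)])
        values = pd.Series(np.repeat([0, 1], config.n_per_group), index=sample_ids)
        return Phenotype(values, "binary")
    n = config.n_per_group
    sample_ids = pd.Index([f"S{i:04d}" for i in range(n)])
    lo, hi = config.continuous_range
    values = pd.Series(rng.uniform(lo, hi, size=n), index=sample_ids)
    return Phenotype(values, "continuous")


def simulate_beta_matrix(config: SimulationConfig):
    """Generate a beta-valued CpG x sample matrix with ground truth.

    Returns
    -------
    (MethylationMatrix, Phenotype, SyntheticTruth)
    """
    rng = np.random.default_rng(config.seed)
    mix = config.baseline_mixture

    component = rng.choice(len(mix.weights), size=config.n_features, p=list(mix.weights))
    baseline_logit = np.asarray(mix.logit_means)[component] + rng.normal(
        0.0, mix.logit_sd, size=config.n_features
    )
    lo_b, hi_b = _logit2(MEAN_CLAMP), _logit2(1.0 - MEAN_CLAMP)
    baseline_logit = np.clip(baseline_logit, lo_b, hi_b)

    phenotype = _draw_phenotype(config, rng)
    n_samples = len(phenotype.sample_ids)

    truth_idx = rng.choice(config.n_features, size=config.n_true, replace=False)
    truth_idx.sort()
    signs = rng.choice([-1.0, 1.0], size=config.n_true)

    # per-CpG, per-sample mean on the logit scale; all truth CpGs track one
    # shared sample-level factor (phenotype plus within-group variation)
    logit_mean = np.tile(baseline_logit[:, None], (1, n_samples))
    tau = config.shared_factor_sd
    if config.phenotype_type == "binary":
        delta, tau_g = _calibrate_logit_shift(
            baseline_logit[truth_idx],
            config.target_effect_size,
            config.precision,
            tau,
        )
        y = phenotype.values.to_numpy(dtype=float)  # 0/1
        eps = np.zeros(n_samples)
        if tau > 0:
            eps = rng.standard_normal(n_samples)
            # standardise within each class so the factor has exactly unit
            # group separation and within-group SD tau
            for cls in (0, 1):
                mask = y == cls
                if mask.sum() >= 2 and eps[mask].std() > 0:
                    eps[mask] = (eps[mask] - eps[mask].mean()) / eps[mask].std()
        shift = signs[:, None] * delta[:, None] * (
            (y - 0.5)[None, :] + tau_g[:, None] * eps[None, :]
        )
        logit_mean[truth_idx, :] += shift
    else:
        x = phenotype.values.to_numpy(dtype=float)
        x_std = (x - x.mean()) / x.std(ddof=0) if x.std(ddof=0) > 0 else np.zeros_like(x)
        factor = x_std
        if tau > 0:
            eps = rng.standard_normal(n_samples)
            if n_samples >= 3 and x_std.std() > 0:
                eps = eps - (eps @ x_std) / (x_std @ x_std) * x_std
                if eps.std() > 0:
                    eps = (eps - eps.mean()) / eps.std()
            factor = factor + tau * eps
        # standardised effect: logit slope per phenotype SD scaled to each
        # CpG's own logit-scale noise SD (delta method on the beta noise),
        # so the methylation-phenotype correlation is the same for every
        # truth CpG regardless of its baseline level
        m_base = _expit2(baseline_logit[truth_idx])
        noise_sd_logit = 1.0 / (
            _LN2 * np.sqrt(m_base * (1.0 - m_base) * (config.precision + 1.0))
        )
        slope = signs * config.target_effect_size * noise_sd_logit
        logit_mean[truth_idx, :] += slope[:, None] * factor[None, :]

    mean = np.clip(_expit2(logit_mean), MEAN_CLAMP, 1.0 - MEAN_CLAMP)
    a = mean * config.precision
    b = (1.0 - mean) * config.precision
    values = rng.beta(a, b)
    values = np.clip(values, VALUE_CLAMP, 1.0 - VALUE_CLAMP)

    feature_ids = pd.Index([f"cg{i:07d}" for i in range(config.n_features)])
    matrix = MethylationMatrix(
        pd.DataFrame(values, index=feature_ids, columns=phenotype.sample_ids), "beta"
    )
    if config.phenotype_type == "binary":
        effects = signs * config.target_effect_size
    else:
        effects = signs * config.target_effect_size
    truth = SyntheticTruth(pd.Series(effects, index=feature_ids[truth_idx]))
    return matrix, phenotype, truth


def simulate_intensities(config: SimulationConfig):
    """Generate paired methy/unmethy intensities on top of the beta model.

    Total intensity per entry is lognormal with median
    ``config.intensity_median``; the methylated share is the underlying
    beta-scale value; additive Gaussian fluorescence noise may push
    individual intensities negative (quantification clamps them).

    Returns
    -------
    (IntensityPair, Phenotype, SyntheticTruth)
    """
    if not config.intensity_mode:
        raise ValueError("intensity_mode must be enabled in the config")
    matrix, phenotype, truth = simulate_beta_matrix(config)
    p = matrix.values.to_numpy()
    rng = np.random.default_rng([config.seed, 7919])
    total = rng.lognormal(np.log(config.intensity_median), config.intensity_sigma, size=p.shape)
    noise_m = rng.normal(0.0, config.intensity_noise_sd, size=p.shape) if config.intensity_noise_sd > 0 else 0.0
    noise_u = rng.normal(0.0, config.intensity_noise_sd, size=p.shape) if config.intensity_noise_sd > 0 else 0.0
    methy = total * p + noise_m
    unmethy = total * (1.0 - p) + noise_u
    pair = IntensityPair(
        pd.DataFrame(methy, index=matrix.feature_ids, columns=matrix.sample_ids),
        pd.DataFrame(unmethy, index=matrix.feature_ids, columns=matrix.sample_ids),
    )
    return pair, phenotype, truth


def realized_effect_sizes(matrix: MethylationMatrix, phenotype: Phenotype) -> pd.Series:
    """Per-CpG pooled-SD standardised mean difference (Cohen's d).

    d = (mean1 - mean0) / s_pooled with the standard pooled-variance
    formula.  A CpG with zero pooled SD is reported as 0 when the group
    means also agree, otherwise as signed infinity.
    """
    if phenotype.kind != "binary":
        raise ValueError("realized_effect_sizes requires a binary phenotype")
    values = matrix.values.loc[:, phenotype.sample_ids].to_numpy()
    y = phenotype.values.to_numpy()
    g0 = values[:, y == 0]
    g1 = values[:, y == 1]
    n0, n1 = g0.shape[1], g1.shape[1]
    if n0 < 2 or n1 < 2:
        raise ValueError("each class needs at least 2 samples")
    diff = g1.mean(axis=1) - g0.mean(axis=1)
    s0 = g0.var(axis=1, ddof=1)
    s1 = g1.var(axis=1, ddof=1)
    pooled = np.sqrt(((n0 - 1) * s0 + (n1 - 1) * s1) / (n0 + n1 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / pooled
    d = np.where(pooled == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), d)
    return pd.Series(d, index=matrix.feature_ids, name="effect_size")
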