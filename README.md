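# methbench

Benchmarking feature selection, classification and dimensional reduction
for Illumina Infinium-style DNA-methylation data.

## The problem

Infinium beadarrays report the methylation state of tens of thousands of
CpGs per sample. Two quantification measures are in common use: the
**β-value**

```
β = max(methy, 0) / (max(methy, 0) + max(unmethy, 0) + 100)
```

— the methylated fraction of the total fluorescence, bounded in (0, 1) and
biologically interpretable but severely heteroscedastic (variance maximal
near β = 0.5, suppressed near 0 and 1) — and the **M-value**

```
M = log2( (max(methy, 0) + 1) / (max(unmethy, 0) + 1) )  ≈  log2(β / (1 − β))
```

which is approximately homoscedastic but unbounded. Whether to analyse β or
M, whether to filter CpGs by variance before testing, and which classifier
to use for phenotype prediction are practical decisions every methylation
study faces. `methbench` implements a complete evaluation framework for
these choices and exercises it end-to-end on a synthetic data generator
with controllable effect size ("signal-to-noise ratio") and number of
associated CpGs ("signal strength"), so every comparison is testable
without downloading cohort data.

## What is implemented

* **Quantification** — β/M computation from intensity pairs and the exact
  logistic conversion between the measures.
* **Association statistics** — pooled-variance two-sample t (binary
  phenotypes), simple-regression slope t (continuous phenotypes), an
  empirical-Bayes **moderated t** whose per-CpG variance is shrunk toward a
  prior (d₀, s₀²) fitted by the method of moments on log s² (with a
  numerically inverted trigamma), and Storey **q-values**.
* **Feature selection** — three procedures: WF (rank everything by
  p-value), VF (restrict to the 5,000 most variable CpGs first), and SPCA
  (SVD of the 5,000 most significant CpGs, rank by loading on the
  component most correlated with the phenotype).
* **PPV evaluation** — 50 balanced train/test partitions; a
  training-selected CpG is a *true positive* when it reaches p < 0.05 in
  the matched test half with the same direction of change; PPV is the
  true-positive fraction of each evaluation set (top 50, 100, …, 1500),
  compared between methods/measures by Wilcoxon rank-sum tests.
* **Classification** — SPCA regression with 1–3 components (feature count
  tuned by internal 10-fold CV), LASSO and Elastic Net (α = 0.05, λ tuned
  by internal 10-fold CV over a 100-point path), and ε-insensitive RBF
  SVM regression (γ = 3, ε = 0.1, fixed), all scored by the concordance
  (C-) index on held-out samples.
* **Unsupervised modelling** — SVD vs NNDSVD-initialised Brunet NMF
  (multiplicative Kullback–Leibler updates, deterministic), component
  count estimated by entry-permutation, both scored by the average R² of
  the two components most associated with the phenotype.
* **Synthetic generator** — beta-distributed CpG × sample matrices with a
  tri-modal baseline and mean-dependent variance, calibrated so the
  realized beta-scale effect size of truth CpGs matches a target, with an
  optional shared latent factor carrying correlated (cell-composition-like)
  signal, plus a raw-intensity mode.

## Worked example

```python
import methbench as mb

cfg = mb.SimulationConfig(
    n_features=10_000, n_true=2_500, target_effect_size=2.5,
    n_per_group=50, seed=15,
)
matrix, phenotype, truth = mb.simulate_beta_matrix(cfg)

ppv = mb.ppv_curve(matrix, phenotype, method="WF", statistic="t",
                   sizes=[200], n_partitions=50, seed=35)
print(f"mean PPV at size 200: {ppv.values.loc[200].mean():.3f}")
```

prints

```
mean PPV at size 200: 1.000
```

— with 2,500 CpGs carrying a large (d = 2.5) diagnostic effect, every one
of the top 200 training-ranked CpGs cross-validates in the test half. The
same pipeline on a no-signal simulation gives a mean PPV of ≈ 0.025, the
analytic false-positive rate of the rule (p < 0.05 two-sided, halved by
the direction-concordance requirement).

A shell interface covers the same pipelines
(`methbench simulate|ppv|classify|decompose <config.yaml>`).

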