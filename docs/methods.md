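# Methods

## The synthetic methylation model

Every benchmark runs on data from the package's own generator, which
emulates the statistical structure of Infinium 27k-style beta-valued
matrices.

**Baseline landscape.** Each CpG draws a baseline mean from a tri-modal
Gaussian mixture on the log2-logit (M) scale: 45% unmethylated CpGs at
logit −3, 45% methylated at +3, 10% hemi-methylated at 0, SD 0.5. This
mirrors the bimodal-with-shoulder histogram of real promoter arrays and,
after the logistic map, concentrates baseline means near 0.1 / 0.9 / 0.5
on the beta scale.

**Noise.** Sample values are drawn from per-entry beta distributions with
a shared concentration ν (`precision`, default 50), so the variance is
mean(1−mean)/(ν+1): maximal for hemi-methylated CpGs and suppressed at the
extremes. This reproduces the severe heteroscedasticity of beta values by
construction; after the logit transform the data are approximately
homoscedastic. The beta-distribution choice itself is a modelling
stand-in: real array noise is not literally beta, but the mean–variance
relationship — the feature the benchmarks depend on — is faithful.
Precision 50 gives per-CpG SDs of ~0.03–0.07, in the range of replicate
variation on real arrays.

**Signal.** `n_true` CpGs are associated with the phenotype at a target
effect size, injected on the logit scale so values stay in (0, 1):

* *Binary phenotypes*: the two group means are separated by a symmetric
  logit shift δ, calibrated per CpG by bisection (≤50 iterations) so the
  analytic beta-scale Cohen's d — computed by Gauss–Hermite quadrature
  over all noise sources — equals the target. Unattainable targets (the
  shift would push a mean outside (0.001, 0.999)) raise a calibration
  error naming the offending CpG. Realized median effects verify within
  ±15% of targets in [0.5, 3.5] at n ≥ 50 per group.
* *Continuous phenotypes*: the logit mean follows
  intercept + slope·(phenotype − mean)/SD, with the slope scaled to the
  CpG's own noise SD so `target_effect_size` is the *standardised
  regression effect* (the regression analogue of Cohen's d). The per-CpG
  methylation–phenotype correlation is then effect/√(1+effect²) —
  about 0.51 at effect 0.6 — independent of the CpG's baseline level.
  The phenotype is uniform on [25, 90], an adult age range.

**Correlated signal (optional).** Real phenotype-associated methylation is
not conditionally independent across CpGs: shared drivers such as
cell-type composition move many CpGs together. With
`shared_factor_sd = τ > 0` all truth CpGs track one continuous
sample-level factor (the phenotype plus within-group variation of SD τ,
standardised within groups so effect calibration stays exact). CpGs whose
target effect exceeds the noise cap this factor imposes carry an
adaptively reduced factor loading — large effects become progressively
CpG-autonomous, as focal events are in tumours. The default is τ = 0
(independent truth CpGs); the variance-filtering/SPCA benchmark enables
τ = 0.5, because correlated signal is precisely the data feature that
supervised principal components exploits.

**What the generator does not model:** probe-level batch and beadchip
position effects, detection failures, type-I/type-II probe-design
differences, or non-beta noise tails. Passing benchmarks therefore speak
to the statistical behaviour of the methods under heteroscedastic bounded
noise with (optionally) correlated signal, not to robustness against
technical artefacts.

## Association statistics

The two-sample t uses the pooled variance (Welch is available via an
explicit flag but off by default, since the moderated-t framework reduces
to the pooled t at d₀ = 0 and the two should nest exactly). Zero-variance
CpGs cannot be ranked: their statistic is NaN and they are excluded from
q-value computation and prior fitting.

The variance prior (d₀, s₀²) is fitted by the method of moments on
z = log s²: the sampling contribution ψ′(d/2) is subtracted from var(z)
and the remainder inverted through the trigamma function (monotone
bisection to 1e−10). A non-positive remainder means the spread of the
variances is entirely sampling noise, giving d₀ = ∞; p-values then use a
df cap of 10⁶. The moderated t shrinks each variance to
(d₀s₀² + d·s²)/(d₀ + d) and gains d₀ degrees of freedom.

q-values use the fixed-λ = 0.5 estimator π̂₀ = #{p > λ}/(m(1−λ)), capped
into (0, 1] — deterministic and robust at small m; with π₀ = 1 the
procedure is exactly Benjamini–Hochberg, which the tests verify against an
independent implementation.

## Feature selection and PPV evaluation

Ties in every ranking are broken by larger |statistic|, then lexicographic
CpG ID, making all selections fully deterministic. VF computes variances
across all training samples without looking at the phenotype. SPCA centers
features (no variance scaling) before the SVD, examines up to
min(n−1, 30) components, and defines a CpG's direction as
sign(loading × component–phenotype correlation), which absorbs the
arbitrary sign of singular vectors.

Partitions are stratified 50/50 splits — by class for binary phenotypes,
by quartile bin for continuous ones — with at most one surplus sample per
stratum dropped (randomly, per partition) to keep training and test sets
exactly equal-sized, so p-values are comparable between the halves. The
small-sample regime instead draws disjoint 2–3-per-class subsets and
forces the moderated t. Method and measure comparisons use the unpaired
Wilcoxon rank-sum test by default; a paired signed-rank option exists
because partitions are shared between arms, but the unpaired test is the
reported one.

Under pure noise the expected PPV is 0.05 × ½ = 0.025 (two-sided test-set
screen times direction concordance); this analytic value is the
calibration anchor for the whole engine.

Evaluation-set sizes can be harmonised across studies by minimising the
between-study variance of mean PPV over the size grid (exhaustive search
when the grid product is tractable, coordinate descent otherwise; ties go
to smaller sizes).

## Classifiers

All four predictor families operate on the 5,000 most variable training
CpGs (configurable) and emit a continuous score evaluated by the C-index
(pairs with distinct phenotype values; prediction ties count ½).

* **SPCA-k**: univariate regression ranking, a feature-count threshold on
  a log-spaced grid (10…5000, 8 points) tuned by phenotype-stratified
  10-fold CV (the ranking is recomputed inside each fold), SVD of the
  centered submatrix, least-squares regression on the leading k component
  scores. The three component counts share the per-fold SVDs for speed.
* **LASSO / ELNET**: glmnet-style objective
  (1/2n)‖y − β₀ − Xβ‖² + λ[(1−α)‖β‖²/2 + α‖β‖₁] on standardized
  features, solved by scikit-learn coordinate descent along a 100-point
  log-spaced path from λ_max = max|xᵀy|/(nα) down to 10⁻³λ_max; λ chosen
  by 10-fold CV mean squared error. α = 1 is the LASSO; the Elastic Net
  runs at α = 0.05. The default coordinate-descent tolerance is 1e−3
  (the CV criterion is insensitive to tighter tolerances; the KKT tests
  use 1e−9).
* **SVM regression**: ε-insensitive RBF SVR with γ = 3, ε = 0.1 and cost
  C = 1 (the conventional default; the method comparison fixes rather
  than tunes these). γ is applied to the **mean** squared difference over
  standardized features — i.e. the kernel coefficient is γ/p — so the
  stated γ keeps the same meaning whether the kernel sees one CpG or
  5,000. With γ applied to the raw sum, the kernel matrix degenerates to
  the identity in high dimensions and the predictor collapses to a
  constant.

## Unsupervised comparison

NMF runs on beta values only (non-negativity is what justifies it) with
the Brunet multiplicative updates for generalised Kullback–Leibler
divergence, stopping at relative objective change < 1e−6 or 2,000
iterations, with the objective trace recorded (and asserted
non-increasing). Initialisation is non-negative double SVD; the
`nndsvd_init` primitive emits the canonical zeros construction, and
`nmf_brunet` fills those zeros with the matrix mean before iterating —
exact zeros are absorbing under multiplicative updates and lock the
factorisation into the initial sparsity pattern, while the mean fill is
equally deterministic, so repeated runs remain bit-identical and the
comparison with SVD stays fair.

The shared component count comes from comparing observed singular values
with those of matrices whose entries are jointly permuted (destroying all
covariance, keeping the marginal distribution): k is the number of leading
observed values above the 0.95 quantile of their rank-matched permuted
counterparts, over 50 permutations by default (both numbers are package
choices; the estimate is insensitive to the permutation count beyond a few
dozen). k = 0 falls back to 2 with a warning. Each component is scored by
the R² of a simple linear regression against the phenotype (symmetric in
which variable is the regressor), summarised as the mean of the two best
components.

Why NMF wins on diagnostic signal: SVD components are orthogonal, so once
one component captures the cancer/normal axis the next must be
uncorrelated with it and contributes ~0 R², capping the best-two average
near R²₁/2. NMF's parts-based factors are not orthogonal — a
"normal-like" and a "cancer-like" metagene can both track the phenotype —
so both of its best components carry signal.

## Benchmark problem sizes

The benchmark scenarios (module `methbench.benchmarks`) use 20,000 CpGs
for the feature-selection experiments, 10,000 for the measure and
classifier comparisons, 2,000 for the factorisation comparison, and 50
train/test partitions throughout — desk-scale versions of 27k-array
cohorts chosen so the full suite completes in minutes while keeping
partition-level summaries stable.

## Known limitations

* The generator's independence default understates the correlation
  structure of real arrays; conclusions about SPCA and NMF depend on the
  shared-factor scenarios.
* The moderated t assumes the scaled-inverse-χ² variance hierarchy on
  whichever measure it is given; its relative behaviour on β vs M is an
  empirical finding of the benchmarks, not a theorem.
* Multi-covariate adjustment (batch, bisulfite-conversion efficiency) is
  out of scope; real-data use should normalise upstream.
* `small_sample_ppv` requires the source study to be large enough to cut
  disjoint train/test subsets per class.
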