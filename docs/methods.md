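# Methods

## Model and pipeline

The package analyses associations between peripheral-blood DNA methylation
(EPIC-style beta values in (0,1)) and three transformed CSF biomarkers in a
two-stage design.

**Biomarker transform.** Raw A\*/T\*/N\* are positive and right-skewed;
T\* and N\* are nearly collinear. Each is log-transformed and standardized
(sample SD, n−1 denominator); A is the standardized log amyloid, while the
tau pair is re-expressed as its mean M and difference D. Because both
scaled terms have unit variance, cov(M, D) = ½(var − var) = 0 exactly
in-sample; tests assert |corr(M, D)| < 1e−10. D retains the contrast
between phospho- and total tau with a much smaller variance than A or M —
downstream fits deliberately do **not** re-scale the phenotypes, so
penalties act on this natural scale.

**Stage 1.** Per probe, OLS of the M-value (natural-log logit of beta,
clipped at eps = 1e−6 to avoid infinities) on intercept, years of
education, age, epigenetic age acceleration (epigenetic minus chronological
age; an input, not estimated here), sex (0/1), and the first three PCs of
the 7 blood cell-type proportions. Residuals are standardized per probe
(mean 0, sample SD 1) so every stage-2 coefficient reads as the effect of a
1-SD change in residual methylation. Probes whose M-values are numerically
in the covariate span (residual SD < 1e−12) are dropped with a warning.
Complete cases are required; a rank-deficient design raises an error naming
the collinear columns.

**Univariate arm.** Per probe and phenotype, OLS of the phenotype on the
probe residual, two diagnosis indicators (MCI, AD vs CN) and the APOE4
allele count, computed via Frisch–Waugh partialling (statistically
identical to the full design, one matrix residualization for all probes).
The t statistic is mapped through its p-value to a z score. Bias and
inflation of the z's are estimated by a three-component Gaussian mixture
fitted by EM: a dominant central null component plus two tail components
for true associations. Initialization: central at (median, 1.4826·MAD) with
weight 0.9, tails at ±3 SD with doubled SD and weight 0.05 each;
convergence at relative log-likelihood change < 1e−8, max 2000 iterations.
Two identifiability constraints are enforced: tail means are pinned at
least 3 central-SDs below/above the central mean, and the central component
must keep the largest weight. The separation constraint matters: with
(near-)null inputs the unconstrained three-component likelihood is flat and
EM lets a tail component slide into the bulk, distorting the null mean and
SD; pinning the tails is the EM analogue of the informative priors used by
the original Gibbs-sampling implementation of this correction. Residual
uncertainty of the estimated bias at n = 10,000 is ≈ 0.015 (1 SE); this is
estimator noise, not bias. z_adj = (z − bias)/inflation; two-sided normal
p-values; significance at p_adj < 3.6e−8/3 (genome-wide) and < 1e−5/3
(suggestive). The genomic inflation factor is median(z²)/0.4549364
(median of χ²₁), reported before and after correction.

**Gene clusters.** A probe joins a gene's cluster when its position lies in
[start − 100 kb, end + 100 kb) — 0-based, half-open, closed on the left
(BED convention; the boundary convention is a documented choice, not an
inference). Probes may join several clusters. Clusters above 300 probes are
split into k = ceil(size/300) consecutive parts with sizes differing by at
most one; the balanced split avoids tiny trailing parts, which a greedy
300/300/… split would create.

**Multivariate arm.** Per cluster, with Y (n×3), unpenalized design W
(intercept, diagnosis coding, APOE4) and standardized residuals X (n×m):

    f(Γ_w, Γ₃, Θ) = (1/n) tr[(Y − WΓ_w − XΓ₃ᵀ)ᵀ(Y − WΓ_w − XΓ₃ᵀ) Θ]
                    − log det Θ + λ‖Γ₃‖₁ + ρ‖Θ‖₁,offdiag.

The trace is n-normalized so the likelihood term is sample-size invariant
and the penalty scales are comparable across clusters. Only the probe block
Γ₃ is L1-penalized (probes, not covariates, are selected); only
off-diagonal Θ entries are penalized (keeps Θ positive definite, matching
graphical-lasso convention). The solver alternates:

* **Θ-step** — graphical lasso on the current residual covariance S with
  penalty ρ (scikit-learn implementation; at ρ = 0, direct inversion, with
  an error if S is singular);
* **Γ-step** — cyclic coordinate descent with exact soft-threshold updates
  (numba-compiled); the update for entry (j,k) is
  soft(b* , nλ/(2 G_jj Θ_kk)) with G = ZᵀZ and b* the unpenalized
  coordinate minimizer; unpenalized rows skip the threshold.

The Θ-step runs first (with Γ₃ = 0 and Γ_w from OLS this reproduces the
covariates-only precision, making the λ_max bound below exact); iterations
stop when the relative objective change falls below `tol` (default 1e−4;
validation tests use 1e−10). The objective is monotone nonincreasing by
construction and asserted per iteration. Non-convergence at `max_outer`
returns the best iterate flagged.

**Penalty grids and tuning.** λ_max = (2/n)·max|Xᵀ R Θ₀| (KKT bound at the
covariates-only solution; the factor 2 follows from the n-normalized
objective) and ρ_max = max off-diagonal |S|; both grids are log-spaced over
[0.01·max, max], traversed in decreasing order with warm starts. BIC =
n[tr(S_res Θ̂) − log det Θ̂] + ln(n)·df with df = nonzero Γ₃ entries +
nonzero upper-off-diagonal Θ̂ entries (a documented definition — reference
implementations of this model class do not publish theirs). k-fold CV
(deterministic folds given a seed) scores the held-out Gaussian negative
log-likelihood tr(S_test Θ̂) − log det Θ̂ with training estimates. BIC is
the default criterion. Selected probes (any nonzero Γ₃ column) are merged
across clusters keeping the largest-magnitude coefficient per phenotype and
ranked by largest absolute effect, ties broken by probe id.

**Reference solvers.** `mvewas.reference` re-solves both subproblems with
algorithmically disjoint methods — FISTA with adaptive restart for the
Γ-step, an ADMM splitting with closed-form eigenvalue updates for the
Θ-step — purely in numpy/scipy. Validation requires the production and
reference objectives to agree within 1e−4 and supports to match at 1e−6 on
random small instances; closed-form anchors are the unpenalized limit
(multivariate OLS + inverse MLE covariance) and the single-response
reduction to the lasso (via the fixed-point penalty mapping
α = λ/(2θ̂), checked against scikit-learn's solver).

## Synthetic cohort generator

The generator replaces restricted cohort data and reproduces the features
the pipeline exercises, with defaults taken from the published cohort
description (n = 540; 174 CN / 278 MCI / 88 AD; APOE4 carrier fractions
24.7 / 41.0 / 73.9% by diagnosis; raw-scale corr(T\*, N\*) = 0.981).

* **Methylation** — probes within a cluster share a latent Gaussian factor:
  logit-scale value = μ_j + 0.4·(√ρ_b f_c + √(1−ρ_b) ε), so within-cluster
  correlation of M-values equals the configured ρ_b (default 0.5) exactly,
  and beta = expit(·) stays strictly inside (0,1). Per-probe baselines μ_j
  come from an equal-weight two-component mixture at ±2.5 (SD 0.5),
  mimicking the hypo/hyper-methylated bimodality of real arrays.
* **Biomarkers** — trivariate lognormal. The configured corr(T\*, N\*) and
  corr(A\*, ·) are *raw-scale* correlations, matched exactly by inverting
  the lognormal moment formula (NORTA); configurations whose implied
  Gaussian correlation matrix is not positive definite are rejected.
  Log-scale means/SDs (6.86/3.14/5.53, 0.60/0.45/0.40) approximate the
  published medians and IQRs.
* **APOE4** — the per-diagnosis {0,1,2} distribution splits the published
  carrier fraction into 1 vs 2 alleles under Hardy–Weinberg proportions.
* **Cell proportions** — Dirichlet around typical adult leukocyte
  fractions (neutrophil-dominant), concentration 60.
* **Detection p-values** — Unif(0, 0.01) for good probes; a configurable
  fraction (default 2%) of bad probes draw Unif(0.05, 0.5), solely to
  exercise the QC rules.
* **Phenotype simulation** — Y = β_dx·DX + β_apoe4·APOE4 + β_p·X + e with
  DX coded 0/1/2 as a single numeric covariate (matching the 3-vector shape
  of β_dx), covariate effects drawn once per dataset as ±Unif(0.1, 0.5),
  e ~ MVN(0, Σ\*) with Σ\* the empirical covariance of the cohort's
  transformed A/M/D, and β_p sparse: 5 entries of 0.04 (moderate) or 0.08
  (strong), spread (2,2,1) across phenotypes with the short row chosen
  uniformly, or all on one uniformly chosen row (single-phenotype
  scenario); null is all-zero.

What the generator does **not** model: array chemistry and batch effects,
SNP-affected or cross-reactive probes, diagnosis-dependent biomarker
shifts, long-range correlation decay within clusters, or the real
covariance geometry of measured cell proportions (its first three PCs
explain ~81% of variance here versus >95% in the real data). Passing tests
therefore demonstrate correctness of the algorithms under realistic
correlation strengths and effect sizes, not calibration to any particular
cohort.

## Simulation benchmark

One synthetic cluster of 100 probes per dataset, n = 540, scenarios
null/moderate/strong sharing per-dataset seeds (common random numbers, so
effect-size comparisons are paired). Methods: multivariate fit tuned by BIC
(grid 20 λ × 5 ρ), the same tuned by 5-fold CV, and the univariate scan
with within-cluster Bonferroni selection at 0.05/(3m) (the comparator's
selection rule is a documented default). Scoring is entrywise on the 3×m
coefficient matrix (an entry is positive when |value| > 1e−8): TPR, TNR,
and MCC computed on counts; metrics with zero marginals (e.g. TPR under
the null) are reported as missing and excluded from aggregates with the
exclusion count logged. The shipped analyses and validation checks use 10
datasets per scenario — enough to reproduce the method ordering stably
while keeping a full run of the benchmark in minutes on one CPU; the
harness accepts any count.

Behaviour worth knowing when reading results: true signals on the D row are
far easier to detect than on A or M (D's residual SD is ~0.18 versus ~1),
and the univariate selector flags the correlated neighbours of every strong
signal, collapsing its TNR and MCC — this is precisely the phenomenon the
joint model addresses.

## Numerical choices and edge cases

* Beta values clipped to [1e−6, 1−1e−6] before the logit.
* `scale` uses the n−1 sample SD throughout.
* Degenerate PCA input (rank < k) raises rather than returning zeros.
* Detection-rule boundaries follow the stated wording literally: mean
  **strictly greater** than 0.05; **half or more** samples above 0.05;
  strictly **more** than 20% of samples at or above 0.01.
* λ_max carries a 1+1e−8 safety factor so coordinates at exact KKT
  equality round to zero.
* Sign convention for PCA scores: the largest-magnitude loading of each
  component is made positive.
* Selection-table ties are broken lexicographically by probe id.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); rerunning any stage with the same inputs
  and seed is byte-identical.

## Known limitations

* The multivariate model handles complete responses only (no
  missing-phenotype support) and provides no standard errors or inference
  on Γ̂ — it is a selection tool.
* The mixture correction estimates a single global bias/inflation per
  phenotype; it does not model covariate-dependent inflation.
* The alternating objective is biconvex, not jointly convex; the solver
  (like the reference) converges to a stationary point. On the instance
  sizes validated, independent solvers agree to 1e−4, but global optimality
  is not guaranteed in general.
* Gene windows use a single annotation interval per gene; transcript-level
  or strand-aware promoter definitions are out of scope.
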