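# mvewas

Blood DNA methylation carries signatures of neurodegeneration, but
single-probe epigenome-wide association studies (EWAS) of Alzheimer-related
cerebrospinal-fluid (CSF) biomarkers are underpowered: the three classic
biomarkers (amyloid-β42 **A\***, phospho-tau-181 **T\***, total tau **N\***)
are strongly correlated with each other, and methylation at neighbouring
CpG probes is strongly correlated along the genome. `mvewas` implements a
two-stage multivariate analysis that exploits both correlation structures,
together with the synthetic data and simulation benchmarking needed to
validate it without access to restricted cohort data.

## What the package computes

**Phenotype construction.** The raw biomarkers are skewed and nearly
collinear (raw corr(T\*, N\*) ≈ 0.981), so they are re-expressed as

```
A = scale(log A*),   M = (scale(log T*) + scale(log N*)) / 2,
D = scale(log N*) − scale(log T*)
```

where `scale` centers and scales to unit sample variance. M and D are
exactly uncorrelated in-sample by construction.

**Stage 1 (global residualization).** Each probe's logit-methylation
(M-value) is regressed on covariates with genome-wide influence — age, sex,
years of education, epigenetic age acceleration, and the first three
principal components of the blood cell-type proportions. The standardized
residuals X_ij isolate the methylation signal available to disease-specific
analysis.

**Stage 2, univariate arm.** A conventional EWAS of each phenotype on each
probe's residual (adjusting for diagnosis and *APOE4* allele count), with
test statistics corrected for bias and inflation by a three-component
Gaussian mixture (the *bacon* approach) and thresholded at genome-wide
(3.6×10⁻⁸/3) and suggestive (10⁻⁵/3) levels.

**Stage 2, multivariate arm.** Probes are grouped into gene clusters (gene
body ± 100 kb, split to ≤ 300 probes), and per cluster the model

```
min over Γ, Θ ≻ 0 of
(1/n) tr[(Y − WΓ_w − XΓ₃ᵀ)ᵀ(Y − WΓ_w − XΓ₃ᵀ)Θ] − log det Θ
    + λ‖Γ₃‖₁ + ρ‖Θ‖₁,offdiag
```

jointly estimates a sparse 3×m coefficient matrix Γ₃ and a sparse precision
matrix Θ of the phenotype residuals, by alternating cyclic coordinate
descent (Γ-step) with a graphical lasso (Θ-step). Penalties are tuned by
BIC (default) or k-fold cross-validation on log-spaced grids with warm
starts. Selected probes — those with any nonzero coefficient — are ranked
by largest absolute effect.

**Benchmarking.** A synthetic-cohort generator plus a simulation harness
scores multivariate-BIC, multivariate-CV and Bonferroni-EWAS selection
entrywise (TPR, TNR, Matthews correlation coefficient) under null, moderate
(0.04) and strong (0.08) effect-size scenarios.

## Worked example

Run the numbered analysis scripts from the repository root (each is a thin
driver over the library; intermediates go to `scratch/`, summaries to
`results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_residualize.py
python analysis/04_ewas.py
python analysis/05_gene_clusters.py
python analysis/06_multivariate_fit.py
python analysis/07_simulation_study.py
```

Step 01 prints the cohort's key properties — with the default configuration:

```
"corr_raw_t_n": 0.9798094321172255,
"abs_corr_m_d": 4.4197878639359394e-17,
"apoe4_carrier_fraction_by_dx": {"AD": 0.744, "CN": 0.286, "MCI": 0.450}
```

i.e. the tau measures are collinear on the raw scale, M and D are exactly
uncorrelated, and APOE4 carriage is strongly diagnosis-dependent. Step 04
reports the genomic inflation factor of each scan before and after mixture
correction, e.g. `M: lambda_gc 1.181 -> 1.091 after correction`. Step 06
fits every gene cluster; on the default synthetic cohort (whose phenotypes
are independent of methylation) it selects only a handful of probes with
near-zero effects — the expected null behaviour. Step 07 prints the
benchmark aggregate; a representative run:

```
scenario  method  mean_tpr  mean_tnr  mean_mcc
strong   mvr_bic      0.32     0.992     0.371
strong    mvr_cv      0.32     0.982     0.285
strong      ewas      0.40     0.671     0.019
null     mvr_bic       NaN     0.998       NaN
```

The univariate selector floods correlated neighbours of true signals with
false positives (low TNR, near-zero MCC), while the BIC-tuned multivariate
fit keeps TNR above 0.99 and attains the best MCC — the motivation for the
multivariate design.

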