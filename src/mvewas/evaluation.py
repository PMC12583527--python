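"""Selection metrics and the simulation benchmark harness.

The benchmark simulates phenotype datasets over synthetic methylation
clusters and scores how well each method recovers the true sparse signal
pattern, entrywise on the 3 x m coefficient matrix: true/false positive and
negative counts, TPR, TNR and Matthews correlation coefficient (MCC).
Compared methods: the penalized multivariate fit tuned by BIC, the same fit
tuned by cross-validation, and a univariate scan with within-cluster
Bonferroni selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ewas import design_covariates, ewas_scan
from .multivar import (
    cross_validate,
    fit_penalized,
    make_grid,
    PenalizedProblem,
    tune_by_bic,
)
from .preprocess import celltype_pca, logit_transform
from .stage1 import residualize
from .synthetic import (
    build_scenario,
    CELL_TYPES,
    CohortConfig,
    dx_numeric,
    generate_cohort,
    simulate_phenotypes,
)

METHODS = ("mvr_bic", "mvr_cv", "ewas")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def mcc_from_counts(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient on counts; NaN when any marginal
    (row or column sum of the confusion matrix) is zero."""
    marginals = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if any(m == 0 for m in marginals):
        return float("nan")
    num = tp * tn - fp * fn
    denom = np.sqrt(float(marginals[0]) * marginals[1] * marginals[2] * marginals[3])
    return float(num / denom)


def confusion_metrics(
    true_beta: np.ndarray, est_beta: np.ndarray, zero_tol: float = 1e-8
) -> dict:
    """Entrywise selection metrics between true and estimated coefficients.

    An entry counts as positive when its magnitude exceeds ``zero_tol``.
    Undefined ratios (zero marginals) are reported as NaN.
    """
    true_beta = np.asarray(true_beta, dtype=float)
    est_beta = np.asarray(est_beta, dtype=float)
    if true_beta.shape != est_beta.shape:
        raise ValueError("true and estimated coefficient shapes differ")
    t = np.abs(true_beta) > zero_tol
    e = np.abs(est_beta) > zero_tol
    tp = int(np.sum(t & e))
    fp = int(np.sum(~t & e))
    fn = int(np.sum(t & ~e))
    tn = int(np.sum(~t & ~e))
    tpr = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    tnr = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "tpr": tpr,
        "tnr": tnr,
        "mcc": mcc_from_counts(tp, fp, fn, tn),
    }


def ewas_selector(
    Y: np.ndarray,
    X: np.ndarray,
    dx: np.ndarray,
    apoe4: np.ndarray,
    alpha: float | None = None,
) -> np.ndarray:
    """Univariate comparator: per-entry selection at p < alpha.

    Runs the per-probe scan for each phenotype column and selects entries
    below the threshold (default: Bonferroni within the cluster,
    0.05 / (q * m)). Returns a q x m boolean matrix.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    q = Y.shape[1]
    m = X.shape[1]
    if alpha is None:
        alpha = 0.05 / (q * m)
    Xdf = pd.DataFrame(X, columns=[str(j) for j in range(m)])
    sel = np.zeros((q, m), dtype=bool)
    for k in range(q):
        rec = ewas_scan(Y[:, k], Xdf, dx, apoe4)
        hit = rec.index[rec["p"] < alpha]
        sel[k, [int(i) for i in hit]] = True
    return sel


def _prepare_base_cohort(
    n_samples: int, n_clusters: int, cluster_size: int, seed: int
):
    """Generate a cohort and produce the standardized per-cluster residuals
    plus the covariate pieces the simulated second stage needs."""
    cfg = CohortConfig(
        n_samples=n_samples,
        n_clusters=n_clusters,
        probes_per_cluster=cluster_size,
        seed=seed,
    )
    cohort = generate_cohort(cfg)
    mvals = logit_transform(cohort.beta)
    cov = cohort.covariates.copy()
    scores, _ = celltype_pca(cov[[f"cell_{c}" for c in CELL_TYPES]].to_numpy())
    cov[["pc1", "pc2", "pc3"]] = scores
    _, resid = residualize(mvals, cov)
    dxn = dx_numeric(cov["dx"].to_numpy())
    apoe4 = cov["apoe4"].to_numpy(dtype=float)
    sigma_star = np.cov(cohort.biomarkers[["A", "M", "D"]].to_numpy(), rowvar=False)
    cluster_cols = [
        resid.columns[cohort.cluster_of_probe.loc[resid.columns] == c]
        for c in range(n_clusters)
    ]
    return cohort, resid, cluster_cols, dxn, apoe4, sigma_star


def run_simulation_study(
    n_datasets: int = 50,
    scenarios: tuple[str, ...] = ("null", "moderate", "strong"),
    methods: tuple[str, ...] = METHODS,
    seed: int = 0,
    n_samples: int = 540,
    cluster_size: int = 100,
    n_signals: int = 5,
    n_lambda: int = 20,
    n_rho: int = 5,
    cv_folds: int = 5,
    tol: float = 1e-4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The variable-selection benchmark.

    One synthetic methylation cluster is generated per dataset; for each
    scenario the sparse true coefficients and phenotypes are simulated and
    every method is scored entrywise. Scenarios share per-dataset seeds
    (common random numbers), so e.g. the moderate and strong scenarios
    differ only in the signal magnitude. Deterministic given ``seed``.

    Returns (per-dataset metrics table, aggregate table). Aggregates are
    means/medians over datasets with NaN metrics excluded and counted.
    """
    _, resid, cluster_cols, dxn, apoe4, sigma_star = _prepare_base_cohort(
        n_samples, n_datasets, cluster_size, seed
    )
    W = design_covariates(dxn, apoe4)
    dataset_seeds = np.random.default_rng(seed).integers(2**31, size=n_datasets)

    rows = []
    for d in range(n_datasets):
        X = np.ascontiguousarray(resid[cluster_cols[d]].to_numpy())
        for scen in scenarios:
            rng = np.random.default_rng(dataset_seeds[d])
            spec = build_scenario(scen, X.shape[1], sigma_star, rng, n_signals=n_signals)
            Y = simulate_phenotypes(X, dxn, apoe4, spec, rng)
            grids = None
            for method in methods:
                if method == "ewas":
                    est = ewas_selector(Y, X, dxn, apoe4).astype(float)
                elif method in ("mvr_bic", "mvr_cv"):
                    if grids is None:
                        grids = make_grid(Y, W, X, n_lambda=n_lambda, n_rho=n_rho)
                    if method == "mvr_bic":
                        fit, _ = tune_by_bic(Y, W, X, *grids, tol=tol)
                    else:
                        (lam, rho), _ = cross_validate(
                            Y, W, X, *grids, k=cv_folds,
                            seed=int(dataset_seeds[d] % 2**31), tol=tol,
                        )
                        fit = fit_penalized(
                            PenalizedProblem(Y, W, X, lam=lam, rho=rho), tol=tol
                        )
                    est = fit.Gamma3
                else:
                    raise ValueError(f"unknown method {method!r}")
                metrics = confusion_metrics(spec.beta_p, est)
                rows.append({"dataset": d, "scenario": scen, "method": method, **metrics})

    table = pd.DataFrame(rows)
    agg = (
        table.groupby(["scenario", "method"])
        .agg(
            mean_tpr=("tpr", "mean"),
            median_tpr=("tpr", "median"),
            mean_tnr=("tnr", "mean"),
            median_tnr=("tnr", "median"),
            mean_mcc=("mcc", "mean"),
            median_mcc=("mcc", "median"),
            n_datasets=("mcc", "size"),
            n_mcc_undefined=("mcc", lambda s: int(s.isna().sum())),
        )
        .reset_index()
    )
    return table, agg
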