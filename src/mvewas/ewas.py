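"""Stage 2, univariate arm: probe-by-phenotype association scan.

For each transformed CSF phenotype (A, M, D) and each probe, the phenotype
is regressed on the probe's standardized stage-1 residual plus diagnosis and
APOE4 allele count. Test statistics are mapped to the z scale, corrected for
bias and inflation with a three-component normal mixture (the bacon
approach: the dominant central component estimates the null mean and SD),
and thresholded for genome-wide / suggestive significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: median of the chi-square distribution with 1 degree of freedom
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

GENOME_WIDE_ALPHA = 3.6e-8
SUGGESTIVE_ALPHA = 1e-5


def design_covariates(dx: np.ndarray, apoe4: np.ndarray) -> np.ndarray:
    """Unpenalized covariate design: intercept, diagnosis coding, APOE4.

    String/categorical ``dx`` becomes two indicator columns (MCI, AD vs CN
    reference); numeric ``dx`` is used as a single column (the coding used
    in simulations).
    """
    dx = np.asarray(dx)
    apoe4 = np.asarray(apoe4, dtype=float)
    n = dx.shape[0]
    if dx.dtype.kind in "OUS":
        cols = [np.ones(n), (dx == "MCI").astype(float), (dx == "AD").astype(float)]
    else:
        cols = [np.ones(n), dx.astype(float)]
    cols.append(apoe4)
    return np.column_stack(cols)


def ewas_scan(
    y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    dx: np.ndarray,
    apoe4: np.ndarray,
    phenotype: str = "Y",
) -> pd.DataFrame:
    """Per-probe OLS scan of one phenotype on residualized methylation.

    Uses the Frisch-Waugh partialling identity: ``y`` and every probe column
    are residualized on the covariate block once, and the slope, SE and
    t-statistic of the probe term in the full model follow from the
    univariate fit between those residuals (with the full-model df). The
    t p-value is mapped back to a z score via the standard-normal quantile.

    Returns one row per probe: beta, se, z, p. Probes whose residualized
    values have (near-)zero variance are dropped.
    """
    if isinstance(X, pd.DataFrame):
        probe_ids = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        probe_ids = [f"p{j}" for j in range(Xv.shape[1])]
    y = np.asarray(y, dtype=float)
    W = design_covariates(dx, apoe4)
    n, c = W.shape
    df = n - c - 1
    if df < 1:
        raise ValueError("not enough samples for the scan design")

    Q, _ = np.linalg.qr(W)
    y_t = y - Q @ (Q.T @ y)
    X_t = Xv - Q @ (Q.T @ Xv)

    ss_x = np.einsum("ij,ij->j", X_t, X_t)
    ok = ss_x > 1e-12 * n
    X_t, ss_x = X_t[:, ok], ss_x[ok]
    kept = [probe_ids[j] for j in np.flatnonzero(ok)]

    xy = X_t.T @ y_t
    beta = xy / ss_x
    rss = float(y_t @ y_t) - beta * xy
    sigma2 = rss / df
    se = np.sqrt(sigma2 / ss_x)
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    z = np.sign(t) * stats.norm.isf(np.clip(p, 1e-300, 1.0) / 2.0)
    return pd.DataFrame(
        {"phenotype": phenotype, "beta": beta, "se": se, "z": z, "p": p},
        index=pd.Index(kept, name="probe_id"),
    )


@dataclass
class BaconFit:
    """Three-component mixture estimate of the null bias and inflation."""

    bias: float
    inflation: float
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    n_iter: int
    converged: bool


class BaconConvergenceError(RuntimeError):
    def __init__(self, fit: BaconFit):
        super().__init__("mixture EM did not converge within the iteration limit")
        self.fit = fit


def bacon_correct(
    z: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 2000,
    tail_separation: float = 3.0,
) -> tuple[BaconFit, np.ndarray, np.ndarray]:
    """Bias/inflation correction of z statistics via a 3-component mixture.

    A Gaussian mixture (dominant central null component plus left and right
    tail components for true associations) is fitted by constrained EM; the
    central component's mean and SD are the estimated null bias and
    inflation. Initialization: central component at (median, MAD-based SD)
    with weight 0.9, tails at +/- 3 SD with doubled SD and weight 0.05
    each. Identifiability constraints keep the tail means at least
    ``tail_separation`` central SDs below/above the central mean — on
    statistics that are (near-)entirely null, the unconstrained
    three-component likelihood is flat and EM would otherwise let a tail
    component slide into the bulk and distort the null estimates. The EM
    stops when the relative log-likelihood change drops below ``tol``.

    Adjusted statistics are z_adj = (z - bias) / inflation with two-sided
    normal p-values.
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0 or not np.all(np.isfinite(z)):
        raise ValueError("z statistics must be nonempty and finite")
    med = float(np.median(z))
    mad_sd = float(stats.median_abs_deviation(z, scale="normal"))
    if mad_sd <= 0:
        mad_sd = max(float(z.std()), 1e-3)

    n = z.size
    mu = np.array([med, med - 3 * mad_sd, med + 3 * mad_sd])
    sd = np.array([mad_sd, 2 * mad_sd, 2 * mad_sd])
    w = np.array([0.9, 0.05, 0.05])
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp = (
            stats.norm.logpdf(z[:, None], mu[None, :], sd[None, :])
            + np.log(np.maximum(w, 1e-300))[None, :]
        )
        mx = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - mx)
        tot = p.sum(axis=1, keepdims=True)
        ll = float((np.log(tot) + mx).sum())
        r = p / tot
        nk = r.sum(axis=0)
        w = nk / n
        safe = np.maximum(nk, 1e-8)
        mu = np.where(nk > 1e-8, (r * z[:, None]).sum(axis=0) / safe, mu)
        var = (r * (z[:, None] - mu[None, :]) ** 2).sum(axis=0) / safe
        sd = np.maximum(np.where(nk > 1e-8, np.sqrt(var), sd), 1e-6)
        mu[1] = min(mu[1], mu[0] - tail_separation * sd[0])
        mu[2] = max(mu[2], mu[0] + tail_separation * sd[0])
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_old = ll

    fit = BaconFit(
        bias=float(mu[0]),
        inflation=float(sd[0]),
        weights=w,
        means=mu,
        sds=sd,
        n_iter=it,
        converged=converged,
    )
    if not converged:
        raise BaconConvergenceError(fit)
    if np.argmax(w) != 0:
        raise BaconConvergenceError(fit)  # central component lost dominance
    z_adj = (z - fit.bias) / fit.inflation
    p_adj = 2.0 * stats.norm.sf(np.abs(z_adj))
    return fit, z_adj, np.clip(p_adj, np.nextafter(0, 1), 1.0)


def inflation_factor(z: np.ndarray) -> float:
    """Genomic-control inflation factor: median(z^2) / median(chi2_1)."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("empty statistic vector")
    return float(np.median(z**2) / CHI2_1_MEDIAN)


def call_significance(p_adj: np.ndarray, n_phenotypes: int = 3) -> np.ndarray:
    """Label each corrected p-value genome_wide / suggestive / none.

    Thresholds are the conventional EWAS levels divided by the number of
    phenotypes tested: genome-wide 3.6e-8 / n, suggestive 1e-5 / n.
    """
    p_adj = np.asarray(p_adj, dtype=float)
    gw = GENOME_WIDE_ALPHA / n_phenotypes
    sug = SUGGESTIVE_ALPHA / n_phenotypes
    out = np.where(p_adj < gw, "genome_wide", np.where(p_adj < sug, "suggestive", "none"))
    return out


def scan_all_phenotypes(
    phenotypes: pd.DataFrame,
    X: pd.DataFrame,
    dx: np.ndarray,
    apoe4: np.ndarray,
    correct: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Run the scan for every phenotype column, with optional mixture
    correction applied per phenotype; returns the stacked record table and a
    summary of inflation factors before/after."""
    records = []
    summary = {}
    for name in phenotypes.columns:
        rec = ewas_scan(phenotypes[name].to_numpy(), X, dx, apoe4, phenotype=name)
        lam_before = inflation_factor(rec["z"].to_numpy())
        if correct:
            fit, z_adj, p_adj = bacon_correct(rec["z"].to_numpy())
            rec["z_adj"], rec["p_adj"] = z_adj, p_adj
            summary[name] = {
                "lambda_before": lam_before,
                "lambda_after": inflation_factor(z_adj),
                "bias": fit.bias,
                "inflation": fit.inflation,
            }
        else:
            rec["z_adj"], rec["p_adj"] = rec["z"], rec["p"]
            summary[name] = {"lambda_before": lam_before}
        rec["significance"] = call_significance(
            rec["p_adj"].to_numpy(), n_phenotypes=phenotypes.shape[1]
        )
        records.append(rec.reset_index())
    return pd.concat(records, ignore_index=True), summary
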