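"""Stage 1: per-probe residualization of logit-methylation on global covariates.

Each probe's M-values are regressed on intercept, years of education, age,
epigenetic age acceleration, sex, and the first three cell-type-proportion
principal components. The residuals, standardized to mean 0 and unit sample
SD per probe, are the methylation signal passed to stage 2; standardization
makes every downstream coefficient a per-1-SD effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

STAGE1_COVARIATES = ("yoe", "age", "eaa", "sex", "pc1", "pc2", "pc3")


@dataclass
class Stage1Fit:
    """Per-probe OLS coefficients and raw (unstandardized) residuals."""

    coefficients: pd.DataFrame  # probes x (intercept + covariates)
    residuals: pd.DataFrame  # samples x probes
    dropped_probes: list


def _design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    missing = [c for c in STAGE1_COVARIATES if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table is missing columns: {missing}")
    cols = covariates[list(STAGE1_COVARIATES)].to_numpy(dtype=float)
    if np.isnan(cols).any():
        raise ValueError("missing covariate values; analysis requires complete cases")
    return np.column_stack([np.ones(len(covariates)), cols])


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    # identify collinear columns from the R factor of a pivoted-free QR
    r = np.linalg.qr(design, mode="r")
    diag = np.abs(np.diag(r))
    tol = design.shape[0] * np.finfo(float).eps * diag.max()
    bad = [names[i] for i in np.flatnonzero(diag < tol)]
    if bad:
        raise ValueError(f"rank-deficient stage-1 design; collinear columns: {bad}")


def residualize(
    mvalues: pd.DataFrame, covariates: pd.DataFrame, sd_tol: float = 1e-12
) -> tuple[Stage1Fit, pd.DataFrame]:
    """OLS of each probe's M-values on the global covariates.

    ``mvalues`` is probes x samples; ``covariates`` is indexed by sample and
    must contain yoe, age, eaa, sex, pc1..pc3. Returns the fit plus the
    standardized residual matrix (samples x probes, mean 0 / SD 1 per
    probe). Probes with residual SD below ``sd_tol`` (e.g. M-values that are
    a linear combination of covariates) are dropped with a warning.
    """
    covariates = covariates.loc[list(mvalues.columns)]
    design = _design_matrix(covariates)
    names = ["intercept", *STAGE1_COVARIATES]
    _check_full_rank(design, names)

    y = mvalues.to_numpy(dtype=float).T  # samples x probes
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef

    sds = resid.std(axis=0, ddof=1)
    keep = sds >= sd_tol
    dropped = list(mvalues.index[~keep])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} probes with (near-)zero residual variance",
            stacklevel=2,
        )
    std = (resid[:, keep] - resid[:, keep].mean(axis=0)) / sds[keep]

    fit = Stage1Fit(
        coefficients=pd.DataFrame(coef.T, index=mvalues.index, columns=names),
        residuals=pd.DataFrame(resid, index=covariates.index, columns=mvalues.index),
        dropped_probes=dropped,
    )
    residual_matrix = pd.DataFrame(
        std, index=covariates.index, columns=mvalues.index[keep]
    )
    return fit, residual_matrix
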