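"""Quality control and variable transforms ahead of the two-stage analysis.

Covers four independent steps: detection-p-value probe filtering, the logit
(M-value) transform of methylation beta values, the A/M/D transform of the
raw CSF biomarkers (amyloid-beta 42, phospho-tau 181, total tau), and PCA of
the leukocyte cell-type proportions.

The A/M/D construction removes the near-collinearity between phospho-tau
(T*) and total tau (N*): after log-transform and standardization, the mean
M = (scale(ln T*) + scale(ln N*))/2 and difference D = scale(ln N*) -
scale(ln T*) are exactly uncorrelated in-sample, because both scaled terms
have unit variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit as _logit
from sklearn.decomposition import PCA


@dataclass
class DetectionFilterReport:
    """Per-rule removal counts from :func:`filter_probes_by_detection`."""

    n_input: int
    n_kept: int
    removed_mean_rule: int
    removed_half_rule: int
    removed_fraction_rule: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def filter_probes_by_detection(
    detp: pd.DataFrame,
    loose_threshold: float = 0.05,
    strict_threshold: float = 0.01,
    strict_fraction: float = 0.20,
) -> tuple[list[str], DetectionFilterReport]:
    """Filter probes (rows) on their detection p-values across samples.

    A probe is removed when any of three rules fires:

    1. mean detection p across samples > ``loose_threshold``;
    2. detection p > ``loose_threshold`` in half or more of the samples;
    3. detection p >= ``strict_threshold`` in more than ``strict_fraction``
       of the samples.

    Returns the surviving probe ids in input order plus a per-rule report.
    The three rules are pure row predicates, so their application order is
    irrelevant.
    """
    if detp.shape[0] == 0 or detp.shape[1] == 0:
        raise ValueError("empty detection p-value matrix")
    vals = detp.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 1) or not np.all(np.isfinite(vals)):
        raise ValueError("detection p-values must be finite and in [0, 1]")
    n_samples = vals.shape[1]
    rule_mean = vals.mean(axis=1) > loose_threshold
    rule_half = (vals > loose_threshold).sum(axis=1) >= n_samples / 2.0
    rule_frac = (vals >= strict_threshold).sum(axis=1) > strict_fraction * n_samples
    keep = ~(rule_mean | rule_half | rule_frac)
    report = DetectionFilterReport(
        n_input=int(vals.shape[0]),
        n_kept=int(keep.sum()),
        removed_mean_rule=int(rule_mean.sum()),
        removed_half_rule=int(rule_half.sum()),
        removed_fraction_rule=int(rule_frac.sum()),
    )
    return list(detp.index[keep]), report


def logit_transform(beta, eps: float = 1e-6):
    """Natural-log logit of methylation beta values, clipped to [eps, 1-eps].

    Accepts any array-like (or DataFrame, which is returned with the same
    index/columns). Values outside [0, 1] raise.
    """
    if isinstance(beta, pd.DataFrame):
        out = logit_transform(beta.to_numpy(dtype=float), eps=eps)
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    arr = np.asarray(beta, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
        raise ValueError("beta values must be finite and in [0, 1]")
    return _logit(np.clip(arr, eps, 1.0 - eps))


def scale(x) -> np.ndarray:
    """Center to mean 0 and scale to unit sample SD (n-1 denominator)."""
    arr = np.asarray(x, dtype=float)
    sd = arr.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot scale a zero-variance vector")
    return (arr - arr.mean()) / sd


def transform_biomarkers(a_raw, t_raw, n_raw) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw CSF biomarkers (A*, T*, N*) -> transformed phenotypes (A, M, D).

    A = scale(ln A*), M = (scale(ln T*) + scale(ln N*)) / 2,
    D = scale(ln N*) - scale(ln T*).

    In-sample corr(M, D) is zero by construction since both scaled log tau
    measures have unit variance.
    """
    vecs = [np.asarray(v, dtype=float) for v in (a_raw, t_raw, n_raw)]
    n = vecs[0].shape[0]
    if any(v.shape[0] != n for v in vecs):
        raise ValueError("biomarker vectors must have equal length")
    if n < 3:
        raise ValueError("need at least 3 samples to scale biomarkers")
    for v in vecs:
        if np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise ValueError("raw biomarker values must be positive and finite")
    a = scale(np.log(vecs[0]))
    st = scale(np.log(vecs[1]))
    sn = scale(np.log(vecs[2]))
    m = (st + sn) / 2.0
    d = sn - st
    return a, m, d


def celltype_pca(cell_props, k: int = 3) -> tuple[np.ndarray, float]:
    """PCA scores of cell-type proportions with a deterministic sign fix.

    Columns are centered; the first ``k`` principal-component scores are
    returned along with the cumulative explained-variance fraction. Each
    component's sign is chosen so its largest-magnitude loading is positive.
    """
    props = np.asarray(cell_props, dtype=float)
    if props.ndim != 2:
        raise ValueError("cell proportions must be a 2-D matrix")
    n = props.shape[0]
    if n <= k:
        raise ValueError("need more samples than requested components")
    centered = props - props.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-10)
    if k > rank:
        raise ValueError(
            f"requested {k} components but centered matrix has rank {rank}"
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(centered)
    for c in range(k):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, c] *= -1.0
    return scores, float(pca.explained_variance_ratio_.sum())
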