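"""Synthetic ADNI-like cohorts and simulated phenotype datasets.

The real study cohort (peripheral-blood EPIC-array methylation plus CSF
biomarkers from ADNI) is access-restricted, so every downstream stage is
exercised on data from this generator instead. It emulates the features the
analysis actually relies on:

* block-correlated, bimodal methylation beta values — probes within a gene
  cluster share a latent Gaussian factor, and per-probe baselines come from
  a hypo/hyper-methylated mixture, so logit(beta) has exactly the configured
  equicorrelation within a cluster;
* skewed lognormal CSF biomarkers with the strong raw-scale correlation
  between phospho-tau (T*) and total tau (N*) reported for ADNI (0.981);
* a 7-cell-type blood composition (Dirichlet around typical leukocyte
  fractions);
* diagnosis-dependent APOE4 allele counts matching the published carrier
  fractions under a Hardy-Weinberg split of carriers;
* the phenotype simulation model Y = beta_dx*DX + beta_apoe4*APOE4 +
  beta_p*X + e with sparse beta_p in {0, 0.04, 0.08} and multivariate normal
  residuals.

It does NOT model array chemistry, batch effects, SNP-affected probes, or
the exact ADNI marginal distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .preprocess import transform_biomarkers

DX_LEVELS = ("CN", "MCI", "AD")
CELL_TYPES = ("B", "NK", "CD4T", "CD8T", "Mono", "Neutro", "Eosino")

#: Typical mean leukocyte fractions in adult whole blood (sum to 1).
_CELL_MEANS = np.array([0.05, 0.06, 0.15, 0.10, 0.08, 0.54, 0.02])
_CELL_CONCENTRATION = 60.0

SCENARIO_NAMES = ("null", "moderate", "strong", "single_phenotype")


def _hwe_apoe4_freqs(carrier_fraction: float) -> tuple[float, float, float]:
    """{0,1,2}-allele-count probabilities from a carrier fraction, assuming
    Hardy-Weinberg proportions for the split of carriers into 1 vs 2 alleles."""
    q = np.sqrt(1.0 - carrier_fraction)  # non-carrier allele frequency
    p = 1.0 - q
    return (q * q, 2 * p * q, p * p)


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the published cohort description: n=540 with
    174 CN / 278 MCI / 88 AD, APOE4 carrier fractions 24.7/41.0/73.9% by
    diagnosis, and raw-scale corr(T*, N*) = 0.981. ``corr_tn``/``corr_at``
    are correlations of the *raw* lognormal biomarkers; the generator
    matches them exactly via the lognormal (NORTA) inversion.
    """

    n_samples: int = 540
    n_clusters: int = 20
    probes_per_cluster: int = 50
    block_correlation: float = 0.5
    biomarker_log_means: tuple[float, float, float] = (6.86, 3.14, 5.53)
    biomarker_log_sds: tuple[float, float, float] = (0.60, 0.45, 0.40)
    corr_tn: float = 0.981
    corr_at: float = -0.30
    apoe4_freq_by_dx: dict = field(
        default_factory=lambda: {
            "CN": _hwe_apoe4_freqs(0.247),
            "MCI": _hwe_apoe4_freqs(0.410),
            "AD": _hwe_apoe4_freqs(0.739),
        }
    )
    dx_proportions: tuple[float, float, float] = (174 / 540, 278 / 540, 88 / 540)
    bad_probe_fraction: float = 0.02
    probe_logit_sd: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 3 or self.n_clusters < 1 or self.probes_per_cluster < 1:
            raise ValueError("cohort dimensions must be positive")
        if not (0.0 <= self.block_correlation < 1.0):
            raise ValueError("block_correlation must be in [0, 1)")
        if abs(sum(self.dx_proportions) - 1.0) > 1e-8:
            raise ValueError("dx_proportions must sum to 1")
        for dx, freqs in self.apoe4_freq_by_dx.items():
            if abs(sum(freqs) - 1.0) > 1e-8:
                raise ValueError(f"APOE4 frequencies for {dx} must sum to 1")
        if any(s <= 0 for s in self.biomarker_log_sds):
            raise ValueError("biomarker_log_sds must be positive")
        # PD check of the implied log-scale correlation matrix
        self._log_scale_corr()

    def _log_scale_corr(self) -> np.ndarray:
        """Log-scale (Gaussian copula) correlation matrix matching the
        requested raw-scale correlations of the lognormal biomarkers."""
        sds = np.asarray(self.biomarker_log_sds)

        def to_log(r: float, s1: float, s2: float) -> float:
            arg = 1.0 + r * np.sqrt(np.expm1(s1 * s1) * np.expm1(s2 * s2))
            if arg <= 0:
                raise ValueError("raw-scale correlation unattainable for these sds")
            rho = np.log(arg) / (s1 * s2)
            if not (-1.0 < rho < 1.0):
                raise ValueError("raw-scale correlation unattainable for these sds")
            return rho

        r_at = to_log(self.corr_at, sds[0], sds[1])
        r_an = to_log(self.corr_at, sds[0], sds[2])
        r_tn = to_log(self.corr_tn, sds[1], sds[2])
        corr = np.array([[1.0, r_at, r_an], [r_at, 1.0, r_tn], [r_an, r_tn, 1.0]])
        if np.linalg.eigvalsh(corr).min() <= 1e-10:
            raise ValueError("implied biomarker correlation matrix is not positive definite")
        return corr


@dataclass
class SyntheticCohort:
    """All generated tables plus the generator truth parameters."""

    beta: pd.DataFrame  # probes x samples, values strictly in (0, 1)
    detection_p: pd.DataFrame  # probes x samples
    covariates: pd.DataFrame  # per sample
    biomarkers: pd.DataFrame  # raw A*/T*/N* plus transformed A/M/D
    probe_positions: pd.DataFrame  # probe_id, chrom, pos
    genes: pd.DataFrame  # gene_id, chrom, start, end
    cluster_of_probe: pd.Series  # probe_id -> cluster index
    truth: dict

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    def write(self, out_dir) -> None:
        """Write all tables as plain-text files (TSV/CSV/BED/JSON)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.beta.to_csv(out / "methylation.tsv", sep="\t", index_label="probe_id")
        self.detection_p.to_csv(out / "detection_p.tsv", sep="\t", index_label="probe_id")
        self.covariates.to_csv(out / "covariates.csv", index_label="sample_id")
        self.biomarkers.to_csv(out / "biomarkers.csv", index_label="sample_id")
        probes_bed = pd.DataFrame(
            {
                "chrom": self.probe_positions["chrom"],
                "start": self.probe_positions["pos"],
                "end": self.probe_positions["pos"] + 1,
                "name": self.probe_positions.index,
            }
        )
        probes_bed.to_csv(out / "probes.bed", sep="\t", header=False, index=False)
        genes_bed = self.genes[["chrom", "start", "end"]].copy()
        genes_bed["name"] = self.genes.index
        genes_bed.to_csv(out / "genes.bed", sep="\t", header=False, index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer, np.floating)):
        return x.item()
    raise TypeError(f"not JSON serializable: {type(x)}")


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Draw a full synthetic cohort; bit-identical given the config seed."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    # --- demographics -----------------------------------------------------
    dx_codes = rng.choice(3, size=n, p=np.asarray(config.dx_proportions))
    dx = np.array(DX_LEVELS)[dx_codes]
    apoe4 = np.empty(n, dtype=int)
    for level in DX_LEVELS:
        mask = dx == level
        apoe4[mask] = rng.choice(3, size=mask.sum(), p=np.asarray(config.apoe4_freq_by_dx[level]))
    age = rng.normal(74.5, 7.5, size=n)
    yoe = np.clip(rng.normal(16.2, 2.7, size=n), 6, 22)
    sex = rng.binomial(1, 0.45, size=n)
    eaa = rng.normal(0.0, 4.0, size=n)
    cell_props = rng.dirichlet(_CELL_MEANS * _CELL_CONCENTRATION, size=n)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    covariates = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "yoe": yoe,
            "eaa": eaa,
            "dx": dx,
            "apoe4": apoe4,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for c, name in enumerate(CELL_TYPES):
        covariates[f"cell_{name}"] = cell_props[:, c]

    # --- CSF biomarkers ---------------------------------------------------
    log_corr = config._log_scale_corr()
    sds = np.asarray(config.biomarker_log_sds)
    cov = log_corr * np.outer(sds, sds)
    logs = rng.multivariate_normal(np.asarray(config.biomarker_log_means), cov, size=n)
    raw = np.exp(logs)
    a, m, d = transform_biomarkers(raw[:, 0], raw[:, 1], raw[:, 2])
    biomarkers = pd.DataFrame(
        {
            "a_raw": raw[:, 0],
            "t_raw": raw[:, 1],
            "n_raw": raw[:, 2],
            "A": a,
            "M": m,
            "D": d,
        },
        index=covariates.index,
    )

    # --- methylation ------------------------------------------------------
    p_total = config.n_clusters * config.probes_per_cluster
    rho = config.block_correlation
    mus = np.where(
        rng.random(p_total) < 0.5,
        rng.normal(-2.5, 0.5, size=p_total),
        rng.normal(2.5, 0.5, size=p_total),
    )
    latent = np.empty((p_total, n))
    cluster_idx = np.repeat(np.arange(config.n_clusters), config.probes_per_cluster)
    for c in range(config.n_clusters):
        rows = cluster_idx == c
        k = rows.sum()
        factor = rng.standard_normal(n)
        noise = rng.standard_normal((k, n))
        latent[rows] = np.sqrt(rho) * factor[None, :] + np.sqrt(1.0 - rho) * noise
    mvals = mus[:, None] + config.probe_logit_sd * latent
    beta_vals = expit(mvals)

    probe_ids = [f"cg{i:06d}" for i in range(p_total)]
    beta = pd.DataFrame(beta_vals, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)

    # --- detection p-values ----------------------------------------------
    detp_vals = rng.uniform(0.0, 0.01, size=(p_total, n))
    bad = rng.random(p_total) < config.bad_probe_fraction
    detp_vals[bad] = rng.uniform(0.05, 0.5, size=(int(bad.sum()), n))
    detp = pd.DataFrame(detp_vals, index=beta.index, columns=sample_ids)

    # --- genomic layout: one gene per cluster on chr1 ---------------------
    probe_spacing = 200
    cluster_origin = 1_000_000
    cluster_stride = 1_000_000
    positions = cluster_origin + cluster_idx * cluster_stride + (
        np.arange(p_total) % config.probes_per_cluster
    ) * probe_spacing
    probe_positions = pd.DataFrame(
        {"chrom": "chr1", "pos": positions}, index=beta.index
    )
    gene_ids = [f"gene{c:03d}" for c in range(config.n_clusters)]
    gene_start = cluster_origin + np.arange(config.n_clusters) * cluster_stride
    genes = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": gene_start,
            "end": gene_start + config.probes_per_cluster * probe_spacing,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    cluster_of_probe = pd.Series(cluster_idx, index=beta.index, name="cluster")

    truth = {
        "seed": config.seed,
        "block_correlation": rho,
        "probe_logit_means": mus,
        "probe_logit_sd": config.probe_logit_sd,
        "bad_probes": [probe_ids[i] for i in np.flatnonzero(bad)],
        "biomarker_log_corr": log_corr,
    }
    return SyntheticCohort(
        beta=beta,
        detection_p=detp,
        covariates=covariates,
        biomarkers=biomarkers,
        probe_positions=probe_positions,
        genes=genes,
        cluster_of_probe=cluster_of_probe,
        truth=truth,
    )


@dataclass
class ScenarioSpec:
    """True parameters of one simulated phenotype dataset."""

    name: str
    beta_dx: np.ndarray  # (3,)
    beta_apoe4: np.ndarray  # (3,)
    beta_p: np.ndarray  # (3, m) sparse
    sigma_star: np.ndarray  # (3, 3) residual covariance
    n_signals: int
    effect_size: float

    def validate(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}")
        nnz = int(np.count_nonzero(self.beta_p))
        if self.name == "null":
            if nnz != 0:
                raise ValueError("null scenario requires all-zero beta_p")
        elif nnz != self.n_signals:
            raise ValueError("beta_p must carry exactly n_signals nonzero entries")
        nz = self.beta_p[self.beta_p != 0]
        if nz.size and not np.allclose(nz, self.effect_size):
            raise ValueError("nonzero beta_p entries must equal effect_size")
        if np.linalg.eigvalsh(self.sigma_star).min() <= 0:
            raise ValueError("sigma_star must be positive definite")


SCENARIO_EFFECT = {"null": 0.0, "moderate": 0.04, "strong": 0.08, "single_phenotype": 0.04}


def draw_covariate_effects(rng) -> tuple[np.ndarray, np.ndarray]:
    """Diagnosis and APOE4 effect vectors: magnitudes ~ Unif(0.1, 0.5) with
    equiprobable random sign, drawn once per simulated dataset."""
    rng = np.random.default_rng(rng)
    mags = rng.uniform(0.1, 0.5, size=(2, 3))
    signs = rng.choice([-1.0, 1.0], size=(2, 3))
    eff = mags * signs
    return eff[0], eff[1]


def _signal_rows(name: str, n_signals: int, rng) -> np.ndarray:
    """Phenotype-row assignment for the nonzero entries.

    Multi-phenotype scenarios spread the signals as evenly as the integer
    count allows (for 5 signals: counts (2,2,1) with the short row chosen
    uniformly); the single-phenotype scenario puts all signals on one
    uniformly chosen row.
    """
    if name == "single_phenotype":
        return np.full(n_signals, rng.integers(3))
    base, extra = divmod(n_signals, 3)
    counts = np.full(3, base)
    counts[rng.permutation(3)[:extra]] += 1
    rows = np.repeat(np.arange(3), counts)
    return rng.permutation(rows)


def build_scenario(
    name: str,
    m: int,
    sigma_star: np.ndarray,
    rng,
    n_signals: int = 5,
) -> ScenarioSpec:
    """Construct a ScenarioSpec with randomly placed sparse signals."""
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}")
    rng = np.random.default_rng(rng)
    effect = SCENARIO_EFFECT[name]
    beta_dx, beta_apoe4 = draw_covariate_effects(rng)
    beta_p = np.zeros((3, m))
    if name != "null":
        if n_signals > m:
            raise ValueError("more signals than probes in the cluster")
        cols = rng.choice(m, size=n_signals, replace=False)
        rows = _signal_rows(name, n_signals, rng)
        beta_p[rows, cols] = effect
    spec = ScenarioSpec(
        name=name,
        beta_dx=beta_dx,
        beta_apoe4=beta_apoe4,
        beta_p=beta_p,
        sigma_star=np.asarray(sigma_star, dtype=float),
        n_signals=0 if name == "null" else n_signals,
        effect_size=effect,
    )
    spec.validate()
    return spec


def simulate_phenotypes(
    X: np.ndarray,
    dx: np.ndarray,
    apoe4: np.ndarray,
    scenario: ScenarioSpec,
    rng,
) -> np.ndarray:
    """Simulate the n x 3 phenotype matrix for one cluster.

    Y = dx * beta_dx + apoe4 * beta_apoe4 + X @ beta_p.T + e, with
    e ~ MVN(0, sigma_star) i.i.d. across samples. ``dx`` is the numeric
    diagnosis code (0=CN, 1=MCI, 2=AD) used as a single covariate.
    """
    scenario.validate()
    X = np.asarray(X, dtype=float)
    dx = np.asarray(dx, dtype=float)
    apoe4 = np.asarray(apoe4, dtype=float)
    n, m = X.shape
    if scenario.beta_p.shape[1] != m:
        raise ValueError(
            f"scenario has {scenario.beta_p.shape[1]} probe columns, cluster has {m}"
        )
    if dx.shape[0] != n or apoe4.shape[0] != n:
        raise ValueError("dx/apoe4 length must match the number of samples")
    rng = np.random.default_rng(rng)
    e = rng.multivariate_normal(np.zeros(3), scenario.sigma_star, size=n)
    return (
        dx[:, None] * scenario.beta_dx[None, :]
        + apoe4[:, None] * scenario.beta_apoe4[None, :]
        + X @ scenario.beta_p.T
        + e
    )


def dx_numeric(dx: np.ndarray) -> np.ndarray:
    """Map CN/MCI/AD labels to the 0/1/2 code used in simulations."""
    mapping = {lvl: i for i, lvl in enumerate(DX_LEVELS)}
    return np.array([mapping[str(v)] for v in np.asarray(dx)], dtype=float)
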