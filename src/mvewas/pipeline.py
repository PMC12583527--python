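"""End-to-end orchestration: QC -> transforms -> stage 1 -> EWAS ->
clustering -> penalized multivariate fits -> probe selection.

Every stage writes its output as a plain-text file under the run directory,
so stages are independently re-runnable, and a manifest records seeds,
input digests and per-stage record counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .clusters import build_and_split, membership_table
from .ewas import design_covariates, scan_all_phenotypes
from .multivar import select_probes, tune_penalized
from .preprocess import (
    celltype_pca,
    filter_probes_by_detection,
    logit_transform,
    transform_biomarkers,
)
from .stage1 import residualize
from .synthetic import CELL_TYPES

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    beta_tsv: str
    detp_tsv: str
    covariates_csv: str
    biomarkers_csv: str
    probes_bed: str
    genes_bed: str
    out_dir: str
    loose_threshold: float = 0.05
    strict_threshold: float = 0.01
    strict_fraction: float = 0.20
    flank: int = 100_000
    max_cluster_size: int = 300
    n_lambda: int = 20
    n_rho: int = 10
    criterion: str = "bic"
    cv_folds: int = 5
    seed: int = 0
    min_cluster_size: int = 2

    def validate(self) -> None:
        missing = [
            p
            for p in (
                self.beta_tsv,
                self.detp_tsv,
                self.covariates_csv,
                self.biomarkers_csv,
                self.probes_bed,
                self.genes_bed,
            )
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing pipeline inputs: {missing}")
        if not 0 < self.loose_threshold < 1 or not 0 < self.strict_threshold < 1:
            raise ValueError("detection thresholds must be in (0, 1)")
        if self.criterion not in ("bic", "cv"):
            raise ValueError("criterion must be 'bic' or 'cv'")


@dataclass
class RunManifest:
    version: str
    seed: int
    input_digests: dict
    stage_counts: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        seed=config.seed,
        input_digests={
            name: mio.file_digest(path)
            for name, path in [
                ("beta", config.beta_tsv),
                ("detp", config.detp_tsv),
                ("covariates", config.covariates_csv),
                ("biomarkers", config.biomarkers_csv),
                ("probes", config.probes_bed),
                ("genes", config.genes_bed),
            ]
        },
    )

    # --- QC ---------------------------------------------------------------
    beta = mio.read_matrix_tsv(config.beta_tsv)
    detp = mio.read_matrix_tsv(config.detp_tsv)
    kept, qc_report = filter_probes_by_detection(
        detp,
        loose_threshold=config.loose_threshold,
        strict_threshold=config.strict_threshold,
        strict_fraction=config.strict_fraction,
    )
    beta = beta.loc[kept]
    mio.write_json(qc_report.to_dict(), out / "qc_report.json")
    manifest.stage_counts["qc_probes_kept"] = len(kept)

    # --- transforms -------------------------------------------------------
    mvalues = logit_transform(beta)
    mio.write_matrix_tsv(mvalues, out / "mvalues.tsv")

    bio = mio.read_sample_table(config.biomarkers_csv)
    a, m, d = transform_biomarkers(
        bio["a_raw"].to_numpy(), bio["t_raw"].to_numpy(), bio["n_raw"].to_numpy()
    )
    phenotypes = pd.DataFrame({"A": a, "M": m, "D": d}, index=bio.index)
    phenotypes.to_csv(out / "phenotypes_amd.csv", index_label="sample_id")

    cov = mio.read_sample_table(config.covariates_csv)
    cell_cols = [f"cell_{c}" for c in CELL_TYPES]
    scores, explained = celltype_pca(cov[cell_cols].to_numpy())
    cov[["pc1", "pc2", "pc3"]] = scores
    manifest.stage_counts["celltype_pca_explained"] = explained

    # --- stage 1 ----------------------------------------------------------
    fit1, resid = residualize(mvalues, cov)
    mio.write_matrix_tsv(resid.T, out / "residuals.tsv")
    fit1.coefficients.to_csv(out / "stage1_coefficients.tsv", sep="\t")
    manifest.stage_counts["stage1_probes"] = resid.shape[1]

    # --- EWAS -------------------------------------------------------------
    dx = cov.loc[resid.index, "dx"].to_numpy()
    apoe4 = cov.loc[resid.index, "apoe4"].to_numpy(dtype=float)
    ewas_table, ewas_summary = scan_all_phenotypes(
        phenotypes.loc[resid.index], resid, dx, apoe4,
        correct=resid.shape[1] >= 100,
    )
    ewas_table.to_csv(out / "ewas.tsv", sep="\t", index=False)
    mio.write_json(ewas_summary, out / "ewas_summary.json")
    manifest.stage_counts["ewas_records"] = len(ewas_table)

    # --- clusters ---------------------------------------------------------
    genes = mio.read_gene_bed(config.genes_bed)
    probes = mio.read_probe_bed(config.probes_bed).loc[
        lambda df: df.index.isin(resid.columns)
    ]
    clusters = build_and_split(
        genes, probes, flank=config.flank, max_size=config.max_cluster_size
    )
    clusters = [c for c in clusters if c.size >= config.min_cluster_size]
    membership_table(clusters).to_csv(out / "clusters.tsv", sep="\t", index=False)
    manifest.stage_counts["n_clusters"] = len(clusters)
    manifest.stage_counts["median_cluster_size"] = float(
        np.median([c.size for c in clusters]) if clusters else 0
    )

    # --- multivariate fits ------------------------------------------------
    W = design_covariates(dx, apoe4)
    Y = phenotypes.loc[resid.index].to_numpy()
    cluster_fits = []
    fit_rows = []
    for cluster in clusters:
        X = np.ascontiguousarray(resid[cluster.probe_ids].to_numpy())
        fit = tune_penalized(
            Y, W, X,
            criterion=config.criterion,
            n_lambda=config.n_lambda,
            n_rho=config.n_rho,
            cv_folds=config.cv_folds,
            seed=config.seed,
        )
        cluster_fits.append((cluster.cluster_id, cluster.probe_ids, fit))
        fit_rows.append(
            {
                "cluster_id": cluster.cluster_id,
                "size": cluster.size,
                "lam": fit.lam,
                "rho": fit.rho,
                "bic": fit.bic,
                "cv_error": fit.cv_error,
                "n_nonzero": fit.n_nonzero,
            }
        )
    pd.DataFrame(fit_rows).to_csv(out / "cluster_fits.tsv", sep="\t", index=False)

    # --- selection table --------------------------------------------------
    selection = select_probes(cluster_fits)
    selection.to_csv(out / "selection_table.tsv", sep="\t")
    manifest.stage_counts["n_selected_probes"] = len(selection)

    mio.write_json(
        {
            "version": manifest.version,
            "seed": manifest.seed,
            "input_digests": manifest.input_digests,
            "stage_counts": manifest.stage_counts,
        },
        out / "manifest.json",
    )
    return manifest
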