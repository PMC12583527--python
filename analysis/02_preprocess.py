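"""QC-filter probes on detection p-values, logit-transform methylation,
build the A/M/D phenotypes, and compute cell-type PCs.

Reads the cohort written by 01_simulate_cohort.py; writes M-values,
phenotypes and augmented covariates to scratch/, plus a QC report under
results/.
"""

import json
from pathlib import Path

from mvewas import io as mio
from mvewas.preprocess import (
    celltype_pca,
    filter_probes_by_detection,
    logit_transform,
    transform_biomarkers,
)
from mvewas.synthetic import CELL_TYPES

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    beta = mio.read_matrix_tsv(COHORT / "methylation.tsv")
    detp = mio.read_matrix_tsv(COHORT / "detection_p.tsv")
    kept, report = filter_probes_by_detection(detp)
    print(
        f"QC: kept {report.n_kept}/{report.n_input} probes "
        f"(mean rule {report.removed_mean_rule}, half rule "
        f"{report.removed_half_rule}, fraction rule {report.removed_fraction_rule})"
    )
    mvalues = logit_transform(beta.loc[kept])
    mio.write_matrix_tsv(mvalues, SCRATCH / "mvalues.tsv")

    bio = mio.read_sample_table(COHORT / "biomarkers.csv")
    a, m, d = transform_biomarkers(bio["a_raw"], bio["t_raw"], bio["n_raw"])
    bio_amd = bio.assign(A=a, M=m, D=d)[["A", "M", "D"]]
    bio_amd.to_csv(SCRATCH / "phenotypes_amd.csv", index_label="sample_id")

    cov = mio.read_sample_table(COHORT / "covariates.csv")
    scores, explained = celltype_pca(cov[[f"cell_{c}" for c in CELL_TYPES]].to_numpy())
    cov[["pc1", "pc2", "pc3"]] = scores
    cov.to_csv(SCRATCH / "covariates_pcs.csv", index_label="sample_id")
    print(f"cell-type PCA: first 3 components explain {explained:.1%} of variance")

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "qc_report.json").write_text(
        json.dumps({**report.to_dict(), "pca_explained_fraction": explained}, indent=2)
    )


if __name__ == "__main__":
    main()
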