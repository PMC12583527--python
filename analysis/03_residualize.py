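"""Stage 1: regress each probe's M-values on age, sex, education, epigenetic
age acceleration and cell-type PCs; write standardized residuals.
"""

from pathlib import Path

from mvewas import io as mio
from mvewas.stage1 import residualize

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"


def main() -> None:
    mvalues = mio.read_matrix_tsv(SCRATCH / "mvalues.tsv")
    cov = mio.read_sample_table(SCRATCH / "covariates_pcs.csv")
    fit, resid = residualize(mvalues, cov)
    mio.write_matrix_tsv(resid.T, SCRATCH / "residuals.tsv")
    fit.coefficients.to_csv(SCRATCH / "stage1_coefficients.tsv", sep="\t")
    print(
        f"residualized {resid.shape[1]} probes over {resid.shape[0]} samples; "
        f"dropped {len(fit.dropped_probes)}"
    )


if __name__ == "__main__":
    main()
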