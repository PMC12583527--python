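"""Univariate EWAS of A/M/D on stage-1 residuals with mixture correction.

Writes the full record table to scratch/ and a summary (inflation factors
before/after correction, significance counts) to results/.
"""

import json
from pathlib import Path

from mvewas import io as mio
from mvewas.ewas import scan_all_phenotypes

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    resid = mio.read_matrix_tsv(SCRATCH / "residuals.tsv").T
    phenotypes = mio.read_sample_table(SCRATCH / "phenotypes_amd.csv")
    cov = mio.read_sample_table(SCRATCH / "covariates_pcs.csv")
    dx = cov.loc[resid.index, "dx"].to_numpy()
    apoe4 = cov.loc[resid.index, "apoe4"].to_numpy(dtype=float)

    table, summary = scan_all_phenotypes(
        phenotypes.loc[resid.index], resid, dx, apoe4,
        correct=resid.shape[1] >= 100,
    )
    table.to_csv(SCRATCH / "ewas.tsv", sep="\t", index=False)
    sig_counts = (
        table.groupby(["phenotype", "significance"]).size().unstack(fill_value=0)
    )
    summary["significance_counts"] = {
        ph: row.to_dict() for ph, row in sig_counts.iterrows()
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "ewas_summary.json").write_text(json.dumps(summary, indent=2))
    for ph, info in summary.items():
        if isinstance(info, dict) and "lambda_before" in info:
            after = info.get("lambda_after")
            print(
                f"{ph}: lambda_gc {info['lambda_before']:.3f}"
                + (f" -> {after:.3f} after correction" if after else "")
            )


if __name__ == "__main__":
    main()
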