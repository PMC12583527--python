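"""Build gene-anchored probe clusters (gene body +/- 100 kb, <= 300 probes).

Writes the membership table to scratch/ and a size summary to results/.
"""

import json
from pathlib import Path

import numpy as np

from mvewas import io as mio
from mvewas.clusters import build_and_split, coverage_fraction, membership_table

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    genes = mio.read_gene_bed(COHORT / "genes.bed")
    probes = mio.read_probe_bed(COHORT / "probes.bed")
    resid = mio.read_matrix_tsv(SCRATCH / "residuals.tsv")
    probes = probes.loc[probes.index.isin(resid.index)]

    clusters = build_and_split(genes, probes, flank=100_000, max_size=300)
    membership_table(clusters).to_csv(SCRATCH / "clusters.tsv", sep="\t", index=False)
    sizes = [c.size for c in clusters]
    summary = {
        "n_clusters": len(clusters),
        "median_size": float(np.median(sizes)),
        "max_size": int(max(sizes)),
        "coverage_fraction": coverage_fraction(clusters, probes),
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "cluster_summary.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
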