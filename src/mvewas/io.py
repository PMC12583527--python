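"""Plain-text readers/writers for the pipeline's stage files.

All intermediates are TSV/CSV/BED/JSON so every stage can be re-run from
disk. Floats are serialized with shortest-roundtrip repr, so a write/read
cycle reproduces values to full precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd


def read_matrix_tsv(path) -> pd.DataFrame:
    """Probe-by-sample matrix TSV: first column is the probe id.

    Uses round-trip float parsing so written matrices read back exactly.
    """
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "probe_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_bed(path, name_col: str = "name") -> pd.DataFrame:
    """BED (0-based, half-open): chrom, start, end, name; indexed by name."""
    bed = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", name_col],
    )
    return bed.set_index(name_col)


def read_probe_bed(path) -> pd.DataFrame:
    """Probe BED of single-base intervals -> (chrom, pos) per probe."""
    bed = read_bed(path, name_col="probe_id")
    if (bed["end"] - bed["start"] != 1).any():
        raise ValueError("probe BED must contain single-base intervals")
    return pd.DataFrame({"chrom": bed["chrom"], "pos": bed["start"]}, index=bed.index)


def read_gene_bed(path) -> pd.DataFrame:
    return read_bed(path, name_col="gene_id")


def read_sample_table(path) -> pd.DataFrame:
    """CSV indexed by sample_id (covariates or biomarkers)."""
    return pd.read_csv(path, index_col=0)


def write_json(obj, path) -> None:
    def default(x):
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
        raise TypeError(f"not JSON serializable: {type(x)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def file_digest(path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()
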