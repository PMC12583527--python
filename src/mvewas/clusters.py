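"""Gene-anchored probe clustering.

Each gene defines a window covering its body plus 100 kb flanks; every
probe whose position falls in the window joins that gene's cluster (probes
can belong to several clusters). Clusters larger than a size cap are split
into consecutive, genomically ordered parts of near-equal size. Coordinates
follow the BED convention: 0-based, half-open windows, closed on the left.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd


@dataclass
class GeneCluster:
    cluster_id: str
    gene_id: str
    chrom: str
    probe_ids: list  # ordered by genomic position
    positions: np.ndarray  # matching probe order
    window: tuple[int, int]  # [start - flank, end + flank)

    @property
    def size(self) -> int:
        return len(self.probe_ids)


def build_gene_clusters(
    genes: pd.DataFrame,
    probes: pd.DataFrame,
    flank: int = 100_000,
) -> list[GeneCluster]:
    """Assign probes to gene windows.

    ``genes``: indexed by gene_id with columns chrom, start, end (0-based,
    half-open, start < end). ``probes``: indexed by probe_id with columns
    chrom, pos (single-base positions). Probes on chromosomes absent from
    the gene table raise, listing the offenders. Genes with empty windows
    are dropped.
    """
    if (genes["start"] >= genes["end"]).any():
        raise ValueError("gene intervals must satisfy start < end")
    gene_chroms = set(genes["chrom"])
    unknown = sorted(set(probes["chrom"]) - gene_chroms)
    if unknown:
        offenders = probes.index[probes["chrom"].isin(unknown)].tolist()
        raise ValueError(
            f"probes on chromosomes absent from the gene annotation {unknown}: "
            f"{offenders[:10]}{'...' if len(offenders) > 10 else ''}"
        )

    clusters: list[GeneCluster] = []
    for chrom, probes_c in probes.groupby("chrom", sort=False):
        order = np.argsort(probes_c["pos"].to_numpy(), kind="stable")
        pos = probes_c["pos"].to_numpy()[order]
        ids = probes_c.index.to_numpy()[order]
        for gene_id, g in genes[genes["chrom"] == chrom].iterrows():
            lo = int(g["start"]) - flank
            hi = int(g["end"]) + flank
            i0, i1 = np.searchsorted(pos, [lo, hi], side="left")
            if i1 > i0:
                clusters.append(
                    GeneCluster(
                        cluster_id=str(gene_id),
                        gene_id=str(gene_id),
                        chrom=str(chrom),
                        probe_ids=list(ids[i0:i1]),
                        positions=pos[i0:i1].copy(),
                        window=(lo, hi),
                    )
                )
    return clusters


def split_cluster(cluster: GeneCluster, max_size: int = 300) -> list[GeneCluster]:
    """Split an oversized cluster into balanced consecutive parts.

    Uses k = ceil(size / max_size) parts with sizes differing by at most
    one, preserving genomic order; an under-cap cluster is returned as-is.
    Parts are named ``gene#1..#k`` in genomic order.
    """
    if cluster.size <= max_size:
        return [cluster]
    k = ceil(cluster.size / max_size)
    base, extra = divmod(cluster.size, k)
    sizes = [base + 1] * extra + [base] * (k - extra)
    parts = []
    start = 0
    for i, sz in enumerate(sizes, start=1):
        stop = start + sz
        parts.append(
            GeneCluster(
                cluster_id=f"{cluster.gene_id}#{i}",
                gene_id=cluster.gene_id,
                chrom=cluster.chrom,
                probe_ids=cluster.probe_ids[start:stop],
                positions=cluster.positions[start:stop].copy(),
                window=cluster.window,
            )
        )
        start = stop
    return parts


def build_and_split(
    genes: pd.DataFrame,
    probes: pd.DataFrame,
    flank: int = 100_000,
    max_size: int = 300,
) -> list[GeneCluster]:
    """Full clustering pass: window assignment followed by size capping."""
    out: list[GeneCluster] = []
    for cluster in build_gene_clusters(genes, probes, flank=flank):
        out.extend(split_cluster(cluster, max_size=max_size))
    return out


def membership_table(clusters: list[GeneCluster]) -> pd.DataFrame:
    """Long-format cluster membership (cluster_id, probe_id, chrom, pos)."""
    rows = [
        (c.cluster_id, pid, c.chrom, int(p))
        for c in clusters
        for pid, p in zip(c.probe_ids, c.positions)
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "probe_id", "chrom", "pos"])


def coverage_fraction(clusters: list[GeneCluster], probes: pd.DataFrame) -> float:
    """Fraction of probes that landed in at least one cluster."""
    covered = {pid for c in clusters for pid in c.probe_ids}
    return len(covered) / len(probes)
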