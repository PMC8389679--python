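"""Descriptive statistics over a populated result store.

All three operations are pure functions of the store: per-chromosome SNP /
gene / rSNP counts, average rSNPs per gene split into upstream and
downstream promoter halves, and TSS-distance histograms of rSNP positions
(whole promoter in 500 bp bins, proximal promoter in 50 bp bins, both
configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .store import ResultStore


def per_chromosome_counts(store: ResultStore) -> pd.DataFrame:
    """Counts of SNPs, genes and rSNPs by chromosome.

    A SNP counts as regulatory when it has at least one loss, gain or
    score-change site.  Chromosomes are sorted naturally (numeric names
    numerically, the rest lexically).
    """
    snps = store.table("snp_info")
    genes = store.table("gene_info")
    rsnp_ids = store.rsnp_ids()
    chroms = sorted(set(snps.chrom) | set(genes.chrom),
                    key=lambda c: (0, int(c)) if str(c).isdigit() else (1, c))
    rows = []
    for chrom in chroms:
        chrom_snps = snps[snps.chrom == chrom]
        rows.append({
            "chrom": chrom,
            "n_snps": chrom_snps.snp_id.nunique(),
            "n_genes": genes[genes.chrom == chrom].gene_id.nunique(),
            "n_rsnps": chrom_snps[chrom_snps.snp_id.isin(rsnp_ids)].snp_id.nunique(),
        })
    return pd.DataFrame(rows, columns=["chrom", "n_snps", "n_genes", "n_rsnps"])


def rsnps_per_gene(store: ResultStore) -> tuple[pd.DataFrame, float]:
    """Average rSNPs per gene by chromosome, split up/downstream of the TSS.

    Upstream means ``dist_tss < 0``, downstream ``dist_tss >= 0`` (the TSS
    base counts as downstream).  Genes with no rSNPs enter the means as
    zeros.  The overall mean is total distinct rSNP–gene pairs divided by
    total genes.
    """
    genes = store.table("gene_info")
    region = store.table("snp_region")
    rsnp_region = region[region.snp_id.isin(store.rsnp_ids())]
    pairs = rsnp_region.drop_duplicates(["snp_id", "gene_id"])
    per_gene = pd.DataFrame({"gene_id": genes.gene_id, "chrom": genes.chrom})
    up = pairs[pairs.dist_tss < 0].groupby("gene_id").size()
    down = pairs[pairs.dist_tss >= 0].groupby("gene_id").size()
    per_gene["n_up"] = per_gene.gene_id.map(up).fillna(0).astype(int)
    per_gene["n_down"] = per_gene.gene_id.map(down).fillna(0).astype(int)
    by_chrom = per_gene.groupby("chrom").agg(
        mean_up=("n_up", "mean"), sd_up=("n_up", "std"),
        mean_down=("n_down", "mean"), sd_down=("n_down", "std"),
    ).reset_index()
    n_genes = len(genes)
    overall_mean = len(pairs) / n_genes if n_genes else 0.0
    return by_chrom, overall_mean


@dataclass(frozen=True)
class DistanceHistogram:
    """rSNP counts by signed TSS distance in fixed-width half-open bins."""

    bin_width: int
    lo: int
    hi: int
    edges: np.ndarray  # len n_bins + 1
    counts: np.ndarray  # len n_bins

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_start": self.edges[:-1],
                             "bin_end": self.edges[1:],
                             "count": self.counts})


def distance_histogram(store: ResultStore, bin_width: int = 500,
                       lo: int = -7500, hi: int = 2500) -> DistanceHistogram:
    """Histogram of rSNP snp_region distances over ``[lo, hi)``.

    ``bin_width`` must divide ``hi - lo``; bins are half-open
    ``[edge, edge + bin_width)`` ascending from ``lo``.
    """
    span = hi - lo
    if span <= 0 or span % bin_width != 0:
        raise ValueError(f"bin width {bin_width} does not divide range "
                         f"[{lo}, {hi})")
    region = store.table("snp_region")
    dist = region[region.snp_id.isin(store.rsnp_ids())].dist_tss.to_numpy()
    dist = dist[(dist >= lo) & (dist < hi)]
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(dist, bins=edges)
    return DistanceHistogram(bin_width, lo, hi, edges, counts)


def plot_distance_histogram(hist: DistanceHistogram, path: str) -> None:
    """Optional bar-plot artifact for a distance histogram."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(hist.edges[:-1], hist.counts, width=hist.bin_width, align="edge",
           edgecolor="white")
    ax.set_xlabel("distance to TSS (bp)")
    ax.set_ylabel("rSNP count")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
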