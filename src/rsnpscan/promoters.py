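"""Strand-aware promoter windows and SNP-to-promoter assignment.

The promoter of a transcript is the interval from ``upstream_bp`` before to
``downstream_bp`` after its TSS, measured in the direction of transcription
(defaults 7500 and 2500, i.e. a 10 kb window).  SNP positions inside a
window are reported with a signed TSS distance: negative upstream of the
TSS, 0 at the TSS base, positive downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .genomic import SnpRecord, TranscriptTss

DEFAULT_UPSTREAM_BP = 7500
DEFAULT_DOWNSTREAM_BP = 2500


@dataclass(frozen=True)
class PromoterWindow:
    """A transcript's promoter as a closed 1-based genomic interval."""

    transcript: TranscriptTss
    upstream_bp: int
    downstream_bp: int
    start: int
    end: int

    @property
    def tss(self) -> int:
        return self.transcript.tss

    def to_bed(self) -> str:
        """One BED line (0-based half-open) for this window."""
        t = self.transcript
        return (f"{t.chrom}\t{self.start - 1}\t{self.end}\t"
                f"{t.gene_id}|{t.transcript_id}\t0\t{t.strand}")


@dataclass(frozen=True)
class SnpRegionRow:
    """A SNP assigned to one promoter, with its signed TSS distance."""

    snp_id: str
    gene_id: str
    transcript_id: str
    dist_tss: int


def promoter_window(t: TranscriptTss,
                    upstream_bp: int = DEFAULT_UPSTREAM_BP,
                    downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
                    chrom_length: int | None = None) -> PromoterWindow:
    """Resolve a transcript's promoter to genomic coordinates.

    On the + strand the window is ``[tss - upstream_bp, tss + downstream_bp]``;
    on the − strand it is mirrored.  Bounds are clipped to
    ``[1, chrom_length]``.
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("window extents must be non-negative")
    if t.strand == "+":
        start, end = t.tss - upstream_bp, t.tss + downstream_bp
    else:
        start, end = t.tss - downstream_bp, t.tss + upstream_bp
    start = max(1, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return PromoterWindow(t, upstream_bp, downstream_bp, start, end)


def signed_tss_distance(window: PromoterWindow, pos: int) -> int:
    """Distance from ``pos`` to the TSS in the direction of transcription."""
    t = window.transcript
    return pos - t.tss if t.strand == "+" else t.tss - pos


def overlap_snps(windows: list[PromoterWindow],
                 snps: list[SnpRecord]) -> list[SnpRegionRow]:
    """Assign every SNP to every promoter window that contains it.

    A SNP inside k overlapping promoters yields k rows.  Uses a per-
    chromosome interval index; output order follows the input SNP order.
    """
    trees: dict[str, IntervalTree] = {}
    for w in windows:
        # IntervalTree is half-open; +1 converts the closed end
        trees.setdefault(w.transcript.chrom, IntervalTree()).addi(
            w.start, w.end + 1, w)
    rows: list[SnpRegionRow] = []
    for snp in snps:
        tree = trees.get(snp.chrom)
        if tree is None:
            continue
        hits = sorted(tree[snp.pos],
                      key=lambda iv: (iv.data.transcript.gene_id,
                                      iv.data.transcript.transcript_id))
        for iv in hits:
            w: PromoterWindow = iv.data
            rows.append(SnpRegionRow(
                snp_id=snp.snp_id,
                gene_id=w.transcript.gene_id,
                transcript_id=w.transcript.transcript_id,
                dist_tss=signed_tss_distance(w, snp.pos),
            ))
    return rows
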