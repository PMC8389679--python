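"""Allele flank extraction and two-allele, two-strand PWM scanning.

For every promoter SNP a pair of 51-bp sequences is built — reference and
alternate allele, SNP at position 26 — and scanned against the PWM library
on both strands.  Hits must clear both score cutoffs and must overlap the
SNP base: a site that does not cover the SNP is identical on both alleles
and can never contribute a consequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .genomic import SnpRecord
from .pwm import PWM, encode_sequence, score_windows

logger = logging.getLogger(__name__)

DEFAULT_HALF_WIDTH = 25

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AllelePair:
    """Reference/alternate flank sequences centred on one SNP."""

    snp_id: str
    ref_seq: str
    alt_seq: str
    snp_index: int  # 1-based position of the SNP within the sequences

    def __post_init__(self) -> None:
        if len(self.ref_seq) != len(self.alt_seq):
            raise ValueError(f"{self.snp_id}: allele sequences differ in length")


@dataclass(frozen=True)
class Discard:
    """A SNP dropped before scanning, with the reason ('short', 'gap',
    'ref-mismatch')."""

    snp_id: str
    reason: str


@dataclass(frozen=True)
class SiteHit:
    """One predicted TFBS on one allele, in forward-flank coordinates."""

    pwm_id: str
    start: int  # 1-based offset of the site within the flank
    strand: str
    mss: float
    css: float

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.pwm_id, self.start, self.strand)


def extract_flanks(genome, snp: SnpRecord,
                   half_width: int = DEFAULT_HALF_WIDTH) -> AllelePair | Discard:
    """Build the ref/alt flank pair for one SNP from an indexed genome.

    Returns a :class:`Discard` when the window is truncated by a chromosome
    end ('short'), contains a non-ACGT base ('gap'), or the genome base at
    the SNP position differs from the declared reference allele
    ('ref-mismatch' — a catalog/assembly version drift signal).
    """
    chrom = genome[snp.chrom]
    lo, hi = snp.pos - half_width, snp.pos + half_width
    if lo < 1 or hi > len(chrom):
        logger.info("%s: flank truncated by chromosome end, discarded (short)",
                    snp.snp_id)
        return Discard(snp.snp_id, "short")
    seq = str(chrom[lo - 1:hi]).upper()
    if any(c not in "ACGT" for c in seq):
        logger.info("%s: flank contains gap/ambiguity, discarded (gap)",
                    snp.snp_id)
        return Discard(snp.snp_id, "gap")
    snp_index = half_width + 1
    if seq[snp_index - 1] != snp.ref:
        logger.warning("%s: genome base %s != declared ref %s, skipped "
                       "(ref-mismatch)", snp.snp_id, seq[snp_index - 1], snp.ref)
        return Discard(snp.snp_id, "ref-mismatch")
    alt_seq = seq[:snp_index - 1] + snp.alt + seq[snp_index:]
    return AllelePair(snp.snp_id, seq, alt_seq, snp_index)


def _scan_sequence(library: list[PWM], seq: str, snp_index: int,
                   require_snp_overlap: bool = True) -> list[SiteHit]:
    """Score every (pwm, offset, strand) on one sequence; apply cutoffs and
    the SNP-overlap filter; report − strand hits in forward coordinates."""
    n = len(seq)
    fwd = encode_sequence(seq)
    rev = encode_sequence(reverse_complement(seq))
    hits: list[SiteHit] = []
    for pwm in library:
        L = pwm.width
        if L > n:
            logger.warning("%s: width %d exceeds flank length %d, skipped",
                           pwm.id, L, n)
            continue
        for strand, codes in (("+", fwd), ("-", rev)):
            windows = sliding_window_view(codes, L)
            mss, css = score_windows(pwm, windows)
            keep = np.flatnonzero((mss >= pwm.mss_cutoff) & (css >= pwm.css_cutoff))
            for j in keep:
                # map a reverse-complement offset back to forward coordinates
                start = int(j) + 1 if strand == "+" else n - L - int(j) + 1
                if require_snp_overlap and not (start <= snp_index <= start + L - 1):
                    continue
                hits.append(SiteHit(pwm.id, start, strand,
                                    float(mss[j]), float(css[j])))
    hits.sort(key=lambda h: h.key)
    return hits


def scan_alleles(library: list[PWM], pair: AllelePair,
                 require_snp_overlap: bool = True,
                 ) -> tuple[list[SiteHit], list[SiteHit]]:
    """Predict TFBSs on both alleles of a flank pair.

    Returns ``(ref_hits, alt_hits)``.  Both strands are scanned; hits whose
    span does not cover the SNP are dropped unless
    ``require_snp_overlap=False``.
    """
    if not library:
        raise ValueError("empty PWM library")
    ref_hits = _scan_sequence(library, pair.ref_seq, pair.snp_index,
                              require_snp_overlap)
    alt_hits = _scan_sequence(library, pair.alt_seq, pair.snp_index,
                              require_snp_overlap)
    return ref_hits, alt_hits
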