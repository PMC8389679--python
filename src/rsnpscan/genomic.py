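"""Readers for the three genomic inputs: genome, annotation, SNP catalog.

Coordinates are 1-based and fully closed throughout the package (the
VCF/GFF convention); any BED export is converted to 0-based half-open at
the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pyfaidx
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class TranscriptTss:
    """One transcription start site anchored to a transcript.

    The TSS is the annotation start on the + strand and the end on the −
    strand.  ``gene_start``/``gene_end`` carry the parent gene's span when
    the annotation provides one (used to populate the gene table).
    """

    gene_id: str
    gene_name: str
    transcript_id: str
    chrom: str
    strand: str
    tss: int
    gene_start: int | None = None
    gene_end: int | None = None


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic single-nucleotide substitution."""

    snp_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
            raise ValueError(f"{self.snp_id}: not a single-base substitution")


def open_genome(path: str | Path) -> pyfaidx.Fasta:
    """Open an indexed FASTA for random access (index built on first use)."""
    return pyfaidx.Fasta(str(path), sequence_always_upper=True)


def _attr(feature: gffutils.Feature, *keys: str) -> str | None:
    for key in keys:
        if key in feature.attributes:
            return feature.attributes[key][0]
    return None


def load_transcripts(annotation: str | Path,
                     valid_chroms: set[str] | None = None,
                     ) -> list[TranscriptTss]:
    """Extract one TSS entry per distinct transcript start.

    Accepts GFF3 or GTF.  Isoforms of the same gene sharing (chrom, strand,
    TSS) are collapsed to a single entry — they define the same promoter —
    while isoforms with distinct TSSs are kept separate.  Records with an
    unknown strand, or on a chromosome absent from ``valid_chroms`` when
    given, are skipped with a warning.
    """
    db = gffutils.create_db(
        str(annotation), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    gene_spans: dict[str, tuple[int, int]] = {}
    gene_names: dict[str, str] = {}
    for gene in db.features_of_type(("gene",)):
        gid = _attr(gene, "gene_id", "ID") or gene.id
        gene_spans[gid] = (gene.start, gene.end)
        gene_names[gid] = _attr(gene, "gene_name", "Name") or gid

    entries: list[TranscriptTss] = []
    seen: set[tuple[str, str, str, int]] = set()
    for tx in db.features_of_type(("transcript", "mRNA")):
        tx_id = _attr(tx, "transcript_id", "ID") or tx.id
        if tx.strand not in ("+", "-"):
            logger.warning("transcript %s: missing strand, skipped", tx_id)
            continue
        if valid_chroms is not None and tx.seqid not in valid_chroms:
            logger.warning("transcript %s: unknown chromosome %s, skipped",
                           tx_id, tx.seqid)
            continue
        gid = _attr(tx, "gene_id", "Parent") or tx.id
        tss = tx.start if tx.strand == "+" else tx.end
        key = (gid, tx.seqid, tx.strand, tss)
        if key in seen:  # isoform with an identical promoter
            continue
        seen.add(key)
        span = gene_spans.get(gid)
        entries.append(TranscriptTss(
            gene_id=gid,
            gene_name=gene_names.get(gid, gid),
            transcript_id=tx_id,
            chrom=tx.seqid,
            strand=tx.strand,
            tss=tss,
            gene_start=span[0] if span else None,
            gene_end=span[1] if span else None,
        ))
    return entries


def load_snps(vcf_path: str | Path) -> list[SnpRecord]:
    """Load single-nucleotide substitutions from a VCF.

    Insertions, deletions and symbolic alleles are discarded (counted in the
    log); multiallelic records are decomposed into one record per alternate
    allele.  Records without an rs-style id get a ``chrom:pos:ref:alt``
    synthetic id.
    """
    records: list[SnpRecord] = []
    n_discarded = 0
    for variant in VCF(str(vcf_path)):
        ref = variant.REF.upper()
        for alt in variant.ALT:
            alt = alt.upper()
            if (len(ref) != 1 or len(alt) != 1
                    or ref not in _VALID_ALLELES or alt not in _VALID_ALLELES):
                n_discarded += 1
                continue
            snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}:{ref}:{alt}"
            records.append(SnpRecord(snp_id, variant.CHROM, variant.POS, ref, alt))
    if n_discarded:
        logger.info("discarded %d non-SNP allele pairs (indels/symbolic)",
                    n_discarded)
    return records
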