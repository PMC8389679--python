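"""End-to-end pipeline: inputs -> promoter SNPs -> allele scan -> store.

The driver behind the ``scan`` CLI command and the programmatic entry
point.  Steps: load the genome, annotation, SNP catalog and PWM library;
build strand-aware promoter windows; assign SNPs to promoters; extract the
51-bp allele flanks of every promoter SNP; scan both alleles and both
strands; classify each affected site; write the four result tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .consequences import ConsequenceRecord, classify
from .genomic import SnpRecord, load_snps, load_transcripts, open_genome
from .promoters import (DEFAULT_DOWNSTREAM_BP, DEFAULT_UPSTREAM_BP,
                        overlap_snps, promoter_window)
from .pwm import (DEFAULT_CSS_CUTOFF, DEFAULT_MSS_CUTOFF, parse_pwm_library,
                  read_cutoff_profile)
from .scanner import DEFAULT_HALF_WIDTH, AllelePair, extract_flanks, scan_alleles
from .store import GeneInfo, ResultStore

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Row counts plus bookkeeping from one pipeline run."""

    counts: dict[str, int]
    n_rsnps: int
    discarded: dict[str, int] = field(default_factory=dict)


def run_pipeline(genome_path: str | Path,
                 annotation_path: str | Path,
                 vcf_path: str | Path,
                 pwm_path: str | Path,
                 store: ResultStore,
                 *,
                 dialect: str = "transfac",
                 upstream_bp: int = DEFAULT_UPSTREAM_BP,
                 downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
                 half_width: int = DEFAULT_HALF_WIDTH,
                 mss_cutoff: float = DEFAULT_MSS_CUTOFF,
                 css_cutoff: float = DEFAULT_CSS_CUTOFF,
                 cutoff_profile_path: str | Path | None = None,
                 ) -> PipelineResult:
    """Run the full detection pipeline and populate ``store``."""
    profile = None
    if cutoff_profile_path is not None:
        profile = read_cutoff_profile(Path(cutoff_profile_path).read_text())
    library = parse_pwm_library(Path(pwm_path).read_text(), dialect,
                                mss_cutoff=mss_cutoff, css_cutoff=css_cutoff,
                                cutoff_profile=profile)
    genome = open_genome(genome_path)
    chrom_lengths = {name: len(genome[name]) for name in genome.keys()}
    transcripts = load_transcripts(annotation_path,
                                   valid_chroms=set(chrom_lengths))
    snps = load_snps(vcf_path)

    windows = [promoter_window(t, upstream_bp, downstream_bp,
                               chrom_lengths[t.chrom]) for t in transcripts]
    regions = overlap_snps(windows, snps)
    in_promoter = {r.snp_id for r in regions}

    snp_by_id: dict[str, list[SnpRecord]] = {}
    for snp in snps:
        if snp.snp_id in in_promoter:
            snp_by_id.setdefault(snp.snp_id, []).append(snp)

    tfbs: list[ConsequenceRecord] = []
    rsnp_ids: set[str] = set()
    discarded: dict[str, int] = {}
    kept_snps: list[SnpRecord] = []
    for snp_id in sorted(snp_by_id):
        for snp in snp_by_id[snp_id]:
            pair = extract_flanks(genome, snp, half_width)
            if not isinstance(pair, AllelePair):
                discarded[pair.reason] = discarded.get(pair.reason, 0) + 1
                continue
            kept_snps.append(snp)
            records = classify(*scan_alleles(library, pair), snp_id=snp.snp_id)
            tfbs.extend(records)
            if any(r.consequence != "no_effect" for r in records):
                rsnp_ids.add(snp.snp_id)

    kept_ids = {s.snp_id for s in kept_snps}
    regions = [r for r in regions if r.snp_id in kept_ids]
    # one snp_region row per (snp, promoter); drop duplicates from
    # multiallelic decomposition sharing one id
    seen = set()
    unique_regions = []
    for r in regions:
        key = (r.snp_id, r.gene_id, r.transcript_id)
        if key not in seen:
            seen.add(key)
            unique_regions.append(r)

    gene_rows: dict[str, GeneInfo] = {}
    for t in transcripts:
        gene_rows.setdefault(t.gene_id, GeneInfo(
            t.gene_id, t.gene_name, t.chrom, t.gene_start, t.gene_end, t.strand))

    counts = store.write_results(
        kept_snps, list(gene_rows.values()), unique_regions, tfbs)
    if discarded:
        logger.info("discarded flanks: %s", discarded)
    return PipelineResult(counts=counts, n_rsnps=len(rsnp_ids),
                          discarded=discarded)
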