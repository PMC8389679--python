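"""Synthetic genome / annotation / SNP / PWM fixtures with planted truth.

The generator emulates the pipeline's study conditions at desk scale: a few
short chromosomes of i.i.d. background sequence, non-overlapping genes with
10 kb promoters, a small TRANSFAC-dialect PWM library, and a SNP catalog in
which chosen SNPs are *planted* to produce a known consequence:

* **loss** — a PWM consensus is written across the SNP; the reference
  allele completes the consensus (MSS = 1) while the alternate allele
  drops the MSS below cutoff.
* **gain** — the mirror image: the genome carries one mismatch and the
  alternate allele restores the consensus.
* **score_change** — one matrix carries a moderately informative column
  outside its core; swapping its two frequent bases moves the MSS a little
  while both alleles stay above both cutoffs.

Planted motif columns are near-deterministic (0.91 / 3 x 0.03) so a single
mismatch reliably crosses the default cutoffs; the score-change column uses
0.46 / 0.44 / 2 x 0.05.  Every planted and neutral SNP is verified against
the real scanner at generation time; flank background is deterministically
resampled if a chance background hit would blur the planted truth, so the
manifest is exact by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .consequences import classify
from .genomic import SnpRecord
from .promoters import DEFAULT_DOWNSTREAM_BP, DEFAULT_UPSTREAM_BP
from .pwm import BASES, PWM, write_transfac
from .scanner import AllelePair, extract_flanks, reverse_complement, scan_alleles

_STRONG = 0.91
_WEAK_PAIR = (0.46, 0.44)
_MOTIF_WIDTH = 10
_WEAK_COL = 8  # 1-based; outside the 5-position core
_MIN_SNP_SPACING = 120
_EDGE_MARGIN = 100


@dataclass
class PlantedEvent:
    """Ground truth for one planted SNP."""

    snp_id: str
    pwm_id: str
    strand: str
    expected_consequence: str
    dist_tss: int
    chrom: str
    pos: int
    gene_id: str


@dataclass
class FixtureManifest:
    """Everything a test needs to check pipeline output exactly."""

    seed: int
    params: dict
    per_chrom: dict[str, dict[str, int]]
    events: list[PlantedEvent] = field(default_factory=list)
    neutral_snp_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FixtureManifest":
        d = json.loads(text)
        d["events"] = [PlantedEvent(**e) for e in d["events"]]
        return cls(**d)


def _random_strong_pwm(rng: np.random.Generator, pwm_id: str,
                       taken: set[str]) -> PWM:
    """A width-10 matrix with near-deterministic columns and a consensus
    distinct (and non-palindromic) w.r.t. every consensus already taken."""
    while True:
        cons = "".join(rng.choice(list(BASES), size=_MOTIF_WIDTH))
        if cons == reverse_complement(cons):
            continue
        if cons in taken or reverse_complement(cons) in taken:
            continue
        taken.add(cons)
        freq = np.full((_MOTIF_WIDTH, 4), (1 - _STRONG) / 3)
        for i, b in enumerate(cons):
            freq[i, BASES.index(b)] = _STRONG
        return PWM(pwm_id, freq)


def _weaken_column(pwm: PWM, col: int, rng: np.random.Generator) -> PWM:
    """Replace one column with the 0.46/0.44/0.05/0.05 score-change column."""
    freq = pwm.freq.copy()
    major = int(freq[col - 1].argmax())
    minor = int(rng.choice([b for b in range(4) if b != major]))
    newcol = np.full(4, 0.05)
    newcol[major], newcol[minor] = _WEAK_PAIR
    freq[col - 1] = newcol
    return PWM(pwm.id, freq, pwm.mss_cutoff, pwm.css_cutoff)


def make_library(rng: np.random.Generator, n_pwms: int) -> list[PWM]:
    """n_pwms matrices; the first one carries the weak score-change column."""
    taken: set[str] = set()
    library = [_random_strong_pwm(rng, f"V$SYN{i:02d}_01", taken)
               for i in range(n_pwms)]
    library[0] = _weaken_column(library[0], _WEAK_COL, rng)
    return library


class _MutableGenome:
    """Per-chromosome mutable sequence, sliceable like an indexed FASTA."""

    def __init__(self, chroms: dict[str, bytearray]) -> None:
        self.chroms = chroms

    def __getitem__(self, chrom: str) -> str:
        return self.chroms[chrom].decode()

    def set_base(self, chrom: str, pos: int, base: str) -> None:
        self.chroms[chrom][pos - 1] = ord(base)

    def write_segment(self, chrom: str, start: int, segment: str) -> None:
        self.chroms[chrom][start - 1:start - 1 + len(segment)] = segment.encode()


def _expected_records_ok(event_kind: str | None, pwm_id: str | None,
                         strand: str | None, records) -> bool:
    if event_kind is None:  # neutral SNP: no affected site at all
        return len(records) == 0
    if len(records) != 1:
        return False
    rec = records[0]
    return (rec.consequence == event_kind and rec.pwm_id == pwm_id
            and rec.strand == strand)


def make_fixture(seed: int,
                 out_dir: str | Path,
                 n_chroms: int = 3,
                 chrom_len: int = 60_000,
                 n_genes: int = 6,
                 n_snps: int = 30,
                 n_pwms: int = 8,
                 plant_spec: dict[str, int] | None = None,
                 upstream_bp: int = DEFAULT_UPSTREAM_BP,
                 downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
                 ) -> FixtureManifest:
    """Write FASTA, GFF3, VCF, TRANSFAC PWM file and a JSON manifest.

    Deterministic under ``seed`` (same seed, byte-identical files).  Raises
    before writing anything if the requested geometry cannot hold the
    requested genes/SNPs, or if a planted event cannot be isolated from
    chance background hits after bounded resampling.
    """
    if plant_spec is None:
        plant_spec = {"loss": 5, "gain": 5, "score_change": 5}
    n_planted = sum(plant_spec.values())
    if any(v < 0 for v in plant_spec.values()):
        raise ValueError("plant_spec counts must be non-negative")
    if set(plant_spec) - {"loss", "gain", "score_change"}:
        raise ValueError(f"unknown consequence class in plant_spec: {plant_spec}")
    if n_planted > n_snps:
        raise ValueError(f"plant_spec wants {n_planted} SNPs but n_snps={n_snps}")
    if _MOTIF_WIDTH > 2 * 25 + 1:
        raise ValueError("motif wider than the flank can never cover the SNP")

    span = upstream_bp + downstream_bp + 1
    slot = span + 2 * _EDGE_MARGIN + 500
    genes_per_chrom = [n_genes // n_chroms + (1 if c < n_genes % n_chroms else 0)
                       for c in range(n_chroms)]
    if max(genes_per_chrom) * slot + 1000 > chrom_len:
        raise ValueError("chrom_len too small for the requested promoters")

    rng = np.random.default_rng(seed)
    library = make_library(rng, n_pwms)
    pwm_by_id = {p.id: p for p in library}

    chrom_names = [f"chr{c + 1}" for c in range(n_chroms)]
    genome = _MutableGenome({
        name: bytearray("".join(rng.choice(list(BASES), size=chrom_len)).encode())
        for name in chrom_names})

    # -- genes with disjoint promoters ------------------------------------
    genes = []  # (gene_id, gene_name, tx_id, chrom, strand, tss, start, end)
    gi = 0
    for c, name in enumerate(chrom_names):
        for k in range(genes_per_chrom[c]):
            region_start = 1000 + k * slot
            strand = str(rng.choice(["+", "-"]))
            if strand == "+":
                tss = region_start + upstream_bp
                g_start, g_end = tss, min(tss + 1999, chrom_len)
            else:
                tss = region_start + downstream_bp
                g_start, g_end = max(1, tss - 1999), tss
            genes.append((f"GENE{gi:03d}", f"GN{gi:03d}", f"TX{gi:03d}",
                          name, strand, tss, g_start, g_end))
            gi += 1

    # -- SNP slots per gene ------------------------------------------------
    kinds = ([k for k, v in sorted(plant_spec.items()) for _ in range(v)]
             + [None] * (n_snps - n_planted))
    rng.shuffle(kinds)
    gene_of = [i % len(genes) for i in range(n_snps)]
    grid = np.arange(-upstream_bp + _EDGE_MARGIN,
                     downstream_bp - _EDGE_MARGIN, _MIN_SNP_SPACING)
    per_gene_n = [gene_of.count(g) for g in range(len(genes))]
    if max(per_gene_n) > len(grid):
        raise ValueError("too many SNPs per promoter for the spacing grid")
    slot_queues: list[list[int]] = []
    for g in range(len(genes)):
        chosen = rng.choice(grid, size=per_gene_n[g], replace=False)
        slot_queues.append([int(d) for d in np.sort(chosen)])
    dists = [slot_queues[g].pop(0) for g in gene_of]

    strong_ids = [p.id for p in library[1:]] or [library[0].id]
    events: list[PlantedEvent] = []
    neutral_ids: list[str] = []
    snps: list[SnpRecord] = []
    planned = []  # (snp, kind, pwm_id, hit_strand, motif_start, motif_len)

    for i, (kind, g_idx, dist) in enumerate(zip(kinds, gene_of, dists)):
        gene_id, _, _, chrom, g_strand, tss, _, _ = genes[g_idx]
        pos = tss + dist if g_strand == "+" else tss - dist
        snp_id = f"rs{900000 + i}"
        if kind is None:
            ref = genome[chrom][pos - 1]
            alt = str(rng.choice([b for b in BASES if b != ref]))
            snps.append(SnpRecord(snp_id, chrom, pos, ref, alt))
            neutral_ids.append(snp_id)
            planned.append((snps[-1], None, None, None, None, None))
            continue
        pwm = pwm_by_id[library[0].id] if kind == "score_change" \
            else pwm_by_id[str(rng.choice(strong_ids))]
        hit_strand = str(rng.choice(["+", "-"]))
        col = _WEAK_COL if kind == "score_change" \
            else int(rng.integers(1, pwm.width + 1))
        planted_seq = pwm.consensus if hit_strand == "+" \
            else reverse_complement(pwm.consensus)
        q = col if hit_strand == "+" else pwm.width - col + 1
        motif_start = pos - (q - 1)
        genome.write_segment(chrom, motif_start, planted_seq)
        # ref/alt in matrix-column space, then mapped to the forward strand
        freq_col = pwm.freq[col - 1]
        order = np.argsort(-freq_col, kind="stable")
        major = BASES[order[0]]
        if kind == "loss":
            ref_m, alt_m = major, str(rng.choice(
                [b for b in BASES if b != major]))
        elif kind == "gain":
            ref_m, alt_m = str(rng.choice(
                [b for b in BASES if b != major])), major
        else:  # score_change: swap the two frequent bases of the weak column
            ref_m, alt_m = major, BASES[order[1]]
        to_fwd = (lambda b: b) if hit_strand == "+" else \
            (lambda b: reverse_complement(b))
        ref, alt = to_fwd(ref_m), to_fwd(alt_m)
        genome.set_base(chrom, pos, ref)
        snps.append(SnpRecord(snp_id, chrom, pos, ref, alt))
        events.append(PlantedEvent(snp_id, pwm.id, hit_strand, kind, dist,
                                   chrom, pos, gene_id))
        planned.append((snps[-1], kind, pwm.id, hit_strand,
                        motif_start, pwm.width))

    # -- verify against the real scanner; resample background on conflict --
    for snp, kind, pwm_id, hit_strand, motif_start, motif_len in planned:
        for attempt in range(100):
            pair = extract_flanks(genome, snp)
            if not isinstance(pair, AllelePair):
                raise RuntimeError(f"{snp.snp_id}: flank unexpectedly discarded "
                                   f"({pair.reason})")
            records = classify(*scan_alleles(library, pair), snp_id=snp.snp_id)
            if _expected_records_ok(kind, pwm_id, hit_strand, records):
                break
            # a chance hit: redraw background bases near the SNP, keeping the
            # planted motif and the SNP base fixed
            protected = set(range(motif_start, motif_start + motif_len)) \
                if motif_start is not None else set()
            protected.add(snp.pos)
            lo = snp.pos - (_MOTIF_WIDTH - 1) - max(p.width for p in library)
            hi = snp.pos + (_MOTIF_WIDTH - 1) + max(p.width for p in library)
            for p in range(max(1, lo), min(len(genome[snp.chrom]), hi) + 1):
                if p not in protected:
                    genome.set_base(snp.chrom, p, str(rng.choice(list(BASES))))
        else:
            raise RuntimeError(
                f"{snp.snp_id}: could not isolate planted event from chance "
                "background hits")

    # -- write files -------------------------------------------------------
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "genome.fa"
    with fasta.open("w") as fh:
        for name in chrom_names:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    gff = out_dir / "genes.gff3"
    with gff.open("w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, gene_name, tx_id, chrom, strand, _tss, start, end in genes:
            fh.write(f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                     f"ID={gene_id};Name={gene_name}\n")
            fh.write(f"{chrom}\tsim\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                     f"ID={tx_id};Parent={gene_id}\n")
    vcf = out_dir / "snps.vcf"
    with vcf.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in chrom_names:
            fh.write(f"##contig=<ID={name},length={chrom_len}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for snp in sorted(snps, key=lambda s: (s.chrom, s.pos)):
            fh.write(f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{snp.ref}\t"
                     f"{snp.alt}\t.\t.\t.\n")
    (out_dir / "pwms.transfac").write_text(write_transfac(library))

    manifest = FixtureManifest(
        seed=int(seed),
        params={"n_chroms": n_chroms, "chrom_len": chrom_len,
                "n_genes": n_genes, "n_snps": n_snps, "n_pwms": n_pwms,
                "plant_spec": dict(sorted(plant_spec.items())),
                "upstream_bp": upstream_bp, "downstream_bp": downstream_bp},
        per_chrom={name: {
            "genes": genes_per_chrom[c],
            "snps": sum(1 for s in snps if s.chrom == name)}
            for c, name in enumerate(chrom_names)},
        events=sorted(events, key=lambda e: e.snp_id),
        neutral_snp_ids=sorted(neutral_ids),
    )
    (out_dir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
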