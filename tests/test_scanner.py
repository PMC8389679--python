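"""Flank extraction and two-allele, two-strand scanning."""

import numpy as np
import pytest

from rsnpscan.genomic import SnpRecord
from rsnpscan.pwm import PWM, score_site
from rsnpscan.scanner import (AllelePair, Discard, extract_flanks,
                              reverse_complement, scan_alleles)
from rsnpscan.simulate import make_library

from conftest import random_pwm


def make_genome(rng, length=400, chrom="chr1"):
    return {chrom: "".join(rng.choice(list("ACGT"), size=length))}


class TestExtractFlanks:
    def test_interior_snp_gives_51bp_with_snp_at_26(self, rng):
        genome = make_genome(rng, 200)
        ref = genome["chr1"][99]
        alt = next(b for b in "ACGT" if b != ref)
        pair = extract_flanks(genome, SnpRecord("s", "chr1", 100, ref, alt))
        assert isinstance(pair, AllelePair)
        assert len(pair.ref_seq) == len(pair.alt_seq) == 51
        assert pair.snp_index == 26
        assert pair.ref_seq[25] == ref and pair.alt_seq[25] == alt
        diffs = [i for i in range(51) if pair.ref_seq[i] != pair.alt_seq[i]]
        assert diffs == [25]

    @pytest.mark.parametrize("pos", [10, 195])
    def test_edge_snp_discarded_short(self, rng, pos):
        genome = make_genome(rng, 200)
        out = extract_flanks(genome, SnpRecord("s", "chr1", pos, "A", "C"))
        assert out == Discard("s", "short")

    def test_gap_in_flank_discarded(self, rng):
        genome = make_genome(rng, 200)
        seq = genome["chr1"]
        genome["chr1"] = seq[:109] + "N" + seq[110:]
        ref = genome["chr1"][99]
        alt = next(b for b in "ACGT" if b != ref)
        out = extract_flanks(genome, SnpRecord("s", "chr1", 100, ref, alt))
        assert out == Discard("s", "gap")

    def test_ref_mismatch_skipped(self, rng):
        genome = make_genome(rng, 200)
        wrong = next(b for b in "ACGT" if b != genome["chr1"][99])
        alt = next(b for b in "ACGT" if b not in (wrong,))
        out = extract_flanks(genome, SnpRecord("s", "chr1", 100, wrong, alt))
        assert out == Discard("s", "ref-mismatch")


def exhaustive_scan_oracle(library, seq, snp_index, require_overlap=True):
    """Score every (pwm, offset, strand) with the scalar scorer directly."""
    hits = set()
    n = len(seq)
    for pwm in library:
        L = pwm.width
        if L > n:
            continue
        for start in range(1, n - L + 2):
            window = seq[start - 1:start - 1 + L]
            for strand, s in (("+", window), ("-", reverse_complement(window))):
                mss, css = score_site(pwm, s)
                if mss >= pwm.mss_cutoff and css >= pwm.css_cutoff:
                    if require_overlap and not (start <= snp_index <= start + L - 1):
                        continue
                    hits.add((pwm.id, start, strand,
                              round(mss, 10), round(css, 10)))
    return hits


def hitset(hits):
    return {(h.pwm_id, h.start, h.strand, round(h.mss, 10), round(h.css, 10))
            for h in hits}


def planted_pair(rng, pwm, mutate_alt=True):
    """51-bp pair with the PWM consensus planted across the SNP."""
    flank = "".join(rng.choice(list("ACGT"), size=51))
    L = pwm.width
    start = 26 - L // 2
    seq = flank[:start - 1] + pwm.consensus + flank[start - 1 + L:]
    col = 26 - start  # 0-based column at the SNP
    ref = pwm.consensus[col]
    if mutate_alt:
        alt = "ACGT"[int(np.argmin(pwm.freq[col]))]
    else:
        alt = next(b for b in "ACGT" if b != ref)
    alt_seq = seq[:25] + alt + seq[26:]
    return AllelePair("s", seq, alt_seq, 26)


class TestScanAlleles:
    def test_consensus_disruption_hits_ref_only(self, rng):
        """A site matching the reference exactly disappears when the
        alternate base breaks the consensus (the loss scheme)."""
        lib = make_library(np.random.default_rng(5), 3)
        pwm = lib[1]  # strong columns
        pair = planted_pair(rng, pwm)
        ref_hits, alt_hits = scan_alleles([pwm], pair)
        assert [h.pwm_id for h in ref_hits] == [pwm.id]
        assert ref_hits[0].mss == pytest.approx(1.0)
        assert alt_hits == []

    def test_non_overlapping_hits_dropped_on_both_alleles(self, rng):
        """A motif 5' of the SNP is identical on both alleles: present in
        both raw scans, absent after the SNP-overlap filter."""
        lib = make_library(np.random.default_rng(6), 3)
        pwm = lib[2]
        flank = "".join(rng.choice(list("ACGT"), size=51))
        seq = pwm.consensus + flank[pwm.width:]
        ref = seq[25]
        alt = next(b for b in "ACGT" if b != ref)
        pair = AllelePair("s", seq, seq[:25] + alt + seq[26:], 26)
        raw_ref, raw_alt = scan_alleles([pwm], pair, require_snp_overlap=False)
        assert hitset(h for h in raw_ref if h.start + pwm.width - 1 < 26) \
            == hitset(h for h in raw_alt if h.start + pwm.width - 1 < 26)
        ref_hits, alt_hits = scan_alleles([pwm], pair)
        assert all(h.start <= 26 <= h.start + pwm.width - 1
                   for h in ref_hits + alt_hits)

    def test_matches_exhaustive_oracle(self, rng):
        lib = make_library(np.random.default_rng(7), 6)
        for pwm in lib:
            pair = planted_pair(rng, pwm)
            for seq in (pair.ref_seq, pair.alt_seq):
                got_ref, _ = scan_alleles(lib, AllelePair("s", seq, seq, 26))
                assert hitset(got_ref) == exhaustive_scan_oracle(lib, seq, 26)

    def test_reverse_complement_involution(self, rng):
        """Scanning the reverse complement mirrors positions and swaps
        strands, hit for hit."""
        lib = make_library(np.random.default_rng(8), 4)
        pair = planted_pair(rng, lib[1])
        fwd, _ = scan_alleles(lib, pair)
        rc = reverse_complement(pair.ref_seq)
        rc_pair = AllelePair("s", rc, rc, 51 - 26 + 1)
        rev, _ = scan_alleles(lib, rc_pair)
        mirrored = {(h.pwm_id, 51 - (h.start + next(
            p.width for p in lib if p.id == h.pwm_id) - 1) + 1,
            "+-"[h.strand == "+"], round(h.mss, 10), round(h.css, 10))
            for h in rev}
        assert hitset(fwd) == mirrored

    def test_identical_alleles_give_identical_hits(self, rng):
        lib = make_library(np.random.default_rng(9), 4)
        pair = planted_pair(rng, lib[1])
        same = AllelePair("s", pair.ref_seq, pair.ref_seq, 26)
        ref_hits, alt_hits = scan_alleles(lib, same)
        assert hitset(ref_hits) == hitset(alt_hits)

    def test_hits_respect_cutoffs_and_overlap(self, rng):
        lib = make_library(np.random.default_rng(10), 5)
        by_id = {p.id: p for p in lib}
        for _ in range(20):
            pair = planted_pair(rng, lib[int(rng.integers(len(lib)))])
            for hits in scan_alleles(lib, pair):
                for h in hits:
                    p = by_id[h.pwm_id]
                    assert h.mss >= p.mss_cutoff and h.css >= p.css_cutoff
                    assert h.start <= 26 <= h.start + p.width - 1

    def test_empty_library_rejected(self, rng):
        pair = planted_pair(rng, random_pwm(rng, 6))
        with pytest.raises(ValueError, match="empty"):
            scan_alleles([], pair)

    def test_overwide_pwm_skipped_with_warning(self, rng, caplog):
        wide = random_pwm(rng, 60, "V$WIDE_01")
        pair = planted_pair(rng, random_pwm(rng, 6))
        ref_hits, alt_hits = scan_alleles([wide], pair)
        assert ref_hits == [] and alt_hits == []
        assert any("exceeds flank length" in r.message for r in caplog.records)
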