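"""Allele-wise TFBS comparison and consequence classification.

Two predictions are the *same site* when their PWM, start position and
strand agree between the alleles.  Each site then receives one of four
verdicts:

* ``no_effect``     — present on both alleles with equal scores,
* ``score_change``  — present on both alleles with differing scores,
* ``loss``          — present on the reference allele only,
* ``gain``          — present on the alternate allele only.

A SNP is a regulatory SNP (rSNP) when at least one of its sites is a loss,
gain or score-change.  Score equality is decided after rounding (3 decimals
by default, shared with the scoring module).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .pwm import SCORE_DECIMALS
from .scanner import SiteHit

logger = logging.getLogger(__name__)

NO_EFFECT = "no_effect"
SCORE_CHANGE = "score_change"
LOSS = "loss"
GAIN = "gain"

RSNP_CONSEQUENCES = frozenset({LOSS, GAIN, SCORE_CHANGE})


@dataclass(frozen=True)
class ConsequenceRecord:
    """The verdict for one SNP x PWM x position x strand site."""

    snp_id: str
    pwm_id: str
    strand: str
    start: int
    allele_presence: str  # ref_only | alt_only | both
    ref_mss: float | None
    ref_css: float | None
    alt_mss: float | None
    alt_css: float | None
    consequence: str


def _index_hits(hits: list[SiteHit], which: str) -> dict[tuple, SiteHit]:
    indexed: dict[tuple, SiteHit] = {}
    for hit in hits:
        if hit.key in indexed:
            raise ValueError(
                f"duplicate site key {hit.key} in {which} hit set "
                "(scanner contract violation)")
        indexed[hit.key] = hit
    return indexed


def classify(ref_hits: list[SiteHit], alt_hits: list[SiteHit],
             snp_id: str = "", decimals: int = SCORE_DECIMALS,
             ) -> list[ConsequenceRecord]:
    """Compare the two alleles' hit sets and classify every site.

    Every hit in either set appears in exactly one record.  Records are
    ordered by site key.
    """
    ref_idx = _index_hits(ref_hits, "ref")
    alt_idx = _index_hits(alt_hits, "alt")
    records: list[ConsequenceRecord] = []
    for key in sorted(set(ref_idx) | set(alt_idx)):
        r, a = ref_idx.get(key), alt_idx.get(key)
        pwm_id, start, strand = key
        if r is not None and a is not None:
            same_mss = round(r.mss, decimals) == round(a.mss, decimals)
            same_css = round(r.css, decimals) == round(a.css, decimals)
            if same_mss and same_css:
                verdict = NO_EFFECT
            else:
                verdict = SCORE_CHANGE
                if same_mss and not same_css:
                    logger.info("%s %s: CSS differs while MSS equal; "
                                "classified as score_change", snp_id, pwm_id)
            records.append(ConsequenceRecord(
                snp_id, pwm_id, strand, start, "both",
                r.mss, r.css, a.mss, a.css, verdict))
        elif r is not None:
            records.append(ConsequenceRecord(
                snp_id, pwm_id, strand, start, "ref_only",
                r.mss, r.css, None, None, LOSS))
        else:
            records.append(ConsequenceRecord(
                snp_id, pwm_id, strand, start, "alt_only",
                None, None, a.mss, a.css, GAIN))
    return records


def flag_rsnp(records: list[ConsequenceRecord]) -> bool:
    """True iff any site verdict makes the SNP regulatory."""
    return any(rec.consequence in RSNP_CONSEQUENCES for rec in records)
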