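# Methods

## Model and assumptions

`rsnpscan` predicts the regulatory consequence of a single-nucleotide
substitution purely from sequence: a transcription factor's preference is a
position-frequency matrix (PWM), binding is a thresholded similarity score,
and a variant matters when the two alleles' predicted site sets differ.
That is an affinity-only model — chromatin accessibility, TF concentration,
and cooperative or competitive binding are outside it, so calls are
hypotheses about binding potential, not occupancy.

### Similarity scoring

Each matrix row is normalized to frequencies `f(i,b)`. The per-position
information content is

    I(i) = sum_b f(i,b) * ln(4 * f(i,b)),   0*ln(0) := 0,

which is 0 for an uninformative column and ln 4 for a fixed base. A
candidate site `s` of matrix width `L` scores

    Current = sum_i I(i) * f(i, s_i)
    MSS     = (Current - Min) / (Max - Min)

with Min/Max substituting the per-position minimum/maximum frequency. The
core similarity score (CSS) applies the same formula to the core window:
the five consecutive positions maximizing `sum I(i)` (leftmost on ties;
matrices narrower than five use the whole matrix, making CSS = MSS). Both
scores are bounded in [0, 1] by construction; 1 means every position shows
a maximal-frequency base, 0 a minimal one. Information weighting makes the
score insensitive to mismatches at degenerate positions and sharp at
conserved ones.

Degenerate input: if Max = Min over the scored positions (a fully uniform
matrix or core), the score is defined as 1.0 and a warning is logged rather
than dividing by zero.

### Site prediction and consequence calls

Every promoter SNP contributes two 51-bp sequences (25-bp flanks, SNP at
position 26); both are scanned at every offset on both strands. A hit needs
MSS ≥ `mss_cutoff` and CSS ≥ `css_cutoff` and must overlap the SNP base.
Dropping non-overlapping hits is a pure optimization: such a site sees
identical sequence on both alleles, so it can only ever produce `no_effect`
records; the equivalence is asserted by a dedicated test rather than
assumed. Minus-strand hits are reported in forward-flank coordinates with a
strand flag so that site identity — equality of (PWM, start, strand) — is
well defined across alleles.

Matched sites with equal rounded scores are `no_effect`; with differing
scores, `score_change`; unmatched reference-only sites are `loss`,
alternate-only `gain`. A site whose CSS differs while its MSS is equal is
classified `score_change` (the no-effect definition demands both scores
equal) and logged distinctly, since that corner sits between the two
written rules. A SNP is an rSNP when any of its sites is a loss, gain or
score-change.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `upstream_bp` / `downstream_bp` | 7500 / 2500 | promoter extent around the TSS, direction of transcription; deliberately generous to absorb TSS-annotation inaccuracy, narrowable at query time |
| `half_width` | 25 bp | flank on each side of the SNP; the scan substrate is 2·25+1 = 51 bp |
| `mss_cutoff` / `css_cutoff` | 0.95 / 0.90 | minimum similarity for a hit; overridable globally or per matrix via a cutoff-profile file. Stringent defaults keep the false-positive rate of near-consensus calls low |
| score comparison precision | 3 decimals | two scores are "equal" after rounding to 3 decimals; configurable because the no-effect/score-change boundary depends on it |
| pseudocount | 0 | zero frequencies are legal (they contribute 0 to Current and to I); an ε can be added at parse time for user matrices |

Coordinates are 1-based closed intervals everywhere internally; BED export
converts to 0-based half-open. `dist_tss` is negative upstream, with 0 at
the TSS base counted as downstream — the histogram and per-gene splits use
half-open bins `[lo, lo+w)` and the same zero convention.

Isoforms of a gene sharing (chromosome, strand, TSS) collapse to one
promoter, so a SNP is reported once per distinct TSS, not once per
transcript. Multiallelic VCF records decompose into one biallelic record
per alternate allele; insertions, deletions and symbolic alleles are
discarded at load time.

## Synthetic fixtures

The generator emulates the pipeline's operating conditions at desk scale:
a few ~60 kb chromosomes of i.i.d. uniform background, genes placed so
their 10 kb promoters are disjoint (keeping the SNP→gene bookkeeping
unambiguous), a small PWM library, and ≥120 bp spacing between SNPs so
each flank contains at most its own planted motif.

Planted events are constructed to cross the default cutoffs reliably:

* motif columns are near-deterministic (0.91 / 3×0.03), so one consensus
  mismatch in a width-10 matrix drops the MSS to 0.90 < 0.95 — a clean
  loss (or, mirrored, gain);
* one matrix carries a moderately informative column
  (0.46 / 0.44 / 2×0.05) placed outside its core; swapping its two
  frequent bases moves the MSS from 1.000 to ≈0.999 while both alleles
  stay above both cutoffs — a score-change.

After planting, every SNP (including neutrals) is verified against the real
scanner; if a chance background hit would blur the planted truth, the flank
background is resampled deterministically from the same seeded stream. The
manifest is therefore exact by construction, and fixture files are
byte-identical for a given seed.

What the fixtures do **not** emulate: realistic base composition and repeat
structure, population allele frequencies and linkage, overlapping genes and
promoters, ambiguity codes in the assembly, and commercial-scale PWM
libraries with curated per-matrix cutoffs. Passing tests therefore
demonstrate the correctness of the machinery (windowing, scanning,
classification, storage), not the biological calibration of any particular
matrix library on real genomes.

## Numerical and design choices

* Scoring is vectorized over all windows of a flank; the scalar
  `score_site` and the window scorer share one code path, and an
  independently coded direct-summation oracle checks them exhaustively for
  small widths in the tests.
* Core-window ties are broken leftmost after rounding window sums to 12
  decimals, so algebraically equal windows cannot be split by float noise.
* A matrix wider than the flank (51 bp) can never overlap the SNP with full
  containment; it is skipped with a warning.
* Flanks are discarded — with logged reasons `short`, `gap`,
  `ref-mismatch` — rather than padded; a reference-allele mismatch against
  the genome signals catalog/assembly version drift and is deliberately
  loud.
* The store is an embedded single-file SQLite database with the four-table
  schema (`snp_info`, `gene_info`, `snp_region`, `tfbs_results`);
  referential integrity is checked before an atomic insert and any
  violation rolls the whole write back. A server database would add
  deployment burden without changing the logical schema.
* Query narrowing (`-up_bp ≤ dist_tss ≤ down_bp`) filters stored rows
  post hoc; it is monotone (narrower windows return subsets), which the
  property tests assert.

Test problem sizes were chosen to exercise the oracles convincingly while
keeping the suite quick: the SNP-promoter assignment is checked against an
all-pairs oracle at 10^4 SNPs × 10^3 promoters, scoring bounds on 10^5
randomized cases, scanning against an exhaustive offset/strand oracle on a
10-matrix library, and end-to-end recovery on fixtures planting 5 losses,
5 gains and 5 score-changes (plus smaller multi-seed variants).

## Known limitations

* Affinity-only prediction; no chromatin, expression or conservation
  evidence is integrated, and no p-value calibration of scores is
  attempted — score differences are reported, not ranked for significance.
* Only single-nucleotide substitutions are annotated; MNPs and structural
  variants are out of scope.
* Distal regulatory elements (enhancers) are not modelled; the promoter
  window, however generous, is anchored to annotated TSSs.
* Default cutoffs are sensible for near-deterministic matrices but any
  serious run with a curated library should supply a per-matrix cutoff
  profile.
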