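"""Position weight matrices and MATCH-style similarity scoring.

A PWM models a transcription-factor binding site as per-position base
frequencies.  Candidate sites are scored with two normalized similarities:

* the matrix similarity score (MSS), computed over the whole matrix, and
* the core similarity score (CSS), computed over the core — the five
  most-conserved consecutive positions.

Both use the information-weighted formulation: with per-position
information content ``I(i) = sum_b f(i,b) * ln(4 f(i,b))`` (``0·ln 0 := 0``),

    Current = sum_i I(i) * f(i, s_i)
    MSS     = (Current - Min) / (Max - Min)

where Min/Max substitute the least/most frequent base at every position.
Scores lie in [0, 1]; 1 is an exact match to the consensus, 0 the
anti-consensus.  A site is reported as a putative TFBS only when both
scores clear the matrix's cutoffs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: number of decimals at which scores are compared for equality downstream
SCORE_DECIMALS = 3

#: default cutoffs applied when a matrix (or profile) does not override them
DEFAULT_MSS_CUTOFF = 0.95
DEFAULT_CSS_CUTOFF = 0.90

CORE_LENGTH = 5


def information_vector(freq: np.ndarray) -> np.ndarray:
    """Per-position information content I(i) = sum_b f(i,b) ln(4 f(i,b)).

    Zero frequencies contribute zero (the 0·ln 0 convention).  Each entry
    lies in [0, ln 4]: 0 for a uniform column, ln 4 for a fixed base.
    """
    freq = np.asarray(freq, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freq > 0, freq * np.log(4.0 * freq), 0.0)
    return terms.sum(axis=1)


def core_window(info: np.ndarray) -> int:
    """1-based start of the most informative run of 5 consecutive positions.

    Ties go to the leftmost window.  Matrices narrower than 5 positions use
    the whole matrix as the core.
    """
    L = len(info)
    if L <= CORE_LENGTH:
        return 1
    sums = np.convolve(info, np.ones(CORE_LENGTH), mode="valid")
    # float-noise guard so equal-information windows tie deterministically
    return int(np.argmax(np.round(sums, 12))) + 1


@dataclass
class PWM:
    """A position-frequency matrix with derived scoring vectors.

    Attributes
    ----------
    id : matrix identifier, e.g. ``V$AP2ALPHA_03`` (TRANSFAC style) or a
        JASPAR accession; preserved verbatim from the source file.
    freq : (L, 4) array of base frequencies in A, C, G, T order; every row
        sums to 1.
    mss_cutoff, css_cutoff : minimum similarity scores for a hit.
    """

    id: str
    freq: np.ndarray
    mss_cutoff: float = DEFAULT_MSS_CUTOFF
    css_cutoff: float = DEFAULT_CSS_CUTOFF
    info: np.ndarray = field(init=False, repr=False)
    core_start: int = field(init=False)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.ndim != 2 or self.freq.shape[1] != 4:
            raise ValueError(f"{self.id}: frequency matrix must be L x 4")
        if (self.freq < 0).any():
            raise ValueError(f"{self.id}: negative frequencies")
        rowsums = self.freq.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError(f"{self.id}: rows must sum to 1")
        self.info = information_vector(self.freq)
        self.core_start = core_window(self.info)
        # Precomputed scoring vectors: weighted frequencies and the
        # per-position extremes used for min-max normalization.
        self._weighted = self.info[:, None] * self.freq
        self._wmin = self._weighted.min(axis=1)
        self._wmax = self._weighted.max(axis=1)

    @property
    def width(self) -> int:
        return self.freq.shape[0]

    @property
    def core_slice(self) -> slice:
        stop = min(self.core_start - 1 + CORE_LENGTH, self.width)
        return slice(self.core_start - 1, stop)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freq.argmax(axis=1))


def encode_sequence(seq: str) -> np.ndarray:
    """Map an ACGT string to integer codes; reject ambiguity codes."""
    try:
        return np.array([_BASE_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character {exc.args[0]!r} in sequence") from None


def _normalize(current: np.ndarray, lo: float, hi: float, pwm_id: str,
               what: str) -> np.ndarray:
    span = hi - lo
    if span <= 0:
        logger.warning("%s: uninformative %s (Max == Min); score defined as 1.0",
                       pwm_id, what)
        return np.ones_like(np.asarray(current, dtype=float))
    return (np.asarray(current, dtype=float) - lo) / span


def score_site(pwm: PWM, seq: str) -> tuple[float, float]:
    """Score one candidate site of exactly the matrix width.

    Returns ``(mss, css)``, each in [0, 1].  Raises on a length mismatch or
    a non-ACGT character; gap handling belongs to the flank extractor.
    """
    if len(seq) != pwm.width:
        raise ValueError(
            f"{pwm.id}: sequence length {len(seq)} != matrix width {pwm.width}")
    codes = encode_sequence(seq)
    mss, css = score_windows(pwm, codes[None, :])
    return float(mss[0]), float(css[0])


def score_windows(pwm: PWM, windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized scoring of an (n, L) array of encoded windows."""
    idx = np.arange(pwm.width)
    cur = pwm._weighted[idx, windows].sum(axis=1)
    mss = _normalize(cur, pwm._wmin.sum(), pwm._wmax.sum(), pwm.id, "matrix")
    cs = pwm.core_slice
    cur_core = pwm._weighted[idx[cs], windows[:, cs]].sum(axis=1)
    css = _normalize(cur_core, pwm._wmin[cs].sum(), pwm._wmax[cs].sum(),
                     pwm.id, "core")
    return mss, css


# ---------------------------------------------------------------------------
# Library parsing: TRANSFAC flat-file and JASPAR PFM dialects
# ---------------------------------------------------------------------------

def _rows_to_freq(rows: list[list[float]], pwm_id: str) -> np.ndarray:
    mat = np.array(rows, dtype=float)
    totals = mat.sum(axis=1)
    for i, t in enumerate(totals, start=1):
        if t <= 0:
            raise ValueError(f"matrix {pwm_id!r}: position row {i} sums to zero")
    return mat / totals[:, None]


def _apply_pseudocount(rows: np.ndarray, eps: float) -> np.ndarray:
    return rows + eps if eps else rows


def _parse_transfac(text: str, pseudocount: float) -> list[tuple[str, np.ndarray]]:
    matrices: list[tuple[str, np.ndarray]] = []
    pwm_id: str | None = None
    rows: list[list[float]] = []
    order = [0, 1, 2, 3]  # column order of the P0 header, A C G T by default

    def flush() -> None:
        nonlocal pwm_id, rows, order
        if pwm_id is not None and rows:
            raw = np.array(rows, dtype=float)[:, np.argsort(order)]
            freq = _rows_to_freq(_apply_pseudocount(raw, pseudocount).tolist(), pwm_id)
            matrices.append((pwm_id, freq))
        pwm_id, rows, order = None, [], [0, 1, 2, 3]

    for line in text.splitlines():
        line = line.rstrip()
        if not line:
            continue
        tag = line[:2]
        if tag == "//":
            flush()
        elif tag == "ID":
            if pwm_id is not None and rows:
                flush()
            pwm_id = line[2:].strip().split()[0]
        elif tag in ("P0", "PO"):
            header = line[2:].split()[:4]
            if sorted(header) == sorted(BASES):
                order = [list(BASES).index(b) for b in header]
        elif re.match(r"^\d+\s", line):
            parts = line.split()
            rows.append([float(x) for x in parts[1:5]])
    flush()
    return matrices


def _parse_jaspar(text: str, pseudocount: float) -> list[tuple[str, np.ndarray]]:
    matrices: list[tuple[str, np.ndarray]] = []
    pwm_id: str | None = None
    base_rows: list[list[float]] = []

    def flush() -> None:
        nonlocal pwm_id, base_rows
        if pwm_id is not None:
            if len(base_rows) != 4:
                raise ValueError(f"matrix {pwm_id!r}: expected 4 base rows, "
                                 f"got {len(base_rows)}")
            widths = {len(r) for r in base_rows}
            if len(widths) != 1:
                raise ValueError(f"matrix {pwm_id!r}: ragged base rows")
            raw = np.array(base_rows, dtype=float).T  # positions x bases
            freq = _rows_to_freq(_apply_pseudocount(raw, pseudocount).tolist(), pwm_id)
            matrices.append((pwm_id, freq))
        pwm_id, base_rows = None, []

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            pwm_id = line[1:].split()[0]
        else:
            # "A [ 3 5 0 ]" rows or bare number rows, in A C G T order
            nums = re.findall(r"-?\d+\.?\d*", line.split("[", 1)[-1])
            base_rows.append([float(x) for x in nums])
    flush()
    return matrices


def parse_pwm_library(text: str, dialect: str = "transfac", *,
                      pseudocount: float = 0.0,
                      mss_cutoff: float = DEFAULT_MSS_CUTOFF,
                      css_cutoff: float = DEFAULT_CSS_CUTOFF,
                      cutoff_profile: dict[str, tuple[float, float]] | None = None,
                      ) -> list[PWM]:
    """Parse a PWM library from TRANSFAC flat-file or JASPAR PFM text.

    Counts (or frequencies) are row-normalized; an optional pseudocount is
    added to every count first.  ``cutoff_profile`` maps matrix ids to
    per-matrix ``(mss_cutoff, css_cutoff)`` pairs overriding the globals.
    """
    if dialect == "transfac":
        parsed = _parse_transfac(text, pseudocount)
    elif dialect == "jaspar_pfm":
        parsed = _parse_jaspar(text, pseudocount)
    else:
        raise ValueError(f"unknown PWM dialect {dialect!r}")
    seen: set[str] = set()
    library: list[PWM] = []
    for pwm_id, freq in parsed:
        if pwm_id in seen:
            raise ValueError(f"duplicate matrix id {pwm_id!r}")
        seen.add(pwm_id)
        mc, cc = mss_cutoff, css_cutoff
        if cutoff_profile and pwm_id in cutoff_profile:
            mc, cc = cutoff_profile[pwm_id]
        library.append(PWM(pwm_id, freq, mss_cutoff=mc, css_cutoff=cc))
    return library


def read_cutoff_profile(text: str) -> dict[str, tuple[float, float]]:
    """Parse a cutoff-profile table: ``pwm_id<TAB>mss_cutoff<TAB>css_cutoff``.

    A header line is recognized and skipped; '#' starts a comment.
    """
    profile: dict[str, tuple[float, float]] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", "\t").split("\t") if "\t" in line or "," in line \
            else line.split()
        if len(parts) < 3:
            raise ValueError(f"malformed cutoff-profile line: {line!r}")
        try:
            profile[parts[0].strip()] = (float(parts[1]), float(parts[2]))
        except ValueError:
            if parts[0].strip().lower() in ("id", "pwm_id", "matrix_id"):
                continue  # header row
            raise
    return profile


def write_transfac(library: list[PWM], counts_scale: int = 100) -> str:
    """Serialize PWMs in the TRANSFAC flat-file dialect (scaled counts)."""
    out: list[str] = []
    for pwm in library:
        out.append(f"ID {pwm.id}")
        out.append("P0      A      C      G      T")
        counts = np.rint(pwm.freq * counts_scale).astype(int)
        for i in range(pwm.width):
            a, c, g, t = counts[i]
            cons = BASES[int(pwm.freq[i].argmax())]
            out.append(f"{i + 1:02d} {a:6d} {c:6d} {g:6d} {t:6d} {cons}")
        out.append("XX")
        out.append("//")
    return "\n".join(out) + "\n"
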