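"""PWM parsing, information content, core window and similarity scoring."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsnpscan.pwm import (BASES, PWM, core_window, information_vector,
                          parse_pwm_library, read_cutoff_profile, score_site,
                          write_transfac)

from conftest import random_pwm

TRANSFAC_TEXT = """\
ID V$TOY_01
P0      A      C      G      T
01      7      0      0      0
02      0      7      0      0
03      2      2      2      1
04      0      0      0      7
XX
//
ID V$TOY_02
P0      A      C      G      T
01      1      1      1      1
02      4      0      0      0
XX
//
"""

JASPAR_TEXT = """\
>MA0001.1 TOY
A [ 7 0 1 ]
C [ 0 7 1 ]
G [ 0 0 1 ]
T [ 0 0 1 ]
>MA0002.1 TOY2
7 0
0 7
0 0
0 0
"""


class TestParsing:
    def test_transfac_blocks_normalized(self):
        lib = parse_pwm_library(TRANSFAC_TEXT, "transfac")
        assert [p.id for p in lib] == ["V$TOY_01", "V$TOY_02"]
        toy = lib[0]
        assert toy.width == 4
        assert np.allclose(toy.freq.sum(axis=1), 1.0)
        assert toy.freq[0, 0] == 1.0
        assert np.allclose(toy.freq[2], [2 / 7, 2 / 7, 2 / 7, 1 / 7])

    def test_jaspar_counts_transposed_and_normalized(self):
        lib = parse_pwm_library(JASPAR_TEXT, "jaspar_pfm")
        assert [p.id for p in lib] == ["MA0001.1", "MA0002.1"]
        assert lib[0].width == 3
        # column 1 counts (7,0,0,0) -> f(1,A)=1
        assert lib[0].freq[0, 0] == 1.0
        assert np.allclose(lib[0].freq[2], 0.25)
        assert lib[1].width == 2

    def test_zero_row_is_parse_error_naming_matrix_and_row(self):
        bad = "ID V$BAD_01\nP0 A C G T\n01 1 0 0 0\n02 0 0 0 0\n//\n"
        with pytest.raises(ValueError, match=r"V\$BAD_01.*row 2"):
            parse_pwm_library(bad, "transfac")

    def test_duplicate_ids_error(self):
        dup = TRANSFAC_TEXT.replace("V$TOY_02", "V$TOY_01")
        with pytest.raises(ValueError, match="duplicate"):
            parse_pwm_library(dup, "transfac")

    def test_unknown_dialect(self):
        with pytest.raises(ValueError, match="dialect"):
            parse_pwm_library(TRANSFAC_TEXT, "meme")

    def test_pseudocount_removes_zeros(self):
        lib = parse_pwm_library(TRANSFAC_TEXT, "transfac", pseudocount=1.0)
        assert (lib[0].freq > 0).all()

    def test_cutoff_profile_overrides(self):
        profile = read_cutoff_profile(
            "pwm_id\tmss_cutoff\tcss_cutoff\nV$TOY_01\t0.8\t0.7\n")
        lib = parse_pwm_library(TRANSFAC_TEXT, "transfac",
                                cutoff_profile=profile)
        assert (lib[0].mss_cutoff, lib[0].css_cutoff) == (0.8, 0.7)
        assert lib[1].mss_cutoff == 0.95  # default untouched

    def test_transfac_roundtrip(self, rng):
        lib = parse_pwm_library(TRANSFAC_TEXT, "transfac")
        again = parse_pwm_library(write_transfac(lib), "transfac")
        for a, b in zip(lib, again):
            assert a.id == b.id
            assert np.allclose(a.freq, b.freq, atol=5e-3)


class TestInformationVector:
    @pytest.mark.parametrize("column, expected", [
        ([0.25, 0.25, 0.25, 0.25], 0.0),
        ([1.0, 0.0, 0.0, 0.0], math.log(4)),
        ([0.5, 0.5, 0.0, 0.0], math.log(2)),
    ])
    def test_closed_forms(self, column, expected):
        assert information_vector(np.array([column]))[0] == pytest.approx(expected)

    def test_bounds(self, rng):
        freq = rng.dirichlet(np.ones(4), size=200)
        info = information_vector(freq)
        assert (info >= -1e-12).all() and (info <= math.log(4) + 1e-12).all()


class TestCoreWindow:
    @pytest.mark.parametrize("info, expected", [
        (np.ones(5), 1),                                  # single window
        (np.array([0.1, 1, 1, 1, 1, 1, 0.1]), 2),         # unique maximum
        (np.full(8, 0.7), 1),                             # leftmost tie
        (np.ones(3), 1),                                  # L < 5: whole matrix
    ])
    def test_start_selection(self, info, expected):
        assert core_window(info) == expected

    def test_core_is_whole_matrix_when_narrow(self):
        pwm = PWM("V$W3_01", np.eye(4)[[0, 1, 2]])
        mss, css = score_site(pwm, "ACG")
        assert mss == css == 1.0


def brute_force_score(pwm: PWM, seq: str):
    """Independent direct-summation oracle for the similarity scores."""
    info = [sum(f * math.log(4 * f) for f in row if f > 0) for row in pwm.freq]

    def over(positions):
        cur = sum(info[i] * pwm.freq[i][BASES.index(seq[i])] for i in positions)
        lo = sum(info[i] * min(pwm.freq[i]) for i in positions)
        hi = sum(info[i] * max(pwm.freq[i]) for i in positions)
        return 1.0 if hi == lo else (cur - lo) / (hi - lo)

    core = range(pwm.core_start - 1,
                 min(pwm.core_start + 4, pwm.width))
    return over(range(pwm.width)), over(core)


class TestScoreSite:
    def test_consensus_scores_one(self, rng):
        pwm = random_pwm(rng, 8)
        assert score_site(pwm, pwm.consensus) == (1.0, 1.0)

    def test_anticonsensus_scores_zero(self, rng):
        pwm = random_pwm(rng, 8)
        anti = "".join(BASES[i] for i in pwm.freq.argmin(axis=1))
        mss, css = score_site(pwm, anti)
        assert mss == pytest.approx(0.0, abs=1e-12)
        assert css == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_against_oracle(self, rng):
        """All 4^5 sequences of a seed-fixed random width-5 matrix."""
        pwm = random_pwm(rng, 5)
        for bases in itertools.product(BASES, repeat=5):
            seq = "".join(bases)
            expect = brute_force_score(pwm, seq)
            got = score_site(pwm, seq)
            assert got == pytest.approx(expect, abs=1e-12)

    def test_length_mismatch_and_bad_base(self, rng):
        pwm = random_pwm(rng, 5)
        with pytest.raises(ValueError, match="length"):
            score_site(pwm, "ACGT")
        with pytest.raises(ValueError, match="non-ACGT"):
            score_site(pwm, "ACGTN")

    def test_uninformative_matrix_defined_as_one(self, caplog):
        flat = PWM("V$FLAT_01", np.full((5, 4), 0.25))
        assert score_site(flat, "ACGTA") == (1.0, 1.0)

    @settings(max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), width=st.integers(1, 12),
           data=st.data())
    def test_scores_bounded(self, seed, width, data):
        r = np.random.default_rng(seed)
        pwm = random_pwm(r, width)
        seq = "".join(data.draw(st.sampled_from(BASES)) for _ in range(width))
        mss, css = score_site(pwm, seq)
        assert -1e-12 <= mss <= 1 + 1e-12
        assert -1e-12 <= css <= 1 + 1e-12

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_base_permutation_invariance(self, seed):
        """Relabelling the four bases consistently leaves scores unchanged."""
        r = np.random.default_rng(seed)
        pwm = random_pwm(r, 6)
        perm = r.permutation(4)
        permuted = PWM("V$PERM_01", pwm.freq[:, perm])
        seq = "".join(r.choice(list(BASES), size=6))
        inv = np.argsort(perm)
        mapped = "".join(BASES[inv[BASES.index(c)]] for c in seq)
        assert score_site(pwm, seq) == pytest.approx(
            score_site(permuted, mapped), abs=1e-12)
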