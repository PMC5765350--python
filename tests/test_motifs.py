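"""PWM model, motif I/O and scanning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motifbench.errors import (
    InvalidBackgroundError,
    MalformedMotifError,
    SequenceTooShortError,
)
from motifbench.motifs import (
    PWM,
    affinity_score,
    max_pwm_score,
    read_pwms,
    reverse_complement,
    to_score_matrix,
    write_pwms,
)

from conftest import one_hot_pwm, random_pwm

UNIFORM3 = PWM(name="u3", matrix=np.full((3, 4), 0.25))


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestPWMType:
    def test_rejects_bad_row_sum(self):
        m = np.full((2, 4), 0.25)
        m[1, 0] = 0.5
        with pytest.raises(MalformedMotifError):
            PWM(name="bad", matrix=m)

    def test_rejects_width_zero(self):
        with pytest.raises(MalformedMotifError):
            PWM(name="empty", matrix=np.zeros((0, 4)))

    def test_double_reverse_complement_is_identity(self):
        pwm = random_pwm(7, seed=3)
        rc2 = reverse_complement(reverse_complement(pwm))
        np.testing.assert_array_equal(rc2.matrix, pwm.matrix)
        assert rc2.metadata == pwm.metadata

    def test_reverse_complement_one_hot(self, make_one_hot):
        rc = reverse_complement(make_one_hot("A", name="a"))
        np.testing.assert_array_equal(rc.matrix, [[0, 0, 0, 1]])

    def test_palindromic_pwm_is_own_reverse_complement(self, make_one_hot):
        pal = make_one_hot("AT")
        np.testing.assert_array_equal(
            reverse_complement(pal).matrix, pal.matrix
        )


class TestScoreMatrix:
    def test_uniform_pwm_uniform_background_gives_zero_matrix(self):
        for pc in (0.0, 0.01, 1.0):
            sm = to_score_matrix(UNIFORM3, pseudocount=pc)
            np.testing.assert_allclose(sm.matrix, 0.0, atol=1e-12)

    def test_one_hot_entry_matches_hand_computation(self, make_one_hot):
        # log2((1 + 0.01*0.25) / (1.01*0.25)) = 1.98925...
        sm = to_score_matrix(make_one_hot("A"), pseudocount=0.01)
        assert sm.matrix[0, 0] == pytest.approx(1.98925, abs=1e-4)

    def test_zero_background_entry_rejected(self):
        with pytest.raises(InvalidBackgroundError):
            to_score_matrix(UNIFORM3, background=np.array([0.0, 0.5, 0.25, 0.25]))


class TestMaxScore:
    def test_uniform_matrix_scores_zero_anywhere(self):
        sm = to_score_matrix(UNIFORM3)
        assert max_pwm_score("ACGTACGT", sm) == 0.0

    def test_planted_site_attains_three_times_single_base_score(self, make_one_hot):
        sm = to_score_matrix(make_one_hot("ACG"), pseudocount=0.01)
        score = max_pwm_score("TTACGTT", sm, both_strands=True)
        assert score == pytest.approx(3 * 1.98925, abs=1e-3)
        # brute force over all forward and reverse windows
        per_base = sm.matrix[0, 0]
        brute = max(
            sum(
                sm.matrix[j, "ACGT".index(b)]
                for j, b in enumerate("TTACGTT"[i : i + 3])
            )
            for i in range(5)
        )
        assert score == pytest.approx(max(brute, per_base * 3))

    def test_reverse_strand_site_needs_both_strands(self, make_one_hot):
        # only the reverse complement CGT of ACG is present
        sm = to_score_matrix(make_one_hot("ACG"))
        both = max_pwm_score("TTCGTTT", sm, both_strands=True)
        fwd = max_pwm_score("TTCGTTT", sm, both_strands=False)
        assert both > fwd

    def test_sequence_shorter_than_motif_rejected(self, make_one_hot):
        sm = to_score_matrix(make_one_hot("ACGTA"))
        with pytest.raises(SequenceTooShortError):
            max_pwm_score("ACG", sm)

    def test_n_positions_contribute_zero(self, make_one_hot):
        sm = to_score_matrix(make_one_hot("AC"))
        assert max_pwm_score("NN", sm) == 0.0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.text(alphabet="ACGT", min_size=6, max_size=40),
        st.integers(0, 10_000),
    )
    def test_both_strand_scan_equals_best_of_forward_scans(self, seq, seed):
        sm = to_score_matrix(random_pwm(5, seed))
        both = max_pwm_score(seq, sm, True)
        oracle = max(
            max_pwm_score(seq, sm, False),
            max_pwm_score(revcomp(seq), sm, False),
        )
        assert both == pytest.approx(oracle, abs=1e-12)


class TestAffinity:
    def test_uniform_motif_closed_form(self):
        # 2 * (l - w + 1) * 0.25^w regardless of content
        for seq in ("ACGTACGTAA", "TTTTTTTTTT"):
            expected = 2 * (len(seq) - 3 + 1) * 0.25**3
            assert affinity_score(seq, UNIFORM3) == pytest.approx(expected)

    def test_one_hot_site_counts_once_per_strand(self, make_one_hot):
        # forward window AC scores 1; reverse-complement motif is GT, which
        # does not match AC
        assert affinity_score("AC", make_one_hot("AC")) == pytest.approx(1.0)

    def test_absent_site_scores_zero(self, make_one_hot):
        assert affinity_score("GGGGGG", make_one_hot("AC")) == 0.0

    def test_more_planted_sites_never_decreases_affinity(self, make_one_hot):
        pwm = make_one_hot("ACGT")
        base = "GG" * 20
        one = affinity_score("ACGT" + base, pwm)
        two = affinity_score("ACGT" + base[:-4] + "ACGT", pwm)
        assert two >= one

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.text(alphabet="ACGTN", min_size=6, max_size=40),
        st.integers(0, 10_000),
    )
    def test_both_strand_affinity_invariant_under_revcomp(self, seq, seed):
        pwm = random_pwm(4, seed)
        rc_seq = seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
        assert affinity_score(seq, pwm) == pytest.approx(
            affinity_score(rc_seq, pwm), rel=1e-9
        )


MEME_BLOCK = """MEME version 4

ALPHABET= ACGT

MOTIF m1
letter-probability matrix: alength= 4 w= 2
0.25 0.25 0.25 0.25
1 0 0 0
"""


class TestMotifIO:
    def test_meme_minimal_parse(self):
        (pwm,) = read_pwms(MEME_BLOCK)
        assert pwm.name == "m1"
        np.testing.assert_allclose(
            pwm.matrix, [[0.25, 0.25, 0.25, 0.25], [1, 0, 0, 0]]
        )

    def test_row_sum_within_tolerance_renormalized(self):
        text = MEME_BLOCK.replace("1 0 0 0", "1.0005 0 0 0")
        (pwm,) = read_pwms(text)
        assert pwm.matrix[1].sum() == pytest.approx(1.0)

    def test_row_sum_far_from_one_rejected(self):
        text = MEME_BLOCK.replace("1 0 0 0", "0.5 0 0 0")
        with pytest.raises(MalformedMotifError, match="m1"):
            read_pwms(text)

    def test_empty_file_gives_empty_list(self):
        assert read_pwms("") == []

    def test_write_empty_list_gives_header_only(self):
        text = write_pwms([])
        assert "MOTIF" not in text
        assert read_pwms(text) == []

    def test_two_motifs_round_trip_in_order(self, make_one_hot):
        motifs = [random_pwm(3, 1, name="a"), make_one_hot("ACGT", name="b")]
        back = read_pwms(write_pwms(motifs))
        assert [m.name for m in back] == ["a", "b"]
        for orig, rt in zip(motifs, back):
            np.testing.assert_allclose(rt.matrix, orig.matrix, atol=1e-6)

    def test_tsv_matrix_dialect(self):
        text = "#m2\t2\n0.25\t0.25\t0.25\t0.25\n0\t0\t1\t0\n"
        (pwm,) = read_pwms(text, format="tsv_matrix")
        assert pwm.name == "m2" and pwm.matrix[1, 2] == 1.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 15))
    def test_round_trip_preserves_any_matrix(self, seed, width):
        pwm = random_pwm(width, seed, name=f"w{width}")
        (back,) = read_pwms(write_pwms([pwm]))
        np.testing.assert_allclose(back.matrix, pwm.matrix, atol=1e-6)

    def test_biopython_reads_our_meme_output(self, make_one_hot):
        # independent parser as cross-check of the dialect
        from io import StringIO

        from Bio import motifs as bio_motifs

        text = write_pwms([one_hot_pwm("ACGT", name="x"), random_pwm(6, 2, "y")])
        parsed = bio_motifs.parse(StringIO(text), "minimal")
        assert [m.name for m in parsed] == ["x", "y"]
        assert parsed[1].length == 6
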