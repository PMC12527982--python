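"""Count matrix construction, HI scoring and both-strand scanning."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sosdep.genome_io import GenomeRecord
from sosdep.sosbox_scoring import (
    default_matrix,
    CANONICAL_BOX,
    MatrixFormatError,
    SosBoxMatrix,
    build_matrix,
    hi_score,
    reverse_complement,
    scan_region,
)


def brute_force_hi(matrix, window):
    """Independent per-position ln-ratio summation straight from the counts."""
    total = 0.0
    p = matrix.pseudocount
    for i, b in enumerate(window):
        n_cons = matrix.counts[i]["ACGT".index(matrix.consensus[i])]
        n_b = matrix.counts[i]["ACGT".index(b)]
        total += math.log((n_cons + p) / (n_b + p))
    return total


def brute_force_scan(matrix, seq, mismatch_allowance=0, hi_cap=None):
    """All-windows filter oracle: plain string comparisons, no vectorization."""
    L = matrix.motif_length
    hits = {}
    for s in range(len(seq) - L + 1):
        window = seq[s : s + L]
        if any(ch not in "ACGT" for ch in window):
            continue
        for strand, oriented in (("+", window), ("-", reverse_complement(window))):
            mm = sum(1 for pos, b in matrix.core_positions if oriented[pos] != b)
            if mm > mismatch_allowance:
                continue
            hi = brute_force_hi(matrix, oriented)
            if hi_cap is not None and hi > hi_cap:
                continue
            key = (s, s + L)
            if key not in hits or hi < hits[key][0] - 1e-9:
                hits[key] = (hi, strand, oriented)
    return hits


class TestBuildMatrix:
    def test_degenerate_alignment_of_canonical_copies(self):
        m = build_matrix([CANONICAL_BOX] * 10)
        assert m.consensus == CANONICAL_BOX
        assert m.n_sites == 10
        for i, b in enumerate(CANONICAL_BOX):
            assert m.counts[i]["ACGT".index(b)] == 10
            assert m.counts[i].sum() == 10

    def test_tie_breaks_toward_canonical_then_alphabetical(self):
        # final column ties A/T; the canonical box has T at position 3
        m = build_matrix(["ACGA", "ACGT"], core_positions=())
        assert m.consensus[3] == "T"
        # without a canonical winner the tie falls back to alphabetical order
        m2 = build_matrix(["ACCG", "ACCC"], core_positions=())
        assert m2.consensus[3] == "C"

    def test_rejects_ragged_and_tiny_inputs(self):
        with pytest.raises(MatrixFormatError):
            build_matrix(["ACGT", "ACG"])
        with pytest.raises(MatrixFormatError):
            build_matrix(["ACGT"])

    def test_packaged_matrix_is_consistent(self, matrix):
        assert (matrix.counts.sum(axis=1) == matrix.n_sites).all()
        assert matrix.consensus == CANONICAL_BOX
        for pos, base in matrix.core_positions:
            assert matrix.counts[pos]["ACGT".index(base)] == matrix.n_sites

    def test_tsv_roundtrip(self, matrix, tmp_path):
        path = tmp_path / "m.tsv"
        matrix.save(path)
        loaded = SosBoxMatrix.load(path)
        assert (loaded.counts == matrix.counts).all()
        assert loaded.consensus == matrix.consensus
        assert loaded.core_positions == matrix.core_positions
        assert loaded.pseudocount == matrix.pseudocount


class TestHiScore:
    def test_consensus_scores_zero(self, matrix):
        assert hi_score(matrix, matrix.consensus) == 0.0

    def test_uniform_matrix_scores_everything_zero(self):
        m = SosBoxMatrix(motif_length=4, counts=np.full((4, 4), 5), core_positions=())
        for w in ["AAAA", "ACGT", "TTTT", "GCGC"]:
            assert hi_score(m, w) == pytest.approx(0.0)

    def test_matches_per_position_hand_sum(self, matrix, rng):
        from conftest import random_window

        for window in random_window(rng, matrix, n=50):
            assert hi_score(matrix, window) == pytest.approx(
                brute_force_hi(matrix, window), abs=1e-9
            )

    def test_rejects_bad_windows(self, matrix):
        with pytest.raises(ValueError):
            hi_score(matrix, "ACGT")
        with pytest.raises(ValueError):
            hi_score(matrix, "N" * matrix.motif_length)

    @given(st.text(alphabet="ACGT", min_size=20, max_size=20))
    def test_nonnegative_and_zero_only_at_count_maximal(self, window):
        m = default_matrix()
        hi = hi_score(m, window)
        assert hi >= 0.0
        maximal = all(
            m.counts[i]["ACGT".index(b)] == m.counts[i].max()
            for i, b in enumerate(window)
        )
        assert (hi == pytest.approx(0.0, abs=1e-12)) == maximal

    @given(st.text(alphabet="ACGT", min_size=20, max_size=20))
    def test_strand_symmetry_of_packaged_matrix(self, window):
        """The symmetrized matrix scores a window and its reverse complement
        identically, as a palindromic double-stranded site demands."""
        m = default_matrix()
        assert hi_score(m, window) == pytest.approx(
            hi_score(m, reverse_complement(window)), abs=1e-9
        )

    def test_additive_over_concatenated_halves(self, matrix, rng):
        from conftest import random_window

        left = SosBoxMatrix(10, matrix.counts[:10], matrix.pseudocount,
                            core_positions=())
        right = SosBoxMatrix(10, matrix.counts[10:], matrix.pseudocount,
                             core_positions=())
        for window in random_window(rng, matrix, n=20):
            # half-matrices recompute their own consensus; additivity holds
            # relative to those local consensi
            expected = brute_force_hi(left, window[:10]) + brute_force_hi(
                right, window[10:]
            )
            got = hi_score(left, window[:10]) + hi_score(right, window[10:])
            assert got == pytest.approx(expected, abs=1e-9)


class TestScanRegion:
    def test_poly_a_has_no_core_match(self, matrix):
        g = GenomeRecord("r", "A" * 500)
        assert scan_region(matrix, g) == []

    def test_canonical_box_is_palindromic_single_hit(self, matrix):
        assert reverse_complement(CANONICAL_BOX) == CANONICAL_BOX
        seq = "A" * 100 + CANONICAL_BOX + "A" * 100
        hits = scan_region(matrix, GenomeRecord("r", seq))
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end) == (100, 120)
        assert h.hi == pytest.approx(0.0)
        assert h.strand == "+"  # both strands tie at 0; tie keeps plus

    def test_designed_boxes_recovered_at_their_hi(self, matrix):
        from sosdep.synthetic_fixtures import design_sequence_for_hi

        b1 = design_sequence_for_hi(matrix, 5.0, 0.25, seed=1)
        b2 = design_sequence_for_hi(matrix, 18.0, 0.25, seed=2)
        seq = "A" * 60 + b1 + "A" * 60 + b2 + "A" * 60
        hits = scan_region(matrix, GenomeRecord("r", seq))
        assert len(hits) == 2
        assert hits[0].hi == pytest.approx(5.0, abs=0.5)
        assert hits[1].hi == pytest.approx(18.0, abs=0.5)

    def test_windows_with_n_are_skipped(self, matrix):
        box = CANONICAL_BOX[:10] + "N" + CANONICAL_BOX[11:]
        seq = "A" * 50 + box + "A" * 50
        assert scan_region(matrix, GenomeRecord("r", seq)) == []

    def test_short_interval_yields_empty(self, matrix):
        g = GenomeRecord("r", CANONICAL_BOX * 3)
        assert scan_region(matrix, g, interval=(0, 10)) == []

    def test_equals_brute_force_oracle_on_random_sequences(self, matrix, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=2000))
            got = {
                (h.start, h.end): (h.hi, h.strand, h.sequence)
                for h in scan_region(matrix, GenomeRecord("r", seq))
            }
            want = brute_force_scan(matrix, seq)
            assert got.keys() == want.keys()
            for key in want:
                assert got[key][0] == pytest.approx(want[key][0], abs=1e-9)
                assert got[key][1:] == want[key][1:]

    def test_mismatch_allowance_and_hi_cap(self, matrix, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        for mm, cap in [(1, None), (0, 10.0), (2, 25.0)]:
            got = {
                (h.start, h.end)
                for h in scan_region(matrix, GenomeRecord("r", seq), None, mm, cap)
            }
            want = set(brute_force_scan(matrix, seq, mm, cap))
            assert got == want
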