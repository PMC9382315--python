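import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonlogo.codon_matrix import (
    AlphabetSpec,
    compute_smax,
    count_codons,
    position_entropy,
    read_matrix_csv,
    select_alphabet,
    to_bits,
    to_probability,
    tokenize_codons,
    write_matrix,
)
from codonlogo.errors import (
    AlphabetMismatchError,
    ContractError,
    DegenerateColumnError,
    FrameError,
)

from conftest import make_alignment

# Frozen oracle values for the two-symbol (0.75, 0.25) row.
H_75_25 = 0.8112781244591328
RSEQ_75_25 = 6 - H_75_25  # 5.1887218755408675


def brute_force_entropy(probs):
    """Independent oracle: direct term-by-term summation."""
    total = 0.0
    for p in probs:
        if p > 0:
            total -= p * math.log2(p)
    return total


class TestTokenize:
    def test_frame_zero_split(self):
        assert tokenize_codons("ATGAAATGA") == ["ATG", "AAA", "TGA"]

    def test_gap_codon_null(self):
        assert tokenize_codons("ATG---AAA") == ["ATG", None, "AAA"]

    def test_partial_gap_codon_also_null(self):
        assert tokenize_codons("ATGA-AAAA") == ["ATG", None, "AAA"]

    def test_empty(self):
        assert tokenize_codons("") == []

    def test_frame_error(self):
        with pytest.raises(FrameError):
            tokenize_codons("ATGA")


class TestCountCodons:
    def test_tally(self):
        aln = make_alignment(["AAA", "AAA", "AAA", "AAT"])
        counts = count_codons(aln)
        assert counts.codons == ["AAA", "AAT"]
        assert counts.counts.tolist() == [[3, 1]]
        assert counts.depth_per_position.tolist() == [4]

    def test_all_gap_position_zero_depth(self):
        aln = make_alignment(["ATG---", "ATG---"])
        counts = count_codons(aln)
        assert counts.depth_per_position.tolist() == [2, 0]

    def test_conserved_single_column(self, conserved_alignment):
        counts = count_codons(conserved_alignment)
        assert counts.counts.shape == (3, 3)
        assert counts.depth_per_position.tolist() == [40, 40, 40]

    def test_columns_lexicographic(self):
        aln = make_alignment(["TTTAAA", "AAATTT"])
        assert count_codons(aln).codons == ["AAA", "TTT"]

    def test_permutation_invariance(self, fixture_40x10):
        fwd = count_codons(fixture_40x10)
        rev = count_codons(make_alignment(
            [r.sequence for r in reversed(fixture_40x10.records)]
        ))
        assert fwd.codons == rev.codons
        assert np.array_equal(fwd.counts, rev.counts)


class TestToProbability:
    def test_three_quarters(self):
        aln = make_alignment(["AAA", "AAA", "AAA", "AAT"])
        prob = to_probability(count_codons(aln))
        assert prob.row(1) == {"AAA": 0.75, "AAT": 0.25}

    def test_certainty(self, conserved_alignment):
        prob = to_probability(count_codons(conserved_alignment))
        assert prob.row(1)["ATG"] == 1.0

    def test_uniform_64(self):
        bases = "ACGT"
        codons = [a + b + c for a in bases for b in bases for c in bases]
        aln = make_alignment(codons)
        prob = to_probability(count_codons(aln))
        assert np.allclose(prob.values, 1 / 64)

    def test_rows_sum_to_one(self, fixture_40x10):
        prob = to_probability(count_codons(fixture_40x10))
        assert np.allclose(prob.values.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_depth_errors_naming_position(self):
        aln = make_alignment(["ATG---", "ATG---"])
        with pytest.raises(DegenerateColumnError, match="2"):
            to_probability(count_codons(aln))

    def test_drop_empty_positions(self):
        aln = make_alignment(["ATG---AAA", "ATG---AAA"])
        prob = to_probability(count_codons(aln), drop_empty_positions=True)
        assert prob.positions == [1, 3]


class TestPositionEntropy:
    def test_uniform_64_is_6_bits(self):
        assert position_entropy([1 / 64] * 64) == pytest.approx(6.0, abs=1e-12)

    def test_certain_is_zero(self):
        assert position_entropy([1.0]) == 0.0

    def test_75_25(self):
        assert position_entropy([0.75, 0.25]) == pytest.approx(
            H_75_25, abs=1e-12
        )

    def test_unnormalized_rejected(self):
        with pytest.raises(ContractError):
            position_entropy([0.5, 0.1])

    @settings(max_examples=200)
    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=8
        )
    )
    def test_matches_brute_force(self, weights):
        probs = np.array(weights) / sum(weights)
        assert position_entropy(probs) == pytest.approx(
            brute_force_entropy(probs), abs=1e-12
        )


class TestSmax:
    def test_codon_alphabet(self):
        assert compute_smax(AlphabetSpec.unambiguous()) == 6.0

    def test_nucleotide_alphabet(self):
        assert compute_smax(AlphabetSpec(4)) == 2.0

    def test_amino_acid_alphabet(self):
        assert round(compute_smax(AlphabetSpec(20)), 2) == 4.32

    def test_ambiguous_extended(self):
        assert compute_smax(AlphabetSpec.ambiguous_extended()) == (
            pytest.approx(11.720671786825555, abs=1e-12)
        )

    def test_too_small_alphabet(self):
        with pytest.raises(ValueError):
            AlphabetSpec(1)

    def test_mode_consistency(self):
        with pytest.raises(ValueError):
            AlphabetSpec(63, "unambiguous64")

    def test_auto_selection(self, fixture_40x10):
        counts = count_codons(fixture_40x10)
        assert select_alphabet(counts).n_symbols == 64
        ambiguous = make_alignment(["ATGANN", "ATGAAA"])
        assert select_alphabet(count_codons(ambiguous)).n_symbols == 3375


class TestToBits:
    def test_fully_conserved(self, conserved_alignment):
        prob = to_probability(count_codons(conserved_alignment))
        bits = to_bits(prob, 6.0)
        assert bits.rseq.tolist() == [6.0, 6.0, 6.0]
        assert bits.values.max() == 6.0

    def test_75_25_heights(self):
        aln = make_alignment(["AAA", "AAA", "AAA", "AAT"])
        bits = to_bits(to_probability(count_codons(aln)), 6.0)
        row = bits.row(1)
        assert row["AAA"] == pytest.approx(0.75 * RSEQ_75_25, abs=1e-12)
        assert row["AAT"] == pytest.approx(0.25 * RSEQ_75_25, abs=1e-12)
        assert bits.rseq[0] == pytest.approx(RSEQ_75_25, abs=1e-12)

    def test_uniform_64_all_zero(self):
        bases = "ACGT"
        codons = [a + b + c for a in bases for b in bases for c in bases]
        prob = to_probability(count_codons(make_alignment(codons)))
        bits = to_bits(prob, 6.0)
        assert np.allclose(bits.values, 0.0, atol=1e-9)

    def test_smax_too_small(self):
        aln = make_alignment(["AAA", "AAT", "AAG", "AAC"])
        prob = to_probability(count_codons(aln))
        with pytest.raises(AlphabetMismatchError):
            to_bits(prob, 1.0)

    def test_conservation_property(self, fixture_40x10):
        prob = to_probability(count_codons(fixture_40x10))
        bits = to_bits(prob, 6.0)
        assert np.allclose(bits.values.sum(axis=1), bits.rseq, atol=1e-9)
        assert np.allclose(bits.rseq, 6.0 - bits.entropy, atol=1e-12)
        assert (bits.values >= 0).all()

    def test_entropy_bounds(self, fixture_40x10):
        prob = to_probability(count_codons(fixture_40x10))
        bits = to_bits(prob, 6.0)
        assert (bits.entropy >= 0).all()
        assert (bits.entropy <= math.log2(40) + 1e-12).all()

    @given(st.floats(min_value=0.5, max_value=1.0 - 1e-9))
    def test_concentration_monotonicity(self, p):
        # a more concentrated 2-symbol row never has lower Rseq
        q = min(1.0, p + (1 - p) / 2)
        h_p = position_entropy([p, 1 - p])
        h_q = position_entropy([q, 1 - q])
        assert (6.0 - h_q) >= (6.0 - h_p) - 1e-12


class TestWriteMatrix:
    def test_header_shape(self, tmp_path):
        aln = make_alignment(["AAA", "AAA", "AAA", "AAT"])
        bits = to_bits(to_probability(count_codons(aln)), 6.0)
        path = write_matrix(bits, tmp_path / "m.csv")
        lines = path.read_text().splitlines()
        assert lines[0] == "position,AAA,AAT"
        assert len(lines) == 2

    def test_round_trip_lossless(self, tmp_path, fixture_40x10):
        bits = to_bits(to_probability(count_codons(fixture_40x10)), 6.0)
        path = write_matrix(bits, tmp_path / "m.csv")
        df = read_matrix_csv(path)
        assert list(df.columns) == bits.codons
        assert np.abs(df.to_numpy() - bits.values).max() <= 1e-12

    def test_probability_rows_sum_to_one(self, tmp_path, fixture_40x10):
        prob = to_probability(count_codons(fixture_40x10))
        path = write_matrix(prob, tmp_path / "p.csv")
        df = read_matrix_csv(path)
        assert np.allclose(df.sum(axis=1), 1.0, atol=1e-9)
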