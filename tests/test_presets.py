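"""Preset machines: coding behaviour, error models, CTC, translation."""

import itertools
import math
import re

import numpy as np
import pytest

from seqfst import algebra, decode, inference, presets
from seqfst.core import machine_stats

from .oracles import all_strings, ctc_oracle_weight

NEG_INF = float("-inf")


def fwd(m, x, y, p=None):
    lw = inference.forward(m, x, y, p).log_weight
    return math.exp(lw) if lw > NEG_INF else 0.0


class TestGeneratorRecognizer:
    def test_generator_emits_exactly_its_sequence(self):
        g = presets.generator("TCGA")
        assert fwd(g, "", "TCGA") == pytest.approx(1.0)
        for y in ("", "TCG", "TCGG"):
            assert fwd(g, "", y) == 0.0

    def test_recognizer_is_the_transpose(self):
        r = presets.recognizer("TCGA")
        for x in ("TCGA", "TCG", ""):
            assert fwd(r, x, "") == fwd(presets.generator("TCGA"), "", x)

    def test_empty_sequence_gives_single_state_machine(self):
        g = presets.generator("")
        assert len(g.states) == 1
        assert fwd(g, "", "") == pytest.approx(1.0)


class TestRegex:
    @pytest.mark.parametrize("pattern", ["AC*G", "A|C", "[AG].T", "(AC)+T",
                                         "G?A", "A[CT]G|TT*"])
    def test_agrees_with_python_regex_engine(self, pattern):
        m = presets.regex_machine(pattern, "ACGT")
        compiled = re.compile(f"^(?:{pattern})$")
        for s in all_strings("ACGT", 4):
            expect = 1.0 if compiled.match(s) else 0.0
            assert fwd(m, s, "") == pytest.approx(expect), (pattern, s)

    @pytest.mark.parametrize("bad", ["A(", "[", "*A", "A)B", "[]T", "AZ"])
    def test_malformed_pattern_rejected(self, bad):
        with pytest.raises(ValueError):
            presets.regex_machine(bad, "ACGT")


class TestDnaToRna:
    def test_thymine_maps_to_uracil_only(self):
        m = presets.dna_to_rna()
        assert fwd(m, "T", "U") == pytest.approx(1.0)
        assert fwd(m, "T", "T") == 0.0

    def test_composition_with_taq_site(self):
        comp = algebra.compose(presets.generator("TCGA"), presets.dna_to_rna())
        assert fwd(comp, "", "UCGA") == pytest.approx(1.0)


class TestBinaryToTernary:
    @pytest.mark.parametrize("bits,trits", [
        ("000", "00"), ("001", "01"), ("010", "02"), ("011", "10"),
        ("100", "11"), ("101", "12"), ("110", "20"), ("111", "21"),
    ])
    def test_batch_mapping(self, bits, trits):
        m = presets.binary_to_ternary(with_eof=False)
        assert fwd(m, bits, trits) == pytest.approx(1.0)

    def test_eof_marker_appended(self):
        m = presets.binary_to_ternary(with_eof=True)
        assert fwd(m, "111", "2122") == pytest.approx(1.0)
        assert fwd(m, "", "22") == pytest.approx(1.0)

    def test_length_not_multiple_of_three_rejected_without_eof(self):
        m = presets.binary_to_ternary(with_eof=False)
        out, _ = decode.viterbi_output(m, "0000")
        assert out is None

    def test_aligned_trit_pair_22_never_precedes_the_marker(self):
        """Exhaustively over all bit strings of length <= 12: reading the
        output in aligned trit pairs, "22" appears only as the final
        end-of-message marker."""
        m = presets.binary_to_ternary(with_eof=True)
        for n in range(0, 13, 3):
            for bits in itertools.product("01", repeat=n):
                out, lw = decode.viterbi_output(m, "".join(bits))
                assert out is not None and out.endswith("22")
                pairs = [out[i:i + 2] for i in range(0, len(out), 2)]
                assert "22" not in pairs[:-1], bits


class TestTernaryToDna:
    def test_start_convention(self):
        m = presets.ternary_to_dna()
        assert fwd(m, "00", "AC") == pytest.approx(1.0)

    def test_rule_derived_example(self):
        # 0 -> A (start treats previous base as T); 1 from prev A -> G
        # (sorted {C,G,T}[1]); 2 from prev G -> T (sorted {A,C,T}[2])
        m = presets.ternary_to_dna()
        assert fwd(m, "012", "AGT") == pytest.approx(1.0)

    def test_output_never_repeats_adjacent_bases(self):
        m = presets.ternary_to_dna()
        for n in range(1, 9):
            for trits in itertools.product("012", repeat=n):
                out, _ = decode.viterbi_output(m, "".join(trits))
                assert out is not None
                assert all(a != b for a, b in zip(out, out[1:])), trits

    def test_has_five_states(self):
        assert machine_stats(presets.ternary_to_dna()).n_states == 5


class TestStorageCode:
    def test_encoded_output_is_repeat_free(self):
        from seqfst import coding
        dna = coding.encode_bits("110101001110101")
        assert all(a != b for a, b in zip(dna, dna[1:]))

    def test_round_trip_on_sample_messages(self, rng):
        from seqfst import coding
        for _ in range(20):
            n = int(rng.integers(1, 40))
            msg = "".join(rng.choice(["0", "1"], size=n))
            assert coding.decode_dna(coding.encode_bits(msg), n) == msg

    def test_decode_rejects_dna_outside_the_image(self):
        from seqfst import coding
        with pytest.raises(ValueError, match="image"):
            coding.decode_dna("AAAA")


class TestHamming:
    def test_codeword_for_1011(self):
        from seqfst import coding
        assert coding.hamming_encode("1011") == "0110011"

    def test_zero_noise_channel_is_bit_identity(self):
        ch = presets.bitflip_channel(0.0)
        assert fwd(ch, "0110", "0110") == pytest.approx(1.0)
        assert fwd(ch, "0110", "0111") == 0.0

    def test_every_single_bit_error_corrected(self):
        """All 16 codewords x 7 flip positions decode back to the data bits
        by maximum-likelihood decoding through the noisy channel."""
        from seqfst import coding
        for bits in itertools.product("01", repeat=4):
            data = "".join(bits)
            cw = coding.hamming_encode(data)
            for pos in range(7):
                corrupted = (cw[:pos] + ("1" if cw[pos] == "0" else "0")
                             + cw[pos + 1:])
                assert coding.hamming_decode(corrupted, q=0.05) == data, \
                    (data, pos)

    def test_invalid_flip_probability_rejected(self):
        with pytest.raises(ValueError):
            presets.bitflip_channel(1.5)


class TestErrorModels:
    def test_sci_has_five_states(self):
        assert machine_stats(presets.error_model_sci()).n_states == 5

    def test_acd_has_fifty_states(self):
        assert machine_stats(presets.error_model_acd()).n_states == 50

    def test_acd_blocks_cover_sixteen_contexts(self):
        m = presets.error_model_acd()
        match_states = [s for s in m.states if s.startswith("M")]
        assert len(match_states) == 16
        assert len([s for s in m.states if s.startswith("I")]) == 16
        assert len([s for s in m.states if s.startswith("D")]) == 16

    def test_sci_degenerates_to_exact_matching(self):
        degen = {**{f"sub_{a}{b}": (1.0 if a == b else 0.0)
                    for a in "ACGT" for b in "ACGT"},
                 "gap_open": 0.0, "gap_ext": 0.0}
        m = presets.error_model_sci(degen)
        assert fwd(m, "GATTA", "GATTA") == pytest.approx(1.0)
        assert fwd(m, "GATTA", "GATTC") == 0.0

    def test_sci_aligns_with_gaps_under_defaults(self):
        m = presets.error_model_sci()
        assert fwd(m, "ACGT", "ACT") > 0.0  # one deletion
        assert fwd(m, "ACT", "ACGT") > 0.0  # one insertion

    def test_acd_composes_with_translation(self):
        # a protein-to-noisy-DNA aligner, as used for nanopore read search
        aligner = algebra.compose(presets.protein_to_codon(),
                                  presets.error_model_acd())
        assert fwd(aligner, "MW", "ATGTGG") > 0.0


class TestProteinToCodon:
    def test_single_codon_amino_acids(self):
        m = presets.protein_to_codon()
        assert fwd(m, "M", "ATG") == pytest.approx(1.0)
        assert fwd(m, "W", "TGG") == pytest.approx(1.0)

    def test_uniform_weights_split_synonymous_codons(self):
        m = presets.protein_to_codon()
        assert fwd(m, "F", "TTT") == pytest.approx(0.5)
        assert fwd(m, "F", "TTC") == pytest.approx(0.5)

    def test_non_normalized_weights_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            presets.protein_to_codon({"F": {"TTT": 0.9, "TTC": 0.2}})


class TestCtcRecognizer:
    def test_adjacent_repeats_merge(self):
        P = np.array([[1, 0, 0, 0, 0], [1, 0, 0, 0, 0]], float)
        m = presets.ctc_recognizer(P, "ACGT")
        assert fwd(m, "A", "") == pytest.approx(1.0)
        assert fwd(m, "AA", "") == 0.0

    def test_blank_separates_repeats(self):
        P = np.array([[1, 0, 0, 0, 0], [0, 0, 0, 0, 1], [1, 0, 0, 0, 0]], float)
        m = presets.ctc_recognizer(P, "ACGT")
        assert fwd(m, "AA", "") == pytest.approx(1.0)
        assert fwd(m, "A", "") == 0.0

    def test_matches_exhaustive_collapse_oracle(self, rng):
        """Recognizer weight equals the sum over all 5^T framewise paths
        that collapse to the label sequence, for random 4-frame matrices."""
        for _ in range(4):
            P = rng.uniform(0.05, 1.0, size=(4, 5))
            m = presets.ctc_recognizer(P, "ACGT")
            for y in all_strings("ACGT", 4):
                assert fwd(m, y, "") == pytest.approx(
                    ctc_oracle_weight(P, "ACGT", y), rel=1e-9, abs=1e-12), y

    def test_dataframe_input_with_named_columns(self):
        import pandas as pd
        df = pd.DataFrame({"A": [1.0, 0.0], "C": [0.0, 1.0],
                           "blank": [0.0, 0.0]})
        m = presets.ctc_recognizer(df)
        assert fwd(m, "AC", "") == pytest.approx(1.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            presets.ctc_recognizer(np.zeros((0, 5)), "ACGT")


class TestJukesCantor:
    def test_zero_time_is_identity(self):
        m = presets.jukes_cantor(0.0)
        assert fwd(m, "ACGT", "ACGT") == pytest.approx(1.0)
        assert fwd(m, "A", "C") == 0.0

    def test_long_time_limit_is_uniform(self):
        m = presets.jukes_cantor(1e6)
        assert fwd(m, "A", "C") == pytest.approx(0.25, abs=1e-9)
        assert fwd(m, "A", "A") == pytest.approx(0.25, abs=1e-9)

    def test_rows_sum_to_one(self):
        m = presets.jukes_cantor(0.37, rate=2.0)
        for a in "ACGT":
            total = sum(fwd(m, a, b) for b in "ACGT")
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            presets.jukes_cantor(-1.0)


class TestKmerAvoiding:
    @pytest.mark.parametrize("k,prohibited", [
        (2, ["AA", "CC"]),
        (3, ["ACA", "CAC", "AAA"]),
    ])
    def test_accepts_exactly_motif_free_strings(self, k, prohibited):
        """Exhaustive over a binary sub-alphabet: acceptance (weight 1) iff
        no prohibited k-mer occurs, for strings up to length 10."""
        m = presets.kmer_avoiding_recognizer(k, prohibited, "AC")
        for s in all_strings("AC", 10):
            has_bad = any(s[i:i + k] in prohibited
                          for i in range(len(s) - k + 1))
            assert fwd(m, s, "") == pytest.approx(0.0 if has_bad else 1.0), s

    def test_bad_kmer_length_rejected(self):
        with pytest.raises(ValueError):
            presets.kmer_avoiding_recognizer(2, ["AAA"])
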