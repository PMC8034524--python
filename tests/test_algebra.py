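"""Machine algebra against brute-force enumeration oracles.

Every operation is checked against its defining matrix/string identity,
computed independently by naive path enumeration on the operand machines
(tests.oracles), on batches of random small machines.
"""

import math

import pytest

from seqfst import algebra, inference, presets
from seqfst.core import machine, transition

from .oracles import all_strings, brute_force_forward, random_machine

TOL = 1e-9


def fwd(m, x, y):
    lw = inference.forward(m, x, y).log_weight
    return math.exp(lw) if lw > -math.inf else 0.0


class TestCompose:
    def test_taq_site_to_rna(self):
        comp = algebra.compose(presets.generator("TCGA"), presets.dna_to_rna())
        assert fwd(comp, "", "UCGA") == pytest.approx(1.0)
        assert fwd(comp, "", "TCGA") == 0.0
        assert fwd(comp, "", "UCG") == 0.0

    def test_identity_is_right_unit(self, rng):
        for _ in range(10):
            t = random_machine(rng, n_states=4, in_alpha="ab", out_alpha="xy",
                               acyclic=True)
            tid = algebra.compose(t, algebra.identity_machine("xy"))
            for x in all_strings("ab", 2):
                for y in all_strings("xy", 2):
                    assert fwd(tid, x, y) == pytest.approx(fwd(t, x, y), abs=TOL)

    def test_matrix_product_identity_against_enumeration(self, rng):
        """Forward(TU, x, z) = sum over y of T[x,y] U[y,z], the sum running
        over all intermediate sequences up to the acyclic path bound."""
        for _ in range(15):
            t = random_machine(rng, n_states=int(rng.integers(2, 5)),
                               in_alpha="ab", out_alpha="pq", acyclic=True)
            u = random_machine(rng, n_states=int(rng.integers(2, 5)),
                               in_alpha="pq", out_alpha="xy", acyclic=True)
            tu = algebra.compose(t, u)
            for x in all_strings("ab", 2):
                for z in all_strings("xy", 2):
                    expect = sum(brute_force_forward(t, x, y)
                                 * brute_force_forward(u, y, z)
                                 for y in all_strings("pq", 6))
                    assert fwd(tu, x, z) == pytest.approx(expect, abs=1e-7), \
                        (x, z)

    def test_associative_under_forward(self, rng):
        for _ in range(5):
            t = random_machine(rng, 3, "ab", "pq", acyclic=True)
            u = random_machine(rng, 3, "pq", "mn", acyclic=True)
            v = random_machine(rng, 3, "mn", "xy", acyclic=True)
            left = algebra.compose(algebra.compose(t, u), v)
            right = algebra.compose(t, algebra.compose(u, v))
            for x in all_strings("ab", 2):
                for z in all_strings("xy", 2):
                    assert fwd(left, x, z) == pytest.approx(fwd(right, x, z),
                                                            abs=1e-9)

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(algebra.AlphabetMismatchError):
            algebra.compose(presets.generator("AC"), presets.dna_to_rna())


class TestAdd:
    def test_sum_of_generators(self):
        m = algebra.add(presets.generator("A", "ACGT"),
                        presets.generator("C", "ACGT"))
        assert fwd(m, "", "A") == pytest.approx(1.0)
        assert fwd(m, "", "C") == pytest.approx(1.0)

    def test_zero_machine_is_additive_identity(self, rng):
        zero = machine("ab", "xy", ["s", "end"], [])
        for _ in range(5):
            t = random_machine(rng, 4, "ab", "xy", acyclic=True)
            s = algebra.add(t, zero)
            for x in all_strings("ab", 2):
                for y in all_strings("xy", 2):
                    assert fwd(s, x, y) == pytest.approx(fwd(t, x, y), abs=TOL)

    def test_linearity_of_scaled_sum(self, rng):
        g = random_machine(rng, 4, "", "xy", acyclic=True)
        s = algebra.add(algebra.scale(0.3, g), algebra.scale(0.7, g))
        for y in all_strings("xy", 3):
            assert fwd(s, "", y) == pytest.approx(brute_force_forward(g, "", y),
                                                  abs=1e-9)

    def test_pointwise_sum_commutative_and_matches_oracle(self, rng):
        for _ in range(10):
            t = random_machine(rng, 4, "ab", "xy", acyclic=True)
            u = random_machine(rng, 4, "ab", "xy", acyclic=True)
            s1, s2 = algebra.add(t, u), algebra.add(u, t)
            for x in all_strings("ab", 2):
                for y in all_strings("xy", 2):
                    expect = (brute_force_forward(t, x, y)
                              + brute_force_forward(u, x, y))
                    assert fwd(s1, x, y) == pytest.approx(expect, abs=1e-9)
                    assert fwd(s2, x, y) == pytest.approx(expect, abs=1e-9)


class TestIntersect:
    def test_identical_recognizers(self):
        m = algebra.intersect(presets.recognizer("ACG", "ACGT"),
                              presets.recognizer("ACG", "ACGT"))
        assert fwd(m, "ACG", "") == pytest.approx(1.0)

    def test_disjoint_recognizers_are_zero(self):
        m = algebra.intersect(presets.recognizer("ACG", "ACGT"),
                              presets.recognizer("TTT", "ACGT"))
        for x in all_strings("ACGT", 3):
            assert fwd(m, x, "") == 0.0

    def test_pointwise_product_on_random_recognizers(self, rng):
        for _ in range(10):
            t = random_machine(rng, 4, "ab", "", acyclic=True)
            u = random_machine(rng, 4, "ab", "", acyclic=True)
            i = algebra.intersect(t, u)
            for x in all_strings("ab", 4):
                expect = brute_force_forward(t, x, "") * brute_force_forward(u, x, "")
                assert fwd(i, x, "") == pytest.approx(expect, abs=1e-9), x


class TestTranspose:
    def test_generator_becomes_recognizer(self):
        r = algebra.transpose(presets.generator("AC"))
        assert r.is_recognizer
        assert fwd(r, "AC", "") == pytest.approx(1.0)

    def test_involution(self, rng):
        t = random_machine(rng, 4, "ab", "xy")
        tt = algebra.transpose(algebra.transpose(t))
        assert tt.transitions == t.transitions

    def test_forward_equality_on_random_triples(self, rng):
        for _ in range(50):
            t = random_machine(rng, int(rng.integers(2, 5)), "ab", "xy")
            tr = algebra.transpose(t)
            x = "".join(rng.choice(list("ab"), size=rng.integers(0, 3)))
            y = "".join(rng.choice(list("xy"), size=rng.integers(0, 3)))
            assert fwd(tr, y, x) == pytest.approx(fwd(t, x, y), abs=TOL)


class TestConcat:
    def test_generators_concatenate(self):
        m = algebra.concat(presets.generator("AC", "ACGT"),
                           presets.generator("GT", "ACGT"))
        assert fwd(m, "", "ACGT") == pytest.approx(1.0)
        assert fwd(m, "", "AC") == 0.0

    def test_epsilon_machine_is_unit(self, rng):
        eps = machine("ab", "xy", ["s"], [])
        t = random_machine(rng, 4, "ab", "xy", acyclic=True)
        c = algebra.concat(t, eps)
        for x in all_strings("ab", 2):
            for y in all_strings("xy", 2):
                assert fwd(c, x, y) == pytest.approx(fwd(t, x, y), abs=TOL)

    def test_weights_multiply_across_the_join(self):
        g = algebra.scale(0.5, presets.generator("A"))
        m = algebra.concat(g, g)
        assert fwd(m, "", "AA") == pytest.approx(0.25)

    def test_split_sum_identity(self, rng):
        for _ in range(5):
            t = random_machine(rng, 3, "", "xy", acyclic=True)
            u = random_machine(rng, 3, "", "xy", acyclic=True)
            c = algebra.concat(t, u)
            for y in all_strings("xy", 3):
                expect = sum(brute_force_forward(t, "", y[:k])
                             * brute_force_forward(u, "", y[k:])
                             for k in range(len(y) + 1))
                assert fwd(c, "", y) == pytest.approx(expect, abs=1e-9)


class TestReverse:
    def test_generator_reversed(self):
        m = algebra.reverse(presets.generator("ACG"))
        assert fwd(m, "", "GCA") == pytest.approx(1.0)
        assert fwd(m, "", "ACG") == 0.0

    def test_double_reverse_restores_forward(self, rng):
        for _ in range(10):
            t = random_machine(rng, 4, "ab", "xy", acyclic=True)
            rr = algebra.reverse(algebra.reverse(t))
            for x in all_strings("ab", 2):
                for y in all_strings("xy", 2):
                    assert fwd(rr, x, y) == pytest.approx(fwd(t, x, y), abs=TOL)

    def test_forward_of_reversed_pair(self, rng):
        for _ in range(10):
            t = random_machine(rng, 4, "ab", "xy", acyclic=True)
            r = algebra.reverse(t)
            for x in all_strings("ab", 2):
                for y in all_strings("xy", 2):
                    assert fwd(r, x[::-1], y[::-1]) == pytest.approx(
                        fwd(t, x, y), abs=TOL)


class TestReverseComplement:
    def test_simple_generator(self):
        m = algebra.reverse_complement(presets.generator("AC", "ACGT"))
        assert fwd(m, "", "GT") == pytest.approx(1.0)

    def test_taq_site_is_its_own_reverse_complement(self):
        m = algebra.reverse_complement(presets.generator("TCGA"))
        assert fwd(m, "", "TCGA") == pytest.approx(1.0)

    def test_involution(self, rng):
        t = random_machine(rng, 4, "ACGT", "ACGT", acyclic=True)
        rr = algebra.reverse_complement(algebra.reverse_complement(t))
        for x in all_strings("ACG", 2):
            for y in all_strings("ACG", 2):
                assert fwd(rr, x, y) == pytest.approx(fwd(t, x, y), abs=TOL)

    def test_non_nucleic_alphabet_rejected(self):
        with pytest.raises(ValueError, match="not nucleic"):
            algebra.reverse_complement(presets.generator("ab", "ab"))


class TestKleeneStar:
    def test_unweighted_repeat(self):
        m = algebra.kleene_star(presets.generator("A"))
        assert fwd(m, "", "AAA") == pytest.approx(1.0)
        assert fwd(m, "", "") == pytest.approx(1.0)

    def test_weighted_repeat_multiplies(self):
        m = algebra.kleene_star(algebra.scale(0.5, presets.generator("A")))
        assert fwd(m, "", "AAA") == pytest.approx(0.125)

    def test_divergent_closure_rejected(self):
        eps_weight_one = machine((), "A", ["s"], [])  # accepts empty, weight 1
        with pytest.raises(ValueError, match="diverges"):
            algebra.kleene_star(eps_weight_one)


class TestRepeatScaleFlank:
    def test_repeat_n_concatenates(self):
        m = algebra.repeat_n(presets.generator("AC"), 3)
        assert fwd(m, "", "ACACAC") == pytest.approx(1.0)

    def test_repeat_one_is_identity(self, rng):
        t = random_machine(rng, 3, "", "xy", acyclic=True)
        r = algebra.repeat_n(t, 1)
        for y in all_strings("xy", 2):
            assert fwd(r, "", y) == pytest.approx(fwd(t, "", y), abs=TOL)

    def test_repeat_two_equals_concat_with_self(self, rng):
        t = random_machine(rng, 3, "", "xy", acyclic=True)
        a, b = algebra.repeat_n(t, 2), algebra.concat(t, t)
        for y in all_strings("xy", 4):
            assert fwd(a, "", y) == pytest.approx(fwd(b, "", y), abs=TOL)

    def test_repeat_zero_rejected(self):
        with pytest.raises(ValueError):
            algebra.repeat_n(presets.generator("A"), 0)

    def test_scale_multiplies_every_weight(self):
        m = algebra.scale(0.5, presets.generator("A"))
        assert fwd(m, "", "A") == pytest.approx(0.5)

    def test_scale_by_one_is_identity(self, rng):
        t = random_machine(rng, 4, "", "xy", acyclic=True)
        s = algebra.scale(1.0, t)
        for y in all_strings("xy", 3):
            assert fwd(s, "", y) == pytest.approx(fwd(t, "", y), abs=TOL)

    def test_symbolic_scale_doubles_after_assignment(self):
        m = algebra.scale("alpha", presets.generator("A"))
        assert math.exp(inference.forward(m, "", "A", {"alpha": 2.0}).log_weight
                        ) == pytest.approx(2.0)

    def test_local_flank_embeds_pattern(self):
        m = algebra.local_flank(presets.recognizer("TCGA"))
        assert fwd(m, "GGTCGAGG", "") >= 1.0 - TOL
        assert fwd(m, "TCGA", "") >= 1.0 - TOL
        assert fwd(m, "GGTGGA", "") == 0.0

    def test_local_flank_rejects_two_tape_machines(self):
        with pytest.raises(ValueError):
            algebra.local_flank(presets.dna_to_rna())


class TestIdentity:
    def test_matches_on_equal_strings_only(self):
        idm = algebra.identity_machine("ACGT")
        assert fwd(idm, "ACG", "ACG") == pytest.approx(1.0)
        assert fwd(idm, "ACG", "ACT") == 0.0

    def test_idempotent_under_composition(self):
        idm = algebra.identity_machine("AC")
        comp = algebra.compose(idm, idm)
        for x in all_strings("AC", 3):
            assert fwd(comp, x, x) == pytest.approx(1.0)

    def test_empty_alphabet_rejected(self):
        with pytest.raises(ValueError):
            algebra.identity_machine("")
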