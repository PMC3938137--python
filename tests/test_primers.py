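import itertools

import numpy as np
import pytest

from dmakit.primers import (PrimerConstraints, design_primers, dimer_score,
                            gc_fraction, hairpin_check, max_homopolymer_run,
                            melting_temperature, reverse_complement,
                            screen_oligo)


def hairpin_oracle(seq, min_stem, min_loop):
    """Exhaustive substring-pair scan for the best hairpin stem."""
    n = len(seq)
    best = 0
    for L in range(min_stem, n + 1):
        for i in range(0, n - L + 1):
            for j in range(i + L + min_loop, n - L + 1):
                if seq[j:j + L] == reverse_complement(seq[i:i + L]):
                    best = max(best, L)
    return best >= min_stem, best


def dimer_oracle(seq1, seq2):
    """Best contiguous complementary run over all antiparallel offsets,
    via explicit base-pair table."""
    pair = {"A": "T", "T": "A", "C": "G", "G": "C"}
    s2 = seq2[::-1]
    best = 0
    for off in range(-(len(s2) - 1), len(seq1)):
        run = 0
        for k, c2 in enumerate(s2):
            i = off + k
            if 0 <= i < len(seq1) and pair[seq1[i]] == c2:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


class TestBasicMetrics:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGC", 0.5), ("GGCC", 1.0), ("ATAT", 0.0)])
    def test_gc_fraction(self, seq, expected):
        assert gc_fraction(seq) == expected

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            gc_fraction("ACGN")

    @pytest.mark.parametrize("seq,expected", [
        ("AAAT", 3), ("ACGT", 1), ("TTTTT", 5)])
    def test_max_homopolymer_run(self, seq, expected):
        assert max_homopolymer_run(seq) == expected


class TestMeltingTemperature:
    def test_wallace_worked_examples(self):
        assert melting_temperature("ACGT", "wallace") == 12
        assert melting_temperature("AAAATTTT", "wallace") == 16

    def test_wallace_exact_on_enumerated_short_oligos(self):
        for tup in itertools.product("ACGT", repeat=4):
            seq = "".join(tup)
            at = seq.count("A") + seq.count("T")
            gc = seq.count("G") + seq.count("C")
            assert melting_temperature(seq, "wallace") == 2 * at + 4 * gc

    def test_nn_duplex_symmetry(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        for _ in range(50):
            seq = "".join(rng.choice(bases, size=int(rng.integers(18, 26))))
            assert melting_temperature(seq) == pytest.approx(
                melting_temperature(reverse_complement(seq)), abs=1e-9)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTACGT", "bogus")


class TestHairpin:
    def test_perfect_stem_detected(self):
        flag, stem = hairpin_check("GGGGAAAACCCC", 4, 4)
        assert flag and stem == 4
        assert hairpin_oracle("GGGGAAAACCCC", 4, 4) == (True, 4)

    def test_alternating_sequence_clean(self):
        flag, _ = hairpin_check("ACACACACAC", 4, 3)
        assert flag is False

    def test_stem_longer_than_half_impossible(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=10))
        flag, _ = hairpin_check(seq, min_stem=6, min_loop=3)
        assert not flag

    def test_matches_exhaustive_oracle_on_random_oligos(self):
        rng = np.random.default_rng(4)
        bases = np.array(list("ACGT"))
        for _ in range(60):
            seq = "".join(rng.choice(bases, size=int(rng.integers(10, 22))))
            ours = hairpin_check(seq, 3, 3)
            oracle = hairpin_oracle(seq, 3, 3)
            assert ours[0] == oracle[0]
            assert ours[1] == oracle[1]


class TestDimer:
    def test_full_complement(self):
        assert dimer_score("AAAA", "TTTT") == 4

    def test_palindrome_self_dimer(self):
        assert dimer_score("ACGT", "ACGT") == 4

    def test_non_pairing_bases_score_zero(self):
        assert dimer_score("AAAA", "AAAA") == 0

    def test_symmetry_and_oracle_agreement(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        for _ in range(40):
            s1 = "".join(rng.choice(bases, size=int(rng.integers(6, 20))))
            s2 = "".join(rng.choice(bases, size=int(rng.integers(6, 20))))
            assert dimer_score(s1, s2) == dimer_score(s2, s1)
            assert dimer_score(s1, s2) == dimer_oracle(s1, s2)


class TestDesignPrimers:
    def test_planted_pair_ranked_first(self):
        from dmakit.simulate import gen_template
        _name, seq, truth = gen_template(seed=9)
        result = design_primers(seq, PrimerConstraints(), top_k=5)
        top = result.pairs[0]
        assert (top.forward.start, top.forward.length) == truth.planted_forward
        assert (top.reverse.start, top.reverse.length) == truth.planted_reverse

    def test_unconstrained_candidate_count_is_closed_form(self):
        rng = np.random.default_rng(3)
        template = "".join(rng.choice(list("ACGT"), size=60))
        constraints = PrimerConstraints(
            gc_min=0.0, gc_max=1.0, tm_min=-1e9, tm_max=1e9,
            max_tm_difference=None, max_run=None, hairpin_min_stem=None,
            max_dimer_score=None, amplicon_min=30, amplicon_max=60)
        result = design_primers(template, constraints, top_k=1)
        expected = sum(60 - L + 1
                       for L in range(constraints.length_min,
                                      constraints.length_max + 1))
        assert len(result.forward_candidates) == expected
        assert len(result.reverse_candidates) == expected

    def test_homopolymer_template_yields_nothing(self):
        result = design_primers("A" * 200, PrimerConstraints(), top_k=5)
        assert result.pairs == []
        assert result.attrition["windows"] > 0

    def test_feasibility_pass_cells_match_emitted_pairs(self):
        from dmakit.simulate import gen_template
        _name, seq, _truth = gen_template(seed=2)
        result = design_primers(seq, PrimerConstraints(), top_k=100)
        n_pass = int((result.feasibility == 0).sum())
        assert n_pass == len(result.pairs)  # top_k did not truncate here

    def test_emitted_primers_satisfy_all_constraints_independently(self):
        from dmakit.simulate import gen_template
        constraints = PrimerConstraints()
        _name, seq, _truth = gen_template(seed=4)
        result = design_primers(seq, constraints, top_k=10)
        assert result.pairs
        for pair in result.pairs:
            for cand in (pair.forward, pair.reverse):
                verdict, props = screen_oligo(cand.sequence, constraints)
                assert verdict == "pass"
                assert constraints.length_min <= cand.length <= constraints.length_max
            assert constraints.amplicon_min <= pair.amplicon_length \
                <= constraints.amplicon_max
            assert abs(pair.tm_difference) <= constraints.max_tm_difference
            assert pair.cross_dimer_score <= constraints.max_dimer_score

    def test_tightening_constraints_never_adds_candidates(self):
        rng = np.random.default_rng(6)
        template = "".join(rng.choice(list("ACGT"), size=150))
        loose = PrimerConstraints(gc_min=0.2, gc_max=0.8, tm_min=40,
                                  tm_max=75, amplicon_min=70, amplicon_max=140)
        tight = PrimerConstraints(gc_min=0.4, gc_max=0.6, tm_min=50,
                                  tm_max=65, amplicon_min=70, amplicon_max=140)
        res_loose = design_primers(template, loose, top_k=1000)
        res_tight = design_primers(template, tight, top_k=1000)
        loose_set = {(c.start, c.length) for c in res_loose.forward_candidates}
        tight_set = {(c.start, c.length) for c in res_tight.forward_candidates}
        assert tight_set <= loose_set

    def test_reverse_candidate_is_reverse_complement_of_template_slice(self):
        from dmakit.simulate import gen_template
        _name, seq, _truth = gen_template(seed=1)
        result = design_primers(seq, PrimerConstraints(), top_k=5)
        for cand in result.reverse_candidates:
            window = seq[cand.start:cand.start + cand.length]
            assert cand.sequence == reverse_complement(window)
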