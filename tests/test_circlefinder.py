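import numpy as np
import pytest

from vcgsim import (
    AnnealSchedule,
    CircularGenome,
    count_self_complementary,
    energy,
    excluded_paired_selfcomp,
    fragments_and_splints,
    is_repeat_free,
    make_circle_fragments,
    metropolis_search,
    naive_upper_bound,
    random_repeat_free_circle,
    refined_upper_bound,
    reverse_complement,
)
from vcgsim.core import BASES


def brute_energy(genome: CircularGenome) -> int:
    """Independent oracle: count circular windows of both strands with a
    dictionary and apply sum n(n-1)/2."""
    counts = {}
    for strand in (genome.plus, genome.minus):
        doubled = strand + strand[:genome.w - 1]
        for i in range(genome.L):
            word = doubled[i:i + genome.w]
            counts[word] = counts.get(word, 0) + 1
    return sum(c * (c - 1) // 2 for c in counts.values())


class TestCombinatorics:
    @pytest.mark.parametrize("w,expected", [(1, 0), (2, 4), (3, 0),
                                            (4, 16), (5, 0), (6, 64)])
    def test_self_complementary_word_counts(self, w, expected):
        assert count_self_complementary(w) == expected

    def test_self_complementary_matches_brute_force(self):
        import itertools
        for w in (2, 3, 4):
            brute = sum(1 for p in itertools.product(BASES, repeat=w)
                        if reverse_complement("".join(p)) == "".join(p))
            assert count_self_complementary(w) == brute

    @pytest.mark.parametrize("w,bound", [(4, 120), (5, 512), (6, 2016)])
    def test_naive_upper_bounds(self, w, bound):
        assert naive_upper_bound(w) == bound

    def test_twelve_extra_paired_self_complementary_tetramers(self):
        assert excluded_paired_selfcomp(4) == 12
        assert refined_upper_bound(4) == 114

    def test_already_self_complementary_words_not_double_counted(self):
        # CGCG is built from two self-complementary dimers but is itself
        # self-complementary, so it is not among the 12 extra exclusions
        assert reverse_complement("CGCG") == "CGCG"
        assert reverse_complement("CG") == "CG"


class TestEnergy:
    def test_repeat_free_circle_has_zero_energy(self, circle10):
        assert energy(circle10) == 0
        assert is_repeat_free(circle10)

    def test_homopolymer_energy_is_L_times_L_minus_1(self):
        for L in (6, 10, 15):
            g = CircularGenome("C" * L, 4)
            assert energy(g) == L * (L - 1)
            assert brute_energy(g) == L * (L - 1)

    def test_energy_matches_brute_force_oracle(self, rng):
        for _ in range(60):
            L = int(rng.integers(5, 30))
            w = int(rng.integers(2, 6))
            g = CircularGenome(
                "".join(BASES[i] for i in rng.integers(0, 4, L)), w)
            assert energy(g) == brute_energy(g)

    def test_zero_energy_iff_no_word_repeats(self, rng):
        seen = {True: 0, False: 0}
        for _ in range(80):
            L = int(rng.integers(6, 16))
            g = CircularGenome(
                "".join(BASES[i] for i in rng.integers(0, 4, L)), 4)
            assert (energy(g) == 0) == is_repeat_free(g)
            seen[energy(g) == 0] += 1
        assert seen[False] > 0   # both branches exercised


class TestMetropolis:
    def test_finds_zero_energy_well_below_the_bound(self, quick_schedule):
        res = metropolis_search(40, 4, quick_schedule,
                                np.random.default_rng(0))
        assert res.energy == 0
        assert is_repeat_free(res.genome)
        assert res.genome.L == 40

    def test_returns_the_trace_minimum(self):
        # an over-tight budget cannot reach zero; the reported genome must
        # still match the best energy seen in the trace
        sched = AnnealSchedule(t_initial=0.2, t_final=0.15, cooling=0.5,
                               steps_per_temp=50, endgame_steps=50, restarts=3)
        res = metropolis_search(116, 4, sched, np.random.default_rng(1))
        assert res.energy == min(e for _, e in res.trace)
        assert energy(res.genome) == res.energy

    def test_random_repeat_free_circle_is_verified(self, circle10):
        assert circle10.L == 10 and circle10.w == 4
        assert is_repeat_free(circle10)
        # tetramer-repeat-free implies 5-mer-repeat-free
        five = CircularGenome(circle10.plus, 5)
        assert is_repeat_free(five)

    def test_raises_when_no_circle_exists(self):
        sched = AnnealSchedule(t_initial=0.2, t_final=0.15, cooling=0.5,
                               steps_per_temp=30, endgame_steps=30, restarts=2)
        with pytest.raises(RuntimeError):
            # length 121 exceeds even the naive tetramer bound
            random_repeat_free_circle(121, 4, np.random.default_rng(2), sched)


class TestFragments:
    def test_fragments_are_circular_substrings(self, circle10, rng):
        frags = make_circle_fragments(circle10, [4, 5, 6, 7, 10] * 4, rng)
        plus2, minus2 = circle10.doubled("plus"), circle10.doubled("minus")
        assert all(f in plus2 or f in minus2 for f in frags)

    def test_fragment_below_minimum_length_rejected(self, circle10, rng):
        with pytest.raises(ValueError):
            make_circle_fragments(circle10, [3], rng)

    def test_splints_bridge_consecutive_fragments(self, rng):
        plus = "".join(BASES[i] for i in rng.integers(0, 4, 100))
        frags, splints = fragments_and_splints(plus, 5, 10)
        assert [len(f) for f in frags] == [20] * 5
        assert [len(s) for s in splints] == [20] * 5
        for i in range(5):
            junction = frags[i][-10:] + frags[(i + 1) % 5][:10]
            assert splints[i] == reverse_complement(junction)
        assert "".join(frags) == plus
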