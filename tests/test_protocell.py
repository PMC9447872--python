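import numpy as np
import pytest

from vcgsim import (
    CircularGenome,
    Mixture,
    Parameters,
    Population,
    apply_selection,
    count_ribozyme,
    divide_cell,
    g_fraction,
    make_cell,
    make_ribozyme_fixture,
    reverse_complement,
    run_population,
)
from vcgsim.core import BASES, InconsistentStateError
from vcgsim.protocell import Cell


@pytest.fixture(scope="module")
def fixture_seqs():
    return make_ribozyme_fixture(np.random.default_rng(42))


class TestRibozymeCounting:
    def test_exact_copy_counts_once(self, fixture_seqs):
        rib, _, _ = fixture_seqs
        mix = Mixture()
        mix.new_strand(rib)
        assert count_ribozyme(mix, rib) == 1

    def test_embedded_copy_counts(self, fixture_seqs):
        rib, _, _ = fixture_seqs
        mix = Mixture()
        mix.new_strand("ACGU" + rib + "GGCA")
        assert count_ribozyme(mix, rib) == 1

    def test_fragments_only_count_zero(self, fixture_seqs):
        rib, frags, splints = fixture_seqs
        mix = Mixture()
        for s in frags + splints:
            mix.new_strand(s)
        assert count_ribozyme(mix, rib) == 0

    def test_overlapping_occurrences_counted(self):
        mix = Mixture()
        mix.new_strand("AAAAA")
        assert count_ribozyme(mix, "AAA") == 3


class TestSelection:
    def test_no_ribozymes_leaves_base_rates(self):
        for mode in ("none", "ligase", "polymerase"):
            assert apply_selection(0, mode) == (1.0, 1.0)

    def test_polymerase_scales_addition(self):
        assert apply_selection(5, "polymerase") == (6.0, 1.0)

    def test_ligase_scales_ligation_only(self):
        assert apply_selection(3, "ligase") == (1.0, 4.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            apply_selection(1, "helicase")


class TestDivision:
    def _cell(self, n_strands=10, seq="ACGUACGUAC"):
        mix = Mixture({b: 100 for b in BASES})
        for _ in range(n_strands):
            mix.new_strand(seq)
        return Cell(mix, L_init=n_strands * len(seq) // 2)

    def test_daughters_partition_the_strands(self, rng):
        cell = self._cell(10)
        d1, d2 = divide_cell(cell, rng)
        assert len(d1.mixture.strands) + len(d2.mixture.strands) == 10
        total = sum(s.n for s in d1.mixture.strands.values()) + \
            sum(s.n for s in d2.mixture.strands.values())
        assert total == cell.total_length()
        assert d1.L_init == d2.L_init == cell.L_init

    def test_split_is_even_on_average(self, rng):
        fractions = []
        for _ in range(200):
            cell = self._cell(20)
            d1, _ = divide_cell(cell, rng)
            fractions.append(len(d1.mixture.strands) / 20)
        assert np.mean(fractions) == pytest.approx(0.5, abs=0.02)

    def test_division_below_threshold_rejected(self, rng):
        cell = self._cell(10)
        cell.L_init = 1000
        with pytest.raises(InconsistentStateError):
            divide_cell(cell, rng)

    def test_standard_fixture_thresholds(self, fixture_seqs):
        rib, frags, splints = fixture_seqs
        cell = make_cell(Parameters(), rib, frags, splints)
        assert cell.L_init == 1500      # 5*100 + 25*20 + 25*20
        assert cell.N_rib == 5


class TestGFraction:
    def test_circle_fragments_give_one(self, circle10):
        mix = Mixture()
        mix.new_strand(circle10.doubled("plus")[2:8])
        mix.new_strand(circle10.doubled("minus")[0:6])
        assert g_fraction(mix, circle10, 6) == 1.0

    def test_foreign_strand_excluded_from_numerator(self, circle10):
        mix = Mixture()
        mix.new_strand(circle10.doubled("plus")[0:6])
        foreign = "AAAAAA" if "AAAAAA" not in circle10.doubled("plus") else "CCCCCC"
        mix.new_strand(foreign)
        assert g_fraction(mix, circle10, 6) == 0.5

    def test_absent_length_is_undefined_not_zero(self, circle10):
        mix = Mixture()
        mix.new_strand(circle10.plus[:5])
        assert g_fraction(mix, circle10, 7) is None
        assert g_fraction(mix, circle10, 5) == 1.0

    def test_repeats_longer_than_the_circle_still_count(self, circle10):
        mix = Mixture()
        mix.new_strand(circle10.doubled("plus") + circle10.plus[:3])
        assert g_fraction(mix, circle10, 23) == 1.0


class TestPopulation:
    def test_population_size_constant_under_division(self, fixture_seqs):
        rib, frags, splints = fixture_seqs
        p = Parameters(T_grow=3.0)
        cells = [make_cell(p, rib, frags, splints) for _ in range(5)]
        pop = Population(cells, rib, "polymerase", p)
        traj = run_population(pop, 6, np.random.default_rng(8))
        assert len(pop.cells) == 5
        assert all(m.divisions >= 0 for m in traj)

    def test_cells_are_exchangeable_without_selection(self, fixture_seqs):
        """With mode=none no cell is systematically favoured: the identity
        of the fastest-growing cell varies across independent runs."""
        rib, frags, splints = fixture_seqs
        p = Parameters(T_grow=2.0)
        winners = set()
        for seed in range(4):
            cells = [make_cell(p, rib, frags, splints) for _ in range(4)]
            pop = Population(cells, rib, "none", p)
            run_population(pop, 2, np.random.default_rng(100 + seed))
            lengths = [c.total_length() for c in pop.cells]
            winners.add(int(np.argmax(lengths)))
        assert len(winners) > 1

    def test_ligation_only_assembly_is_monotone(self, fixture_seqs):
        # with only ligation active no process can destroy a ribozyme copy,
        # so N_rib never decreases and levels off once fragments run out
        rib, frags, splints = fixture_seqs
        p = Parameters(k_nuc=0.0, k_add=0.0, k_ann=300.0, k_lig=2.0,
                       k_melt=1.0, phi=0.0, oligomer_inflow=False)
        cell = make_cell(p, rib, frags, splints, n_rib_copies=0,
                         n_frag_copies=20)
        pop = Population([cell], rib, "none", p)
        traj = run_population(pop, 12, np.random.default_rng(5))
        counts = [m.mean_n_rib for m in traj]
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] > 0
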