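import numpy as np
import pytest

from vcgsim import (
    GrowthEngine,
    Mixture,
    Parameters,
    addition_rate,
    annealing_attempt_rate,
    ligation_candidates,
    melting_rate,
    nucleation_rate,
    run_growth_phase,
    reverse_complement,
    zip_helix,
)
from vcgsim.core import BASES, InconsistentStateError
from vcgsim.kinetics import zip_extent


class TestRateLaws:
    def test_nucleation_at_initial_concentration_is_k_nuc(self):
        p = Parameters()
        counts = {b: p.N0 for b in BASES}
        assert nucleation_rate("ACGU", counts, p) == pytest.approx(p.k_nuc)

    def test_nucleation_zero_without_required_monomer(self):
        p = Parameters()
        counts = {"A": 5000, "C": 5000, "G": 5000, "U": 0}
        # template base A needs a U monomer
        assert nucleation_rate("AAAA", counts, p) == 0.0

    def test_nucleation_quartic_in_monomer_concentration(self):
        p = Parameters()
        counts = {b: p.N0 // 2 for b in BASES}
        assert nucleation_rate("ACGU", counts, p) == pytest.approx(p.k_nuc / 16)

    def test_annealing_attempt_rate_scaling(self):
        p = Parameters()
        assert annealing_attempt_rate(p.N0, p) == pytest.approx(p.k_ann)
        assert annealing_attempt_rate(0, p) == 0.0

    def test_addition_rate_models(self):
        counts = {b: 5000 for b in BASES}
        basic = Parameters()
        assert addition_rate("U", "A", counts, basic) == pytest.approx(10.0)
        assert addition_rate("C", "A", counts, basic) == 0.0
        err = Parameters(rate_model="equal_error", eps=0.05)
        assert addition_rate("C", "A", counts, err) == pytest.approx(0.5)
        scaled = Parameters(rate_model="scaled_experimental")
        # the Watson-Crick mean of the scaled matrix is k_add again
        wc = [addition_rate(reverse_complement(j), j, counts, scaled)
              for j in BASES]
        assert np.mean(wc) == pytest.approx(scaled.k_add, rel=1e-3)

    def test_melting_rate_falls_exponentially_with_length(self):
        p = Parameters()   # dG/kT = 2
        assert melting_rate(4, p) == pytest.approx(p.k_melt)
        assert melting_rate(5, p) == pytest.approx(p.k_melt * np.exp(-2))
        assert melting_rate(14, p) == pytest.approx(p.k_melt * np.exp(-20))
        with pytest.raises(InconsistentStateError):
            melting_rate(3, p)


class TestZip:
    def test_full_complement_zips_to_full_length(self):
        mix = Mixture()
        a = mix.new_strand("ACGUACGUAC")
        b = mix.new_strand(reverse_complement(a.seq))
        # minimal seed in the middle: a[3..7) pairs b[3..7)
        sa, sb, length = zip_helix(mix, a.id, b.id, 3, 3, 4)
        assert (sa, sb, length) == (0, 0, 10)

    def test_zip_blocked_by_existing_helix(self):
        mix = Mixture()
        a = mix.new_strand("ACGUACGUAC")
        b = mix.new_strand(reverse_complement(a.seq))
        blocker = mix.new_strand(reverse_complement(a.seq[:4]))
        mix.add_helix(a.id, blocker.id, 0, 0, 4)    # occupies a[0..4)
        sa, sb, length = zip_helix(mix, a.id, b.id, 4, 2, 4)
        assert sa == 4 and length == 6              # stops at the blocker

    def test_zip_against_brute_force_oracle(self, rng):
        def oracle(seq_a, seq_b, pm_a, pm_b, sa, sb, length):
            # grow in each direction one base at a time, checking the
            # antiparallel pairing rule from scratch
            comp = dict(zip("ACGU", "UGCA"))
            while True:
                na, nb = sa + length, sb - 1
                if (na < len(seq_a) and nb >= 0 and pm_a[na] == -1
                        and pm_b[nb] == -1 and comp[seq_a[na]] == seq_b[nb]):
                    length += 1
                    sb -= 1
                    continue
                break
            while True:
                na, nb = sa - 1, sb + length
                if (na >= 0 and nb < len(seq_b) and pm_a[na] == -1
                        and pm_b[nb] == -1 and comp[seq_a[na]] == seq_b[nb]):
                    sa -= 1
                    length += 1
                    continue
                break
            return sa, sb, length

        for _ in range(200):
            n = int(rng.integers(6, 20))
            seq_a = "".join(BASES[i] for i in rng.integers(0, 4, n))
            # partner: reverse complement with random corruption
            seq_b = list(reverse_complement(seq_a))
            for pos in rng.integers(0, n, size=rng.integers(0, 4)):
                seq_b[pos] = BASES[int(rng.integers(0, 4))]
            seq_b = "".join(seq_b)
            pm_a = [-1] * n
            pm_b = [-1] * n
            for pos in rng.integers(0, n, size=rng.integers(0, 3)):
                pm_a[pos] = 99
            # pick a valid seed: a[sa..sa+4) complementary to b[sb..sb+4)
            seeds = [(sa, sb) for sa in range(n - 3) for sb in range(n - 3)
                     if reverse_complement(seq_a[sa:sa + 4]) == seq_b[sb:sb + 4]
                     and all(pm_a[p] == -1 for p in range(sa, sa + 4))
                     and all(pm_b[p] == -1 for p in range(sb, sb + 4))]
            if not seeds:
                continue
            sa, sb = seeds[int(rng.integers(0, len(seeds)))]
            got = zip_extent(seq_a, seq_b, pm_a, pm_b, sa, sb, 4)
            assert got == oracle(seq_a, seq_b, pm_a, pm_b, sa, sb, 4)


def _duplex_mixture(k_melt=1.0, dG_kT=2.0):
    """Two independent duplexes of helix lengths 4 and 5."""
    p = Parameters(k_nuc=0.0, k_ann=0.0, k_add=0.0, k_lig=0.0,
                   k_melt=k_melt, dG_kT=dG_kT, N0=100)
    mix = Mixture({b: p.N0 for b in BASES})
    a = mix.new_strand("ACGUACGU")
    b = mix.new_strand(reverse_complement(a.seq[0:4]))
    mix.add_helix(a.id, b.id, 0, 0, 4)
    c = mix.new_strand("GGAUCCAG")
    d = mix.new_strand(reverse_complement(c.seq[0:5]))
    mix.add_helix(c.id, d.id, 0, 0, 5)
    return p, mix


class TestGillespie:
    def test_waiting_time_and_selection_follow_the_gillespie_law(self):
        # two melt events with rates k and k*exp(-dG/kT); with dG/kT=ln 2
        # the rates are 1 and 1/2: mean waiting time 2/3, selection 2:1
        rng = np.random.default_rng(99)
        waits, picks = [], []
        for _ in range(3000):
            p, mix = _duplex_mixture(k_melt=1.0, dG_kT=np.log(2))
            eng = GrowthEngine(mix, p, rng)
            t0 = eng.time
            kind = eng.step(t_max=np.inf)
            assert kind == "melt"
            waits.append(eng.time - t0)
            picks.append(len(mix.helices.values()) and
                         next(iter(mix.helices.values())).length)
        assert np.mean(waits) == pytest.approx(1 / 1.5, rel=0.06)
        # surviving helix length 5 <=> the length-4 helix melted (p=2/3)
        frac_4_melted = np.mean([length == 5 for length in picks])
        assert frac_4_melted == pytest.approx(2 / 3, abs=0.03)

    def test_empty_menu_ends_phase_without_changes(self):
        p = Parameters(k_nuc=0, k_ann=0, k_add=0, k_lig=0, k_melt=0, N0=100)
        mix = Mixture({b: p.N0 for b in BASES})
        mix.new_strand("ACGUACGU")
        before = {sid: s.seq for sid, s in mix.strands.items()}
        eng = run_growth_phase(mix, p, np.random.default_rng(0))
        assert eng.time == p.T_grow
        assert {sid: s.seq for sid, s in mix.strands.items()} == before
        assert sum(eng.event_counts.values()) == 0

    def test_successful_annealing_waiting_time(self):
        # two complementary free tetramers: one matching (unordered) window
        # pair reachable both ways at rate k_ann/N0 each, so the successful
        # annealing rate is 2*k_ann/(2*N0) ... measured against the engine's
        # own menu and against simulated waiting times
        p = Parameters(k_nuc=0, k_add=0, k_lig=0, k_melt=0, k_ann=10.0, N0=100)
        rng = np.random.default_rng(7)
        waits = []
        for _ in range(2000):
            mix = Mixture({b: p.N0 for b in BASES})
            mix.new_strand("ACGG")
            mix.new_strand("CCGU")
            eng = GrowthEngine(mix, p, rng)
            rate = eng.propensities()["annealing"]
            assert rate == pytest.approx(2 * p.k_ann / p.N0)
            t0 = eng.time
            assert eng.step(t_max=np.inf) == "annealing"
            waits.append(eng.time - t0)
            assert len(mix.helices) == 1
        assert np.mean(waits) == pytest.approx(p.N0 / (2 * p.k_ann), rel=0.06)


class TestLigation:
    def _abutting(self, gap=0, mismatch_tail=False):
        mix = Mixture()
        tmpl = mix.new_strand("AGCUUGACCA")
        left = reverse_complement(tmpl.seq[5 - gap:10])      # pairs 3' half
        right = reverse_complement(tmpl.seq[0:5])            # pairs 5' half
        a = mix.new_strand(left)
        c = mix.new_strand(right if not mismatch_tail else right + "A")
        mix.add_helix(a.id, tmpl.id, 0, 5 - gap, 5)
        mix.add_helix(c.id, tmpl.id, 0, 0, 5)
        return mix, tmpl, a, c

    def test_abutting_ends_form_one_junction(self):
        mix, tmpl, a, c = self._abutting()
        cands = ligation_candidates(mix)
        assert len(cands) == 1
        primer, template, acceptor, _, _ = cands[0]
        assert (primer, template, acceptor) == (a.id, tmpl.id, c.id)

    def test_gap_on_template_is_not_a_candidate(self):
        mix, *_ = self._abutting(gap=1)
        assert ligation_candidates(mix) == []

    def test_firing_merges_strands_and_helices(self):
        p = Parameters(k_nuc=0, k_ann=0, k_add=0, k_melt=0, k_lig=1.0, N0=100)
        mix, tmpl, a, c = self._abutting()
        mix.monomers = {b: p.N0 for b in BASES}
        eng = GrowthEngine(mix, p, np.random.default_rng(1))
        assert eng.step(t_max=np.inf) == "ligation"
        assert len(mix.strands) == 2
        assert len(mix.helices) == 1
        product = mix.strands[a.id]
        assert product.seq == reverse_complement(tmpl.seq)
        assert next(iter(mix.helices.values())).length == 10
        mix.check_invariants(4)
        eng.audit()

    def test_mismatch_tail_blocks_ligation(self):
        # the 3' strand ends in an unpaired tail base: no junction
        mix = Mixture()
        tmpl = mix.new_strand("AGCUUGACCA")
        a = mix.new_strand(reverse_complement(tmpl.seq[5:10]) + "G")
        c = mix.new_strand(reverse_complement(tmpl.seq[0:5]))
        mix.add_helix(a.id, tmpl.id, 0, 5, 5)
        mix.add_helix(c.id, tmpl.id, 0, 0, 5)
        assert ligation_candidates(mix) == []


class TestGrowthPhase:
    def test_no_annealing_caps_growth_at_template_length(self, rng):
        p = Parameters(N0=200, k_ann=0.0, k_nuc=1.0, k_add=50.0, k_lig=1.0,
                       k_melt=1.0, T_grow=4.0)
        mix = Mixture({b: p.N0 for b in BASES})
        max_template = 0
        for _ in range(15):
            n = int(rng.integers(4, 11))
            max_template = max(max_template, n)
            mix.new_strand("".join(BASES[i] for i in rng.integers(0, 4, n)))
        for _ in range(5):
            run_growth_phase(mix, p, rng)
            assert max(s.n for s in mix.strands.values()) <= max_template
            mix.melt_all()

    def test_basic_model_never_pairs_mismatches(self, small_params, rng):
        mix = Mixture({b: small_params.N0 for b in BASES})
        for _ in range(10):
            n = int(rng.integers(4, 11))
            mix.new_strand("".join(BASES[i] for i in rng.integers(0, 4, n)))
        eng = run_growth_phase(mix, small_params, rng)
        assert eng.event_counts["mismatch"] == 0
        mix.check_invariants(small_params.l0)   # includes complementarity

    def test_monomer_conservation_and_audit(self, small_params, rng):
        p = Parameters(**{**small_params.__dict__,
                          "rate_model": "equal_error", "eps": 0.1,
                          "r_ex": small_params.r_ex})
        mix = Mixture({b: p.N0 for b in BASES})
        for _ in range(10):
            n = int(rng.integers(4, 11))
            mix.new_strand("".join(BASES[i] for i in rng.integers(0, 4, n)))
        free0 = dict(mix.monomers)
        bound0 = mix.total_bases()
        eng = run_growth_phase(mix, p, rng, audit_every=25)
        bound1 = mix.total_bases()
        for b in BASES:
            assert free0[b] + bound0[b] == mix.monomers[b] + bound1[b]
        assert sum(eng.event_counts.values()) > 20
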