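"""Populations of protocells with growth, division and ribozyme selection.

Each cell holds its own strand mixture; only strands in the same cell
interact.  Membranes are permeable to monomers (monomer counts stay fixed
at N0 per type inside every cell) but not to strands, so there is no strand
inflow or outflow: dilution comes from growth and division.  At the end of
each growth phase a cell whose total strand length has reached twice its
initial value divides, assigning every strand independently to one of two
daughters; a random other cell is eliminated to keep the population size
constant, which is what makes faster-growing cells selectively favoured.

Selection couples cell growth to a functional ribozyme: with polymerase
function the cell's monomer addition rate is k_add * (1 + N_rib), with
ligase function its ligation rate is k_lig * (1 + N_rib), where N_rib
counts complete copies of the ribozyme sequence among the cell's strands
(copies embedded in longer strands included).  The reference ribozyme
fixture is a synthetic random 100-mer standing in for a catalytic core,
split into five 20-mer fragments plus five 20-mer splints, each splint
bridging the last 10 bases of one fragment and the first 10 of the next,
so that the fragment/splint set forms a closed virtual circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .circlefinder import CircularGenome, fragments_and_splints
from .core import BASES, InconsistentStateError, Mixture, Parameters
from .cycling import melt_all
from .kinetics import run_growth_phase

MODES = ("none", "ligase", "polymerase")


def count_ribozyme(mixture: Mixture, ribseq: str) -> int:
    """Occurrences of the complete ribozyme sequence over all strands,
    counting overlapping matches and copies inside longer strands."""
    if not ribseq:
        raise ValueError("empty ribozyme sequence")
    total = 0
    for strand in mixture.strands.values():
        start = strand.seq.find(ribseq)
        while start != -1:
            total += 1
            start = strand.seq.find(ribseq, start + 1)
    return total


def apply_selection(n_rib: int, mode: str) -> Tuple[float, float]:
    """(k_add multiplier, k_lig multiplier) for a cell with n_rib complete
    ribozymes: polymerase scales addition, ligase scales ligation."""
    if mode not in MODES:
        raise ValueError(f"unknown selection mode {mode!r}")
    if mode == "polymerase":
        return 1.0 + n_rib, 1.0
    if mode == "ligase":
        return 1.0, 1.0 + n_rib
    return 1.0, 1.0


@dataclass(eq=False)
class Cell:
    """One protocell: a strand mixture plus division bookkeeping."""

    mixture: Mixture
    L_init: int
    N_rib: int = 0

    def total_length(self) -> int:
        return sum(s.n for s in self.mixture.strands.values())


def divide_cell(cell: Cell, rng: np.random.Generator) -> Tuple[Cell, Cell]:
    """Split a (melted) cell: each strand goes to a uniformly random
    daughter; both daughters inherit L_init and the monomer counts."""
    if cell.total_length() < 2 * cell.L_init:
        raise InconsistentStateError("division below the 2*L_init threshold")
    if cell.mixture.helices:
        raise InconsistentStateError("cell must be melted before division")
    d1 = Mixture(dict(cell.mixture.monomers))
    d2 = Mixture(dict(cell.mixture.monomers))
    for strand in cell.mixture.strands.values():
        target = d1 if rng.random() < 0.5 else d2
        target.new_strand(strand.seq)
    return Cell(d1, cell.L_init), Cell(d2, cell.L_init)


def make_ribozyme_fixture(rng: np.random.Generator, length: int = 100,
                          n_frag: int = 5, overlap: int = 10,
                          ) -> Tuple[str, List[str], List[str]]:
    """Synthetic stand-in for a functional ribozyme core: a random
    ``length``-mer plus its fragments and bridging splints.  Returns
    (ribozyme, fragments, splints)."""
    plus = "".join(BASES[i] for i in rng.integers(0, 4, length))
    frags, splints = fragments_and_splints(plus, n_frag, overlap)
    return plus, frags, splints


def make_cell(params: Parameters, ribseq: str, fragments: List[str],
              splints: List[str], n_rib_copies: int = 5,
              n_frag_copies: int = 5) -> Cell:
    """A cell initialized with complete ribozymes plus fragment/splint
    pools (the standard fixture gives total length 1500)."""
    mixture = Mixture({b: params.N0 for b in BASES})
    for _ in range(n_rib_copies):
        mixture.new_strand(ribseq)
    for frag in fragments + splints:
        for _ in range(n_frag_copies):
            mixture.new_strand(frag)
    cell = Cell(mixture, L_init=sum(s.n for s in mixture.strands.values()))
    cell.N_rib = count_ribozyme(mixture, ribseq)
    return cell


@dataclass
class PopulationMetrics:
    cycle: int
    mean_n_rib: float
    max_n_rib: int
    divisions: int
    mean_total_length: float


@dataclass
class Population:
    """Fixed-size population of protocells under ribozyme selection."""

    cells: List[Cell]
    ribseq: str
    mode: str = "none"
    params: Parameters = field(default_factory=Parameters)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown selection mode {self.mode!r}")

    def run_cycle(self, rng: np.random.Generator) -> PopulationMetrics:
        divisions = 0
        for cell in self.cells:
            k_add_mult, k_lig_mult = apply_selection(cell.N_rib, self.mode)
            run_growth_phase(cell.mixture, self.params, rng,
                             k_add_mult=k_add_mult, k_lig_mult=k_lig_mult,
                             constant_monomers=True)
            cell.N_rib = count_ribozyme(cell.mixture, self.ribseq)
        lengths = [cell.total_length() for cell in self.cells]
        for cell in self.cells:
            melt_all(cell.mixture)
        # division checks at end of growth phase
        for cell in list(self.cells):
            if cell not in self.cells:   # eliminated by an earlier division
                continue
            if cell.total_length() >= 2 * cell.L_init:
                d1, d2 = divide_cell(cell, rng)
                d1.N_rib = count_ribozyme(d1.mixture, self.ribseq)
                d2.N_rib = count_ribozyme(d2.mixture, self.ribseq)
                pos = self.cells.index(cell)
                self.cells[pos] = d1
                self.cells.append(d2)
                # eliminate a random cell other than the two daughters
                candidates = [c for c in self.cells if c is not d1 and c is not d2]
                victim = candidates[int(rng.integers(0, len(candidates)))]
                self.cells.remove(victim)
                divisions += 1
        n_ribs = [cell.N_rib for cell in self.cells]
        return PopulationMetrics(0, float(np.mean(n_ribs)), max(n_ribs),
                                 divisions, float(np.mean(lengths)))


def run_population(population: Population, n_cycles: int,
                   rng: np.random.Generator) -> List[PopulationMetrics]:
    """Simulate the population for n_cycles; per-cycle population metrics
    (mean/max ribozyme count, divisions) recorded at end of growth."""
    out = []
    for cycle in range(1, n_cycles + 1):
        metrics = population.run_cycle(rng)
        metrics.cycle = cycle
        out.append(metrics)
    return out


def g_fraction(mixture: Mixture, genome: CircularGenome, n: int) -> Optional[float]:
    """Fraction of length-n strands whose whole sequence is a contiguous
    substring of the circular plus or minus strand of ``genome``; None if
    no strand has length n (undefined, distinct from 0)."""
    reps = n // genome.L + 2   # periodic repeats cover strands longer than L
    plus_rep = genome.plus * reps
    minus_rep = genome.minus * reps
    total = 0
    hits = 0
    for strand in mixture.strands.values():
        if strand.n != n:
            continue
        total += 1
        if strand.seq in plus_rep or strand.seq in minus_rep:
            hits += 1
    if total == 0:
        return None
    return hits / total
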