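"""Temperature cycling: growth phases alternating with melt, outflow and
inflow, plus per-cycle observables.

One cycle is: growth phase of duration T_grow (Gillespie kinetics at
moderate temperature) -> metrics recorded at the end of the growth phase,
before melting and outflow -> high-temperature melt of every helix ->
outflow of strands and monomers with fractional rate phi -> inflow of fresh
monomers (phi * N0 per type) and, unless disabled, N_inflow = phi * N_init
random oligomers.

The random-oligomer source draws lengths from the truncated geometric
distribution P(n) proportional to lambda**(n - l_min) on [l_min, l_max]
(mean 4.94 for the standard lambda = 1/2 on 4..10) with i.i.d. uniform
bases, emulating untemplated random polymerization outside the reaction
volume.  A source may instead draw fragments from a fixed virtual circular
genome, which is how runs probing virtual-circle maintenance are set up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional

import numpy as np
import pandas as pd

from .circlefinder import CircularGenome
from .core import BASES, Mixture, Parameters
from .kinetics import GrowthEngine, run_growth_phase


@dataclass
class OligomerSource:
    """Random-oligomer generator for the initial pool and per-cycle inflow.

    Lengths follow P(n) ~ lam**(n - l_min) truncated to [l_min, l_max].
    With ``genome`` set, sequences are uniform random circular substrings
    of the genome's plus or minus strand instead of i.i.d. random bases.
    """

    lam: float = 0.5
    l_min: int = 4
    l_max: int = 10
    genome: Optional[CircularGenome] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("lambda must be in (0, 1]")
        if self.l_min > self.l_max:
            raise ValueError("empty length range")
        weights = np.array([self.lam ** (n - self.l_min)
                            for n in range(self.l_min, self.l_max + 1)])
        self._probs = weights / weights.sum()

    @property
    def mean_length(self) -> float:
        """Exact mean of the truncated geometric length distribution."""
        lengths = np.arange(self.l_min, self.l_max + 1)
        return float((lengths * self._probs).sum())

    def sample_length(self, rng: np.random.Generator) -> int:
        return self.l_min + int(rng.choice(len(self._probs), p=self._probs))

    def sample_oligomer(self, rng: np.random.Generator) -> str:
        n = self.sample_length(rng)
        if self.genome is None:
            return "".join(BASES[i] for i in rng.integers(0, 4, n))
        strand = self.genome.doubled("plus" if rng.random() < 0.5 else "minus")
        start = int(rng.integers(0, self.genome.L))
        return strand[start:start + n]

    @classmethod
    def from_params(cls, params: Parameters,
                    genome: Optional[CircularGenome] = None) -> "OligomerSource":
        return cls(params.lam, params.oligo_len_min, params.oligo_len_max, genome)


def sample_oligomer(source: OligomerSource, rng: np.random.Generator) -> str:
    return source.sample_oligomer(rng)


@dataclass
class CycleMetrics:
    """Observables of one cycle, recorded at the end of the growth phase
    (before melting and outflow)."""

    cycle: int
    n_seq: int
    mean_length: float
    max_length: int
    monomers: Dict[str, int]
    length_hist: Dict[int, int]
    # dn = n - n_start keyed by n_start; (sum, count) pairs
    dn_by_nstart: Dict[int, List[float]]
    helices_by_length: Dict[int, float]   # h(n): mean helices per strand
    paired_by_length: Dict[int, float]    # m(n): mean paired bases per strand
    diversity: Optional[int] = None       # distinct k-mer count, on demand
    event_counts: Dict[str, int] = field(default_factory=dict)

    def summary_row(self) -> Dict[str, object]:
        row: Dict[str, object] = {
            "cycle": self.cycle, "n_seq": self.n_seq,
            "mean_length": self.mean_length, "max_length": self.max_length,
        }
        for b in BASES:
            row[f"N_{b}"] = self.monomers[b]
        if self.diversity is not None:
            row["diversity"] = self.diversity
        for k, v in self.event_counts.items():
            row[f"events_{k}"] = v
        return row


def compute_metrics(mixture: Mixture, cycle: int = 0,
                    engine: Optional[GrowthEngine] = None,
                    word_k: Optional[int] = None) -> CycleMetrics:
    """End-of-growth-phase observables of a mixture.

    h(n) and m(n) are the mean number of distinct helices and the mean
    number of paired nucleotides for strands of end-of-phase length n;
    dn = n - n_start is keyed by the length at the start of the phase.
    """
    lengths = [s.n for s in mixture.strands.values()]
    n_seq = len(lengths)
    hist: Dict[int, int] = {}
    for n in lengths:
        hist[n] = hist.get(n, 0) + 1
    helix_count: Dict[int, int] = {}
    paired_count: Dict[int, int] = {}
    for helix in mixture.helices.values():
        for sid in (helix.strand_a, helix.strand_b):
            helix_count[sid] = helix_count.get(sid, 0) + 1
            paired_count[sid] = paired_count.get(sid, 0) + helix.length
    h_sum: Dict[int, List[float]] = {}
    m_sum: Dict[int, List[float]] = {}
    dn: Dict[int, List[float]] = {}
    for sid, strand in mixture.strands.items():
        n = strand.n
        h_sum.setdefault(n, [0.0, 0])
        h_sum[n][0] += helix_count.get(sid, 0)
        h_sum[n][1] += 1
        m_sum.setdefault(n, [0.0, 0])
        m_sum[n][0] += paired_count.get(sid, 0)
        m_sum[n][1] += 1
        dn.setdefault(strand.n_start, [0.0, 0])
        dn[strand.n_start][0] += n - strand.n_start
        dn[strand.n_start][1] += 1
    diversity = None
    if word_k is not None:
        words = set()
        for strand in mixture.strands.values():
            seq = strand.seq
            for i in range(len(seq) - word_k + 1):
                words.add(seq[i:i + word_k])
        diversity = len(words)
    return CycleMetrics(
        cycle=cycle,
        n_seq=n_seq,
        mean_length=float(np.mean(lengths)) if lengths else 0.0,
        max_length=max(lengths) if lengths else 0,
        monomers=dict(mixture.monomers),
        length_hist=hist,
        dn_by_nstart={k: list(v) for k, v in dn.items()},
        helices_by_length={n: v[0] / v[1] for n, v in h_sum.items()},
        paired_by_length={n: v[0] / v[1] for n, v in m_sum.items()},
        diversity=diversity,
        event_counts=dict(engine.event_counts) if engine else {},
    )


def melt_all(mixture: Mixture) -> Mixture:
    """High-temperature phase: every helix melts regardless of length,
    every strand becomes its own cluster, stall flags clear."""
    mixture.melt_all()
    return mixture


def apply_outflow_inflow(mixture: Mixture, params: Parameters,
                         source: OligomerSource,
                         rng: np.random.Generator) -> Mixture:
    """End-of-cycle exchange: each strand is lost with probability phi;
    monomer counts relax as N <- round(N * (1 - phi)) + phi * N0; then
    N_inflow = phi * N_init fresh oligomers enter (unless oligomer inflow
    is disabled).  Must be called on a fully melted mixture."""
    if mixture.helices:
        raise RuntimeError("outflow requires a melted mixture")
    phi = params.phi
    if phi > 0.0:
        doomed = [sid for sid in mixture.strands if rng.random() < phi]
        for sid in doomed:
            mixture.remove_strand(sid)
        inflow_monomers = int(round(phi * params.N0))
        for b in BASES:
            kept = int(np.round(mixture.monomers[b] * (1.0 - phi)))
            mixture.monomers[b] = kept + inflow_monomers
    if params.oligomer_inflow:
        for _ in range(params.N_inflow):
            mixture.new_strand(source.sample_oligomer(rng))
    return mixture


def initialize_mixture(params: Parameters, source: OligomerSource,
                       rng: np.random.Generator) -> Mixture:
    """N0 monomers of each type plus N_init random oligomers."""
    mixture = Mixture({b: params.N0 for b in BASES})
    for _ in range(params.N_init):
        mixture.new_strand(source.sample_oligomer(rng))
    return mixture


def run_simulation(params: Parameters, source: OligomerSource, n_cycles: int,
                   rng: np.random.Generator, word_k: Optional[int] = None,
                   mixture: Optional[Mixture] = None,
                   callback: Optional[Callable[[int, Mixture], None]] = None,
                   ) -> List[CycleMetrics]:
    """Full cycling run: initialize, then repeat growth -> metrics ->
    melt -> outflow/inflow for ``n_cycles`` cycles.

    ``word_k`` switches on per-cycle word-diversity tracking; ``callback``
    (cycle index, mixture) runs after each growth phase, before melting
    (the state metrics are recorded from), e.g. for snapshots.
    """
    if mixture is None:
        mixture = initialize_mixture(params, source, rng)
    metrics: List[CycleMetrics] = []
    for cycle in range(1, n_cycles + 1):
        engine = run_growth_phase(mixture, params, rng)
        metrics.append(compute_metrics(mixture, cycle, engine, word_k))
        if callback is not None:
            callback(cycle, mixture)
        melt_all(mixture)
        apply_outflow_inflow(mixture, params, source, rng)
    return metrics


def metrics_frame(metrics: List[CycleMetrics]) -> pd.DataFrame:
    """One row per cycle of the scalar observables (CSV-ready)."""
    return pd.DataFrame([m.summary_row() for m in metrics])


def steady_state_mean(metrics: List[CycleMetrics], column: str = "mean_length",
                      tail_fraction: float = 0.5) -> float:
    """Average of a scalar observable over the final part of the run
    (default: the last half of the cycles)."""
    frame = metrics_frame(metrics)
    tail = frame.iloc[int(len(frame) * (1.0 - tail_fraction)):]
    return float(tail[column].mean())
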