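"""Sequence, duplex and cluster data model shared by the whole simulator.

The simulated reaction volume contains explicit RNA strands (5'->3' base
strings over A, C, G, U), double-helical regions (helices) pairing intervals
of two strands antiparallel, and clusters of strands connected by helices.
Clusters are constrained to branching trees: a cluster with s strands always
has exactly s - 1 helices, which forbids loops and knots that could not form
in three dimensions.

Conventions: all coordinates are 0-based, intervals half-open, positions
indexed 5'->3' on each strand.  A helix of length l between strand A
(interval starting at ``start_a``) and strand B (``start_b``) pairs position
``start_a + k`` with ``start_b + l - 1 - k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

BASES = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_COMP_TABLE = str.maketrans("ACGU", "UGCA")


class SequenceError(ValueError):
    """Raised for inputs that are not valid RNA sequences."""


class InconsistentStateError(RuntimeError):
    """Raised when an operation would violate a structural invariant."""


def complement_base(base: str) -> str:
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise SequenceError(f"not an RNA base: {base!r}") from None


def reverse_complement(seq: str) -> str:
    """Antiparallel Watson-Crick complement of ``seq``.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    if not seq:
        raise SequenceError("empty sequence")
    bad = set(seq) - set(BASES)
    if bad:
        raise SequenceError(f"non-RNA characters in sequence: {sorted(bad)}")
    return seq.translate(_COMP_TABLE)[::-1]


def is_complementary(a: str, b: str) -> bool:
    """True if single bases a, b form a Watson-Crick pair."""
    return _COMPLEMENT[a] == b


@dataclass
class Strand:
    """One explicit RNA strand with per-cycle growth bookkeeping.

    ``n_start`` is the strand length at the start of the current growth
    phase (used for the per-cycle length increase dn = n - n_start);
    ``stalled_3p`` is set when a mismatched addition terminates the 3' end
    for the remainder of the growth phase and is cleared at every cycle
    boundary.
    """

    id: int
    seq: str
    n_start: int = -1
    stalled_3p: bool = False

    def __post_init__(self) -> None:
        if self.n_start < 0:
            self.n_start = len(self.seq)

    @property
    def n(self) -> int:
        return len(self.seq)


@dataclass
class Helix:
    """A contiguous antiparallel duplex between intervals of two strands."""

    id: int
    strand_a: int
    strand_b: int
    start_a: int
    start_b: int
    length: int

    def interval_on(self, strand_id: int) -> Tuple[int, int]:
        """Half-open paired interval [start, end) on the given strand."""
        if strand_id == self.strand_a:
            return (self.start_a, self.start_a + self.length)
        if strand_id == self.strand_b:
            return (self.start_b, self.start_b + self.length)
        raise InconsistentStateError(f"strand {strand_id} not in helix {self.id}")

    def partner_of(self, strand_id: int) -> int:
        if strand_id == self.strand_a:
            return self.strand_b
        if strand_id == self.strand_b:
            return self.strand_a
        raise InconsistentStateError(f"strand {strand_id} not in helix {self.id}")


@dataclass
class Cluster:
    """A tree of strands connected by helices (s strands, s - 1 helices)."""

    id: int
    strand_ids: Set[int] = field(default_factory=set)
    helix_ids: Set[int] = field(default_factory=set)


@dataclass
class Parameters:
    """Rate constants and system sizes of one simulation run.

    All rate constants are in h^-1.  Monomer-dependent rates are scaled so
    that each rate constant is the rate at the initial monomer count ``N0``
    per base type.  ``rate_model`` selects between error-free polymerization
    (``basic``), a single relative mismatch rate ``eps`` (``equal_error``),
    and addition rates proportional to experimentally measured values
    (``scaled_experimental``, see :data:`R_EX_TABLE`).
    """

    N0: int = 5000
    N_init: int = 500
    phi: float = 0.05
    l0: int = 4
    lam: float = 0.5
    k_nuc: float = 0.1
    k_ann: float = 10.0
    k_add: float = 10.0
    k_lig: float = 1.0
    k_melt: float = 1.0
    dG_kT: float = 2.0
    T_grow: float = 6.0
    rate_model: str = "basic"
    eps: float = 0.0
    r_ex: Tuple[Tuple[float, ...], ...] = None  # type: ignore[assignment]
    oligo_len_min: int = 4
    oligo_len_max: int = 10
    oligomer_inflow: bool = True
    length_cap: int | None = None
    # Optional relative addition rate after a mismatch (0 = absolute stall).
    stalled_rate_factor: float = 0.0

    def __post_init__(self) -> None:
        if self.r_ex is None:
            self.r_ex = R_EX_TABLE
        self.validate()

    def validate(self) -> None:
        for name in ("k_nuc", "k_ann", "k_add", "k_lig", "k_melt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must be in [0, 1]")
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("lambda must be in (0, 1]")
        if self.l0 < 2:
            raise ValueError("l0 must be >= 2")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")
        if self.rate_model not in ("basic", "equal_error", "scaled_experimental"):
            raise ValueError(f"unknown rate model: {self.rate_model!r}")
        if self.oligo_len_min < self.l0:
            raise ValueError("oligomer minimum length must be >= l0")

    @property
    def N_inflow(self) -> int:
        """Number of random oligomers flowing in per cycle (phi * N_init)."""
        return int(round(self.phi * self.N_init))

    @property
    def r_WC(self) -> float:
        """Mean of the four Watson-Crick entries of the experimental table."""
        total = 0.0
        for j, row in enumerate(self.r_ex):
            total += row[BASES.index(complement_base(BASES[j]))]
        return total / 4.0


# Experimental single-nucleotide addition rates r_ex(i|j) in h^-1: rows are
# the template base j, columns the added base i, in A, C, G, U order.  Rates
# of U addition are normalized to the same 10 mM concentration as the other
# bases.  The Watson-Crick mean of this table is r_WC = 4.348 h^-1.
R_EX_TABLE: Tuple[Tuple[float, ...], ...] = (
    (0.043, 0.079, 0.145, 0.204),
    (0.012, 0.013, 1.940, 0.004),
    (0.037, 14.515, 0.205, 0.174),
    (0.735, 0.014, 0.365, 0.024),
)


class Mixture:
    """All strands, helices, clusters and free monomers of one volume."""

    def __init__(self, monomer_counts: Dict[str, int] | None = None) -> None:
        self.strands: Dict[int, Strand] = {}
        self.helices: Dict[int, Helix] = {}
        self.clusters: Dict[int, Cluster] = {}
        self.cluster_of: Dict[int, int] = {}
        self.monomers: Dict[str, int] = dict(monomer_counts or {b: 0 for b in BASES})
        self.time: float = 0.0
        self._next_strand_id = 0
        self._next_helix_id = 0
        self._next_cluster_id = 0

    # -- construction -----------------------------------------------------

    def new_strand(self, seq: str, n_start: int | None = None) -> Strand:
        sid = self._next_strand_id
        self._next_strand_id += 1
        strand = Strand(sid, seq, len(seq) if n_start is None else n_start)
        self.strands[sid] = strand
        cid = self._next_cluster_id
        self._next_cluster_id += 1
        self.clusters[cid] = Cluster(cid, {sid}, set())
        self.cluster_of[sid] = cid
        return strand

    def remove_strand(self, sid: int) -> None:
        cid = self.cluster_of.pop(sid)
        cluster = self.clusters[cid]
        if cluster.helix_ids:
            raise InconsistentStateError("cannot remove a strand bound in helices")
        cluster.strand_ids.discard(sid)
        if not cluster.strand_ids:
            del self.clusters[cid]
        del self.strands[sid]

    def add_helix(self, strand_a: int, strand_b: int, start_a: int,
                  start_b: int, length: int) -> Helix:
        """Create a helix and merge the two clusters (must differ)."""
        ca, cb = self.cluster_of[strand_a], self.cluster_of[strand_b]
        if ca == cb:
            raise InconsistentStateError(
                "new helix would connect strands already in the same cluster")
        hid = self._next_helix_id
        self._next_helix_id += 1
        helix = Helix(hid, strand_a, strand_b, start_a, start_b, length)
        self.helices[hid] = helix
        # merge smaller cluster into larger
        if len(self.clusters[ca].strand_ids) < len(self.clusters[cb].strand_ids):
            ca, cb = cb, ca
        keep, gone = self.clusters[ca], self.clusters[cb]
        keep.strand_ids |= gone.strand_ids
        keep.helix_ids |= gone.helix_ids
        for sid in gone.strand_ids:
            self.cluster_of[sid] = ca
        keep.helix_ids.add(hid)
        del self.clusters[cb]
        return helix

    # -- queries ----------------------------------------------------------

    def helices_on(self, sid: int) -> List[Helix]:
        cid = self.cluster_of[sid]
        return [self.helices[h] for h in self.clusters[cid].helix_ids
                if sid in (self.helices[h].strand_a, self.helices[h].strand_b)]

    def paired_intervals(self, sid: int) -> List[Tuple[int, int]]:
        return sorted(h.interval_on(sid) for h in self.helices_on(sid))

    def total_bases(self) -> Dict[str, int]:
        counts = {b: 0 for b in BASES}
        for strand in self.strands.values():
            for b in strand.seq:
                counts[b] += 1
        return counts

    # -- structural edits -------------------------------------------------

    def remove_helix(self, hid: int) -> Tuple[Cluster, Cluster]:
        """Delete a helix and split its cluster into the two tree parts."""
        helix = self.helices.pop(hid, None)
        if helix is None:
            raise InconsistentStateError(f"no helix {hid}")
        cid = self.cluster_of[helix.strand_a]
        cluster = self.clusters[cid]
        cluster.helix_ids.discard(hid)
        side_a, helices_a = self._component(helix.strand_a, cluster)
        side_b = cluster.strand_ids - side_a
        helices_b = cluster.helix_ids - helices_a
        # reuse cid for side_a; new cluster for side_b
        cluster.strand_ids = side_a
        cluster.helix_ids = helices_a
        nid = self._next_cluster_id
        self._next_cluster_id += 1
        other = Cluster(nid, side_b, helices_b)
        self.clusters[nid] = other
        for sid in side_b:
            self.cluster_of[sid] = nid
        return cluster, other

    def _component(self, start_sid: int, cluster: Cluster) -> Tuple[Set[int], Set[int]]:
        adjacency: Dict[int, List[Helix]] = {}
        for h in cluster.helix_ids:
            helix = self.helices[h]
            adjacency.setdefault(helix.strand_a, []).append(helix)
            adjacency.setdefault(helix.strand_b, []).append(helix)
        seen = {start_sid}
        used_helices: Set[int] = set()
        stack = [start_sid]
        while stack:
            sid = stack.pop()
            for helix in adjacency.get(sid, ()):
                used_helices.add(helix.id)
                other = helix.partner_of(sid)
                if other not in seen:
                    seen.add(other)
                    stack.append(other)
        return seen, used_helices

    def melt_all(self) -> None:
        """High-temperature step: separate every duplex, one strand per cluster."""
        self.helices.clear()
        self.clusters.clear()
        self.cluster_of.clear()
        for sid, strand in self.strands.items():
            cid = self._next_cluster_id
            self._next_cluster_id += 1
            self.clusters[cid] = Cluster(cid, {sid}, set())
            self.cluster_of[sid] = cid
            strand.stalled_3p = False

    # -- integrity --------------------------------------------------------

    def check_invariants(self, l0: int = 2) -> None:
        """Audit all structural invariants; raise on any violation."""
        for cid, cluster in self.clusters.items():
            if len(cluster.helix_ids) != len(cluster.strand_ids) - 1:
                raise InconsistentStateError(
                    f"cluster {cid}: {len(cluster.strand_ids)} strands but "
                    f"{len(cluster.helix_ids)} helices (tree rule violated)")
            for sid in cluster.strand_ids:
                if self.cluster_of[sid] != cid:
                    raise InconsistentStateError("cluster membership desynced")
            seen, _ = self._component(next(iter(cluster.strand_ids)), cluster)
            if seen != cluster.strand_ids:
                raise InconsistentStateError(f"cluster {cid} is not connected")
        covered: Dict[int, List[Tuple[int, int]]] = {}
        for helix in self.helices.values():
            if helix.length < l0:
                raise InconsistentStateError(f"helix {helix.id} shorter than l0")
            a = self.strands[helix.strand_a]
            b = self.strands[helix.strand_b]
            seg_a = a.seq[helix.start_a:helix.start_a + helix.length]
            seg_b = b.seq[helix.start_b:helix.start_b + helix.length]
            if len(seg_a) != helix.length or len(seg_b) != helix.length:
                raise InconsistentStateError(f"helix {helix.id} out of range")
            if reverse_complement(seg_a) != seg_b:
                raise InconsistentStateError(f"helix {helix.id} is not complementary")
            covered.setdefault(helix.strand_a, []).append(helix.interval_on(helix.strand_a))
            covered.setdefault(helix.strand_b, []).append(helix.interval_on(helix.strand_b))
        for sid, intervals in covered.items():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                if s2 < e1:
                    raise InconsistentStateError(
                        f"overlapping helix intervals on strand {sid}")


def free_windows(strand: Strand, helices: Iterable[Helix], l0: int) -> List[int]:
    """Start positions of every run of ``l0`` contiguous unpaired bases.

    Overlapping windows are counted individually; with no helices a strand
    of length n has n - l0 + 1 windows.
    """
    n = strand.n
    if n < l0:
        return []
    paired = [False] * n
    for helix in helices:
        s, e = helix.interval_on(strand.id)
        for i in range(s, e):
            paired[i] = True
    return free_windows_from_mask(paired, l0)


def free_windows_from_mask(paired: Sequence[bool], l0: int) -> List[int]:
    n = len(paired)
    out: List[int] = []
    run = 0
    for i in range(n):
        run = 0 if paired[i] else run + 1
        if run >= l0:
            out.append(i - l0 + 1)
    return out


def split_cluster_on_melt(mixture: Mixture, helix_id: int) -> Tuple[Cluster, Cluster]:
    """Melt one helix: delete it and divide its cluster into two trees."""
    return mixture.remove_helix(helix_id)
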