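"""Virtual circular genomes without repeated words.

A virtual circular genome is a circular plus strand of length L together
with its reverse-complement minus circle.  Each circular strand of length L
contributes exactly L overlapping windows of word length w (windows wrap
around the origin).  The energy

    E = sum_i n_i (n_i - 1) / 2

counts the number of repeated-word pairs, where n_i is the number of
occurrences of word i over both circular strands.  E = 0 means the circle is
repeat-free: no word of length w occurs more than once anywhere in the
plus/minus pair.  Repeat-free circles are the only virtual genomes that can
maintain their sequence information under templated copying with minimum
helix length l0 = w, which makes the maximum repeat-free length a quantity
of direct interest.

This module provides the combinatorial word counts and upper bounds, an
exact energy evaluator, and a Metropolis simulated-annealing search that
minimizes E over circular sequences using point mutations and cut-and-paste
rearrangements (every change to the plus strand is mirrored in the minus
strand through the derived-complement invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import BASES, SequenceError, reverse_complement

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def _encode(seq: str) -> List[int]:
    try:
        return [_BASE_INDEX[b] for b in seq]
    except KeyError as exc:
        raise SequenceError(f"non-RNA character {exc.args[0]!r}") from None


def _decode(codes: Sequence[int]) -> str:
    return "".join(BASES[c] for c in codes)


def _rc_code_table(w: int) -> np.ndarray:
    """rc[word] = code of the reverse complement, for all 4**w word codes."""
    codes = np.arange(4 ** w, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(w):
        rc = rc * 4 + (3 - (tmp % 4))
        tmp //= 4
    return rc


def _window_codes(codes: Sequence[int], w: int) -> np.ndarray:
    """Codes of all L circular windows of the plus strand."""
    arr = np.asarray(list(codes) + list(codes[: w - 1]), dtype=np.int64)
    out = np.zeros(len(codes), dtype=np.int64)
    for j in range(w):
        out = out * 4 + arr[j:j + len(codes)]
    return out


@dataclass
class CircularGenome:
    """A circular plus strand; the minus circle is always its derived
    reverse complement and is never stored independently."""

    plus: str
    w: int = 4

    def __post_init__(self) -> None:
        if len(self.plus) < self.w:
            raise SequenceError("circle shorter than the word length")
        _encode(self.plus)  # validates the alphabet

    @property
    def minus(self) -> str:
        return reverse_complement(self.plus)

    @property
    def L(self) -> int:
        return len(self.plus)

    def word_counts(self) -> np.ndarray:
        """n_i over both circular strands (length 4**w array)."""
        rc = _rc_code_table(self.w)
        plus_codes = _window_codes(_encode(self.plus), self.w)
        n = np.bincount(plus_codes, minlength=4 ** self.w)
        n += np.bincount(rc[plus_codes], minlength=4 ** self.w)
        return n

    def doubled(self, strand: str = "plus") -> str:
        """Linearization covering every circular substring up to length L."""
        s = self.plus if strand == "plus" else self.minus
        return s + s


def energy(genome: CircularGenome) -> int:
    """Repeated-word pair count E = sum_i n_i(n_i - 1)/2; E = 0 iff repeat-free."""
    n = genome.word_counts().astype(np.int64)
    return int((n * (n - 1) // 2).sum())


def is_repeat_free(genome: CircularGenome) -> bool:
    """Independent verification that no word occurs twice: rescans every
    circular window of both strands."""
    seen = set()
    for strand in (genome.plus, genome.minus):
        doubled = strand + strand[: genome.w - 1]
        for i in range(genome.L):
            word = doubled[i:i + genome.w]
            if word in seen:
                return False
            seen.add(word)
    return True


# ---------------------------------------------------------------------------
# Combinatorial counts and upper bounds
# ---------------------------------------------------------------------------

def count_self_complementary(w: int) -> int:
    """Number of length-w words equal to their own reverse complement.

    Exhaustive enumeration; zero for odd w, 4**(w/2) for even w.
    """
    if w < 1:
        raise ValueError("w must be >= 1")
    codes = np.arange(4 ** w, dtype=np.int64)
    return int((codes == _rc_code_table(w)).sum())


def naive_upper_bound(w: int) -> int:
    """Upper limit on the repeat-free circle length from dividing the
    non-self-complementary words into two complementary circles."""
    return (4 ** w - count_self_complementary(w)) // 2


def excluded_paired_selfcomp(w: int = 4) -> int:
    """Count of words made of two self-complementary halves that are not
    themselves self-complementary.

    These words are additionally unusable in a repeat-free circle: for w=4
    these are concatenations of two self-complementary dimers (AU, UA, CG,
    GC), e.g. CGAU, minus the 4 that are already self-complementary (e.g.
    CGCG), giving 12.
    """
    if w % 2:
        raise ValueError("defined for even word lengths only")
    half = w // 2
    halves = [i for i in range(4 ** half)
              if int(_rc_code_table(half)[i]) == i]
    rc = _rc_code_table(w)
    count = 0
    for d1 in halves:
        for d2 in halves:
            word = d1 * 4 ** half + d2
            if int(rc[word]) != word:
                count += 1
    return count


def refined_upper_bound(w: int = 4) -> int:
    """Upper bound after removing the two-self-complementary-pair words as
    well; 114 for w = 4."""
    return (4 ** w - count_self_complementary(w) - excluded_paired_selfcomp(w)) // 2


# ---------------------------------------------------------------------------
# Metropolis search
# ---------------------------------------------------------------------------

@dataclass
class AnnealSchedule:
    """Geometric cooling schedule for the Metropolis search.

    ``t_initial`` is the starting effective temperature of the acceptance
    rule exp(-dE/T); after ``steps_per_temp`` proposals the temperature is
    multiplied by ``cooling`` until it falls below ``t_final`` (one
    annealing sweep).  ``p_cut`` is the probability that a proposal is a
    cut-and-paste rearrangement rather than a point mutation; cut lengths
    are uniform on [1, max(1, L * max_cut_frac)].  ``restarts`` independent
    sweeps are run from fresh random sequences unless E = 0 is found first.
    """

    t_initial: float = 0.5
    t_final: float = 0.03
    cooling: float = 0.98
    steps_per_temp: int = 0  # 0 -> 40 * L proposals per temperature
    p_cut: float = 0.2
    max_cut_frac: float = 0.25
    restarts: int = 20
    # After cooling ends, a plateau walk at t_final: near-zero-temperature
    # diffusion over equal-energy states, which resolves the last few
    # repeated pairs far more effectively than further cooling.
    endgame_steps: int = 0  # 0 -> 400 * L proposals
    # Fraction of point mutations proposed at positions currently covered
    # by a repeated word (0 = all positions uniform).  Biasing proposals
    # toward the offending sites makes the low-energy endgame effective at
    # sizes near the combinatorial limit; the move set is unchanged.
    p_repair: float = 0.6
    # If still trapped at E > 0 after the endgame, re-anneal from the
    # current state: jump back to ``reheat_t`` and cool again (with half
    # the dwell), up to ``reheats`` times before the next cold restart.
    reheats: int = 0
    reheat_t: float = 0.25
    # Overall proposal budget per search call (0 = unlimited); the search
    # returns its best genome when the budget runs out.
    max_proposals: int = 0

    def __post_init__(self) -> None:
        if self.t_initial <= 0 or self.t_final <= 0:
            raise ValueError("temperatures must be positive")
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling factor must be in (0, 1)")


@dataclass
class SearchResult:
    genome: CircularGenome
    energy: int
    trace: List[Tuple[int, int]] = field(default_factory=list)
    proposals: int = 0
    restarts_used: int = 0


class _CircleState:
    """Plus-strand sequence with incrementally maintained word counts and E.

    ``codes[p]`` caches the word code of the circular window starting at
    position p.  Point mutations update the w affected windows in O(w);
    cut-and-paste moves rearrange the cached codes with the same splice as
    the sequence and then repair only the 3(w-1) junction windows whose
    content actually changed.
    """

    __slots__ = ("L", "w", "seq", "rc", "pow_hi", "codes", "n", "E")

    def __init__(self, codes: List[int], w: int):
        self.L = len(codes)
        self.w = w
        self.seq = list(codes)
        self.rc = _rc_code_table(w).tolist()
        self.pow_hi = [4 ** (w - 1 - j) for j in range(w)]
        self.rebuild()

    def rebuild(self) -> None:
        wc = _window_codes(self.seq, self.w)
        self.codes = wc.tolist()
        n = np.bincount(wc, minlength=4 ** self.w)
        n += np.bincount(np.asarray(self.rc, dtype=np.int64)[wc],
                         minlength=4 ** self.w)
        self.n = n.astype(np.int64).tolist()
        self.E = int(sum(v * (v - 1) // 2 for v in self.n))

    def _remove_word(self, code: int) -> None:
        n, rc = self.n, self.rc
        c = n[code] - 1
        n[code] = c
        self.E -= c
        r = rc[code]
        c = n[r] - 1
        n[r] = c
        self.E -= c

    def _add_word(self, code: int) -> None:
        n, rc = self.n, self.rc
        c = n[code]
        self.E += c
        n[code] = c + 1
        r = rc[code]
        c = n[r]
        self.E += c
        n[r] = c + 1

    def word_at(self, start: int) -> int:
        """Recompute the window code at ``start`` from the sequence."""
        seq, L = self.seq, self.L
        code = 0
        for j in range(self.w):
            p = start + j
            if p >= L:
                p -= L
            code = code * 4 + seq[p]
        return code

    def point_mutation(self, pos: int, new_base: int) -> int:
        """Apply the mutation in place; return dE.  Undo by re-mutating to
        the previous base."""
        old_base = self.seq[pos]
        if old_base == new_base:
            return 0
        codes = self.codes
        L, w = self.L, self.w
        E0 = self.E
        delta_tbl = self.pow_hi
        diff = new_base - old_base
        for j in range(w):
            start = pos - j
            if start < 0:
                start += L
            code = codes[start]
            self._remove_word(code)
            code += diff * delta_tbl[j]
            codes[start] = code
            self._add_word(code)
        self.seq[pos] = new_base
        return self.E - E0

    def cut_and_paste(self, start: int, length: int, insert: int):
        """Delete the circular block [start, start+length) and reinsert it
        so that it follows position ``insert`` of the remaining sequence.
        Returns an opaque undo token; dE is read off self.E."""
        L, w = self.L, self.w
        b = length
        i = insert
        old_seq = self.seq
        old_codes = self.codes
        old_E = self.E
        if start + b <= L:
            block = old_seq[start:start + b]
            rest = old_seq[start + b:] + old_seq[:start]
            block_c = old_codes[start:start + b]
            rest_c = old_codes[start + b:] + old_codes[:start]
        else:
            wrap = start + b - L
            block = old_seq[start:] + old_seq[:wrap]
            rest = old_seq[wrap:start]
            block_c = old_codes[start:] + old_codes[:wrap]
            rest_c = old_codes[wrap:start]
        new_seq = rest[:i] + block + rest[i:]
        if min(b, i, L - b - i) < w:
            # junction regions overlap; fall back to a full recount
            token = (old_seq, old_codes, None, list(self.n), old_E)
            self.seq = new_seq
            self.rebuild()
            return token
        ops: List[Tuple[int, int]] = []
        self.seq = new_seq
        self.codes = rest_c[:i] + block_c + rest_c[i:]
        codes = self.codes
        # Repair the three junction regions (wrap point, block start, block
        # end); the stale cached codes there are exactly the destroyed
        # windows of the old arrangement.
        for p0 in (L, i, i + b):
            for s in range(p0 - w + 1, p0):
                s_mod = s if s < L else s - L
                old_code = codes[s_mod]
                self._remove_word(old_code)
                new_code = self.word_at(s_mod)
                codes[s_mod] = new_code
                self._add_word(new_code)
                ops.append((old_code, new_code))
        return (old_seq, old_codes, ops, None, old_E)

    def restore(self, token) -> None:
        old_seq, old_codes, ops, n_copy, old_E = token
        self.seq = old_seq
        self.codes = old_codes
        if ops is not None:
            n, rc = self.n, self.rc
            for removed, added in ops:
                n[added] -= 1
                n[rc[added]] -= 1
                n[removed] += 1
                n[rc[removed]] += 1
        else:
            self.n = n_copy
        self.E = old_E


def metropolis_search(L: int, w: int, schedule: AnnealSchedule | None = None,
                      rng: Optional[np.random.Generator] = None,
                      initial: str | None = None) -> SearchResult:
    """Search for a repeat-free circle of length L by simulated annealing.

    Starts from a uniform random circular sequence (or ``initial``),
    proposes point mutations and cut-and-paste rearrangements, accepts with
    probability min(1, exp(-dE/T)) and cools geometrically.  Returns the
    lowest-energy genome found across all restarts; terminates early when
    E = 0 is reached.  The complementary change on the minus strand is
    implicit in the derived-complement representation.
    """
    if L < w:
        raise ValueError("L must be >= w")
    schedule = schedule or AnnealSchedule()
    rng = rng if rng is not None else np.random.default_rng()
    steps_per_temp = schedule.steps_per_temp or 40 * L
    endgame_steps = schedule.endgame_steps or 400 * L
    max_cut = max(1, int(L * schedule.max_cut_frac))

    best_seq: List[int] | None = None
    best_E = None
    trace: List[Tuple[int, int]] = []
    proposals = 0
    restarts_used = 0

    def over_budget() -> bool:
        return bool(schedule.max_proposals) and proposals >= schedule.max_proposals

    def sweep(state: _CircleState, t_start: float, spt: int, eg: int) -> None:
        """One cooling pass from t_start plus a repair-biased plateau."""
        nonlocal proposals
        T = t_start
        while T >= schedule.t_final and state.E > 0 and not over_budget():
            proposals += _anneal_block(state, T, spt, max_cut,
                                       schedule.p_cut, 0.0, rng)
            T *= schedule.cooling
        if state.E > 0 and not over_budget():
            # repair-biased proposals only help once the mixture is frozen
            proposals += _anneal_block(state, schedule.t_final, eg, max_cut,
                                       schedule.p_cut, schedule.p_repair, rng)

    for restart in range(max(1, schedule.restarts)):
        restarts_used = restart + 1
        if initial is not None and restart == 0:
            state = _CircleState(_encode(initial), w)
        else:
            state = _CircleState(rng.integers(0, 4, size=L).tolist(), w)
        sweep(state, schedule.t_initial, steps_per_temp, endgame_steps)
        reheat = 0
        while (state.E > 0 and reheat < schedule.reheats
               and not over_budget()):
            reheat += 1
            sweep(state, schedule.reheat_t, steps_per_temp // 2,
                  endgame_steps // 2)
        trace.append((proposals, state.E))
        if best_E is None or state.E < best_E:
            best_E = state.E
            best_seq = list(state.seq)
        if best_E == 0 or over_budget():
            break

    genome = CircularGenome(_decode(best_seq), w)
    assert energy(genome) == best_E
    return SearchResult(genome, int(best_E), trace, proposals, restarts_used)


def _repeat_positions(state: _CircleState) -> List[int]:
    """Positions covered by a plus-strand window whose word is repeated
    (every repeat, including minus-strand ones, shows up this way because
    the count vector is reverse-complement symmetric)."""
    L, w = state.L, state.w
    n, codes = state.n, state.codes
    out: List[int] = []
    for s in range(L):
        if n[codes[s]] >= 2:
            out.extend((s + j) % L for j in range(w))
    return out


def _anneal_block(state: _CircleState, T: float, nsteps: int, max_cut: int,
                  p_cut: float, p_repair: float,
                  rng: np.random.Generator) -> int:
    """Run up to ``nsteps`` Metropolis proposals at fixed temperature;
    stops early at E = 0.  Returns the number of proposals made."""
    L = state.L
    kinds = rng.random(nsteps) < p_cut
    repair = rng.random(nsteps) < p_repair
    accept_u = rng.random(nsteps)
    positions = rng.integers(0, L, size=nsteps)
    bases = rng.integers(0, 4, size=nsteps)
    exp = np.exp
    repeat_pos: List[int] = []
    repeat_stale = 0
    for i in range(nsteps):
        if kinds[i] and L > 2:
            # cuts shorter than w are dominated by point mutations and
            # force a full recount; draw lengths from [w, max_cut]
            lo = min(state.w, max_cut)
            length = int(rng.integers(lo, max_cut + 1))
            insert = int(rng.integers(0, L - length + 1))
            E_before = state.E
            token = state.cut_and_paste(int(positions[i]), length, insert)
            dE = state.E - E_before
            if dE > 0 and accept_u[i] >= exp(-dE / T):
                state.restore(token)
        else:
            if repair[i]:
                if repeat_stale <= 0:
                    repeat_pos = _repeat_positions(state)
                    repeat_stale = 64
                repeat_stale -= 1
                if repeat_pos:
                    pos = repeat_pos[int(rng.integers(0, len(repeat_pos)))]
                else:
                    pos = int(positions[i])
            else:
                pos = int(positions[i])
            old_base = state.seq[pos]
            dE = state.point_mutation(pos, int(bases[i]))
            if dE > 0 and accept_u[i] >= exp(-dE / T):
                state.point_mutation(pos, old_base)
        if state.E == 0:
            return i + 1
    return nsteps


def random_repeat_free_circle(L: int, w: int = 4,
                              rng: Optional[np.random.Generator] = None,
                              schedule: AnnealSchedule | None = None) -> CircularGenome:
    """A random repeat-free circle of length L, found by the Metropolis
    search; raises if none is found within the schedule's budget."""
    result = metropolis_search(L, w, schedule, rng)
    if result.energy != 0 or not is_repeat_free(result.genome):
        raise RuntimeError(f"no repeat-free circle of length {L} found (E={result.energy})")
    return result.genome


# ---------------------------------------------------------------------------
# Fragment pools
# ---------------------------------------------------------------------------

def make_circle_fragments(genome: CircularGenome, fragment_lengths: Sequence[int],
                          rng: np.random.Generator, min_len: int = 4) -> List[str]:
    """Random circular substrings of the plus and minus strands.

    Each fragment is drawn from a uniformly chosen strand and uniformly
    chosen circular start position.  Used to initialize simulation runs from
    a virtual circle.
    """
    pool: List[str] = []
    for length in fragment_lengths:
        if length < min_len:
            raise ValueError(f"fragment length {length} below the minimum {min_len}")
        if length > genome.L:
            raise ValueError("fragment longer than the circle")
        strand = genome.doubled("plus" if rng.random() < 0.5 else "minus")
        start = int(rng.integers(0, genome.L))
        pool.append(strand[start:start + length])
    return pool


def fragments_and_splints(plus: str, n_frag: int = 5,
                          overlap: int = 10) -> Tuple[List[str], List[str]]:
    """Split a circular plus strand into equal fragments plus minus-strand
    splints bridging consecutive fragments.

    The plus circle of length n_frag * frag_len is cut into ``n_frag``
    fragments.  Splint i is the reverse complement of (last ``overlap``
    bases of fragment i + first ``overlap`` bases of fragment i+1), indices
    modulo ``n_frag``, so each splint templates the ligation of two
    consecutive fragments and the full set closes the circle.
    """
    if len(plus) % n_frag:
        raise ValueError("circle length must divide evenly into fragments")
    frag_len = len(plus) // n_frag
    if overlap > frag_len:
        raise ValueError("overlap longer than a fragment")
    frags = [plus[i * frag_len:(i + 1) * frag_len] for i in range(n_frag)]
    splints = []
    for i in range(n_frag):
        nxt = frags[(i + 1) % n_frag]
        splints.append(reverse_complement(frags[i][-overlap:] + nxt[:overlap]))
    return frags, splints
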