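"""Reaction propensities and the Gillespie growth phase.

Five reaction channels act on a :class:`~vcgsim.core.Mixture` during the
low-temperature growth phase of a cycle:

* nucleation of a new, exactly complementary tetramer (length l0) from free
  monomers on an unpaired template window, at rate
  ``k_nuc * N_i1 N_i2 N_i3 N_i4 / N0**4`` per window;
* annealing of two free windows on strands of different clusters, attempted
  at rate ``k_ann * w_tot / N0`` per window and successful only when the two
  windows are exact reverse complements, after which the new helix is zipped
  up in both directions;
* templated monomer addition (primer extension) at a paired 3' end whose
  next template site is unpaired, at rate ``k_add * N_i / N0`` for the
  Watson-Crick base (relative mismatch rates depend on the rate model);
* templated ligation of a paired 3' end to the 5' end of another strand
  paired at the adjacent template site, at rate ``k_lig``;
* melting of a helix of length l at rate ``k_melt * exp(-(l-l0)*dG/kT)``.

The Gillespie algorithm selects one event with probability proportional to
its rate and advances time by an exponential increment with mean 1/R.

Implementation note: failed annealing attempts change no state, so the
engine fires *successful* annealings directly at the thinned rate
``(k_ann/N0) * M``, where M is the exactly maintained number of ordered
pairs of complementary free windows on strands in different clusters.  This
is distributionally identical to simulating every attempt and rejecting
mismatches, and removes the dominant cost of diverse mixtures.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from .core import (
    BASES,
    Helix,
    InconsistentStateError,
    Mixture,
    Parameters,
    Strand,
)

_BASE_IDX = {b: i for i, b in enumerate(BASES)}

EVENT_KINDS = ("nucleation", "annealing", "addition", "mismatch", "ligation", "melt")


# ---------------------------------------------------------------------------
# Elementary rate laws (unit-testable, used by the engine)
# ---------------------------------------------------------------------------

def addition_coefficients(params: Parameters) -> np.ndarray:
    """coeff[j, i]: relative rate of adding base i opposite template base j.

    The absolute rate is ``k_add * coeff[j, i] * N_i / N0``.  In the basic
    model only the Watson-Crick base has coefficient 1; the equal-error
    model gives every mismatch the relative rate eps; the scaled model uses
    the experimental table normalized by its Watson-Crick mean r_WC.
    """
    coeff = np.zeros((4, 4))
    for j in range(4):
        for i in range(4):
            wc = (i == 3 - j)
            if params.rate_model == "basic":
                coeff[j, i] = 1.0 if wc else 0.0
            elif params.rate_model == "equal_error":
                coeff[j, i] = 1.0 if wc else params.eps
            else:
                coeff[j, i] = params.r_ex[j][i] / params.r_WC
    return coeff


def nucleation_rate(window_template: str, monomer_counts: Dict[str, int],
                    params: Parameters) -> float:
    """Rate of nucleating a complementary primer on one free window."""
    if len(window_template) != params.l0:
        raise ValueError("window must have length l0")
    prod = 1.0
    for b in window_template:
        prod *= monomer_counts[BASES[3 - _BASE_IDX[b]]]
    return params.k_nuc * prod / params.N0 ** params.l0


def annealing_attempt_rate(w_tot: int, params: Parameters) -> float:
    """Total attempted annealing rate to one window, given w_tot potential
    partner windows on strands of other clusters."""
    return params.k_ann * w_tot / params.N0


def addition_rate(added_base: str, template_base: str,
                  monomer_counts: Dict[str, int], params: Parameters) -> float:
    """Rate of adding ``added_base`` opposite ``template_base``."""
    coeff = addition_coefficients(params)
    i, j = _BASE_IDX[added_base], _BASE_IDX[template_base]
    return params.k_add * coeff[j, i] * monomer_counts[added_base] / params.N0


def melting_rate(length: int, params: Parameters) -> float:
    """Melting rate of a helix of the given length (k_melt at length l0)."""
    if length < params.l0:
        raise InconsistentStateError("helix shorter than l0 cannot exist")
    return params.k_melt * math.exp(-(length - params.l0) * params.dG_kT)


def zip_extent(seq_a: str, seq_b: str, pm_a, pm_b, start_a: int, start_b: int,
               length: int, skip=None) -> Tuple[int, int, int]:
    """Maximal zipped extension of a seed duplex.

    The seed pairs ``seq_a[start_a : start_a+length]`` with the reverse
    complement region of strand b starting at ``start_b``.  Extension
    proceeds stepwise in both directions while the next bases are
    Watson-Crick complementary and neither is already paired in another
    helix (``pm_a``/``pm_b`` map position -> helix id or -1).  Returns the
    extended (start_a, start_b, length).
    """
    def free(pm, pos):
        return pm[pos] == -1 or pm[pos] == skip

    # 3' direction on a / 5' direction on b
    a_hi = start_a + length
    b_lo = start_b
    while (a_hi < len(seq_a) and b_lo - 1 >= 0
           and free(pm_a, a_hi) and free(pm_b, b_lo - 1)
           and _BASE_IDX[seq_a[a_hi]] + _BASE_IDX[seq_b[b_lo - 1]] == 3):
        a_hi += 1
        b_lo -= 1
    # 5' direction on a / 3' direction on b
    a_lo = start_a
    b_hi = start_b + length
    while (a_lo - 1 >= 0 and b_hi < len(seq_b)
           and free(pm_a, a_lo - 1) and free(pm_b, b_hi)
           and _BASE_IDX[seq_a[a_lo - 1]] + _BASE_IDX[seq_b[b_hi]] == 3):
        a_lo -= 1
        b_hi += 1
    return a_lo, b_lo, a_hi - a_lo


def zip_helix(mixture: Mixture, strand_a: int, strand_b: int, start_a: int,
              start_b: int, length: int) -> Tuple[int, int, int]:
    """Public zipping operation on a mixture (positions as in
    :func:`zip_extent`); reads pairing state from the mixture's helices."""
    a, b = mixture.strands[strand_a], mixture.strands[strand_b]
    pm_a = _pairmap(mixture, strand_a)
    pm_b = _pairmap(mixture, strand_b)
    return zip_extent(a.seq, b.seq, pm_a, pm_b, start_a, start_b, length)


def _pairmap(mixture: Mixture, sid: int) -> List[int]:
    pm = [-1] * mixture.strands[sid].n
    for helix in mixture.helices_on(sid):
        s, e = helix.interval_on(sid)
        for p in range(s, e):
            pm[p] = helix.id
    return pm


def ligation_candidates(mixture: Mixture) -> List[Tuple[int, int, int, int, int]]:
    """All junctions (primer, template, acceptor, helix1, helix2) where the
    primer's paired 3' end abuts the acceptor's paired 5' end on the same
    template.  Each fires at rate k_lig.  Recomputed from scratch; the
    engine maintains the same set incrementally."""
    out = []
    pms = {sid: _pairmap(mixture, sid) for sid in mixture.strands}
    for sid, strand in mixture.strands.items():
        pm = pms[sid]
        h = pm[strand.n - 1]
        if h == -1 or strand.stalled_3p:
            continue
        helix = mixture.helices[h]
        tmpl = helix.partner_of(sid)
        tb = helix.interval_on(tmpl)[0]
        if tb - 1 < 0:
            continue
        v = pms[tmpl][tb - 1]
        if v == -1 or v == h:
            continue
        h2 = mixture.helices[v]
        acceptor = h2.partner_of(tmpl)
        if (h2.interval_on(tmpl)[1] - 1 == tb - 1
                and h2.interval_on(acceptor)[0] == 0 and acceptor != sid):
            out.append((sid, tmpl, acceptor, h, v))
    return out


# ---------------------------------------------------------------------------
# Sampling containers
# ---------------------------------------------------------------------------

class IndexedSet:
    """Set with O(1) add/discard and O(1) uniform sampling."""

    __slots__ = ("items", "pos")

    def __init__(self):
        self.items: list = []
        self.pos: dict = {}

    def add(self, x) -> None:
        if x not in self.pos:
            self.pos[x] = len(self.items)
            self.items.append(x)

    def discard(self, x) -> None:
        i = self.pos.pop(x, None)
        if i is None:
            return
        last = self.items.pop()
        if i < len(self.items):
            self.items[i] = last
            self.pos[last] = i

    def sample(self, rng) -> object:
        return self.items[int(rng.integers(0, len(self.items)))]

    def __len__(self):
        return len(self.items)

    def __contains__(self, x):
        return x in self.pos

    def __iter__(self):
        return iter(self.items)


def _rc_codes(l0: int) -> np.ndarray:
    codes = np.arange(4 ** l0, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(l0):
        rc = rc * 4 + (3 - (tmp % 4))
        tmp //= 4
    return rc


# ---------------------------------------------------------------------------
# The growth-phase engine
# ---------------------------------------------------------------------------

class GrowthEngine:
    """Incremental propensity bookkeeping and event execution for one
    growth phase.

    The engine indexes, per strand, the pairing map (position -> helix id)
    and the set of free l0-windows keyed by their word code; globally it
    maintains the word-count vector G over free windows, the per-cluster
    word counts (to exclude same-cluster annealing, which the tree rule
    forbids), the exact ordered count M of cross-cluster complementary
    window pairs, the extension-eligible 3' ends grouped by template base,
    the ligation junction set, and the helix length spectrum for melting.

    ``k_add_mult``/``k_lig_mult`` scale the addition and ligation rate
    constants (used for ribozyme-dependent selection in protocells);
    ``constant_monomers`` freezes monomer counts at their current values
    (permeable-membrane protocell contract).
    """

    def __init__(self, mixture: Mixture, params: Parameters,
                 rng: np.random.Generator, k_add_mult: float = 1.0,
                 k_lig_mult: float = 1.0, constant_monomers: bool = False):
        self.mixture = mixture
        self.params = params
        self.rng = rng
        self.k_add_mult = k_add_mult
        self.k_lig_mult = k_lig_mult
        self.constant_monomers = constant_monomers

        p = params
        self.l0 = p.l0
        self.n_words = 4 ** p.l0
        self.rc = _rc_codes(p.l0)
        self.rc_list = self.rc.tolist()
        # base indices of each word, then complement indices (monomers used)
        codes = np.arange(self.n_words, dtype=np.int64)
        digits = []
        tmp = codes.copy()
        for _ in range(p.l0):
            digits.append(tmp % 4)
            tmp //= 4
        self.word_comp_idx = 3 - np.stack(digits[::-1], axis=1)
        self.coeff = addition_coefficients(p)

        self.N = np.array([mixture.monomers[b] for b in BASES], dtype=np.float64)
        self._monomers_dirty = True
        self._f = np.zeros(self.n_words)
        self._S_nuc = 0.0
        self._aw = np.zeros(4)

        self.pm: Dict[int, List[int]] = {}
        self.windows: Dict[int, Dict[int, int]] = {}   # sid -> {start: code}
        self.G = np.zeros(self.n_words, dtype=np.float64)
        self.word_windows: Dict[int, IndexedSet] = {}
        self.cluster_words: Dict[int, Dict[int, int]] = {}
        self.Mg = 0   # ordered complementary pairs, all windows
        self.Mc = 0   # ordered complementary pairs within one cluster
        self.ext: List[IndexedSet] = [IndexedSet() for _ in range(4)]
        self.ext_info: Dict[int, Tuple[int, int]] = {}  # sid -> (template, tpos)
        self.stall_ext: List[IndexedSet] = [IndexedSet() for _ in range(4)]
        self.stalled_cursor: Dict[int, Tuple[int, int]] = {}
        self.junctions: Dict[int, Tuple[int, int, int, int]] = {}
        self.helix_lengths: Dict[int, Set[int]] = {}
        self._melt_wt: Dict[int, float] = {}
        self.event_counts = {k: 0 for k in EVENT_KINDS}
        self.time = 0.0

        for cid in mixture.clusters:
            self.cluster_words[cid] = {}
        for sid in mixture.strands:
            self.pm[sid] = _pairmap(mixture, sid)
            self.windows[sid] = {}
        for hid, helix in mixture.helices.items():
            self._track_helix_length(helix.length, hid)
        for sid in mixture.strands:
            self._scan_windows(sid, 0, mixture.strands[sid].n)
        for sid in mixture.strands:
            self.refresh_end(sid)

    # -- monomer-dependent quantities ------------------------------------

    def _refresh_monomer_terms(self) -> None:
        self._f = self.N[self.word_comp_idx].prod(axis=1)
        self._S_nuc = float(self._f @ self.G)
        self._aw = self.coeff @ self.N
        self._monomers_dirty = False

    def _take_monomer(self, base_idx: int) -> None:
        if self.constant_monomers:
            return
        self.N[base_idx] -= 1
        self.mixture.monomers[BASES[base_idx]] -= 1
        self._monomers_dirty = True

    # -- window index ------------------------------------------------------

    def _win_add(self, sid: int, start: int, code: int) -> None:
        rc = self.rc_list[code]
        s = 1 if rc == code else 0
        self.Mg += 2 * int(self.G[rc]) + s
        self.G[code] += 1
        if not self._monomers_dirty:
            self._S_nuc += self._f[code]
        d = self.cluster_words[self.mixture.cluster_of[sid]]
        self.Mc += 2 * d.get(rc, 0) + s
        d[code] = d.get(code, 0) + 1
        ws = self.word_windows.get(code)
        if ws is None:
            ws = self.word_windows[code] = IndexedSet()
        ws.add((sid, start))
        self.windows[sid][start] = code

    def _win_remove(self, sid: int, start: int) -> None:
        code = self.windows[sid].pop(start)
        rc = self.rc_list[code]
        s = 1 if rc == code else 0
        self.G[code] -= 1
        self.Mg -= 2 * int(self.G[rc]) + s
        if not self._monomers_dirty:
            self._S_nuc -= self._f[code]
        d = self.cluster_words[self.mixture.cluster_of[sid]]
        c = d[code] - 1
        if c:
            d[code] = c
        else:
            del d[code]
        self.Mc -= 2 * d.get(rc, 0) + s
        self.word_windows[code].discard((sid, start))

    def _scan_windows(self, sid: int, lo: int, hi: int) -> None:
        """Recompute free windows with start positions in [lo-l0+1, hi)."""
        strand = self.mixture.strands[sid]
        pm = self.pm[sid]
        l0 = self.l0
        n = strand.n
        first = max(0, lo - l0 + 1)
        last = min(n - l0, hi - 1)
        wins = self.windows[sid]
        seq = strand.seq
        for s in range(first, last + 1):
            free = True
            for p in range(s, s + l0):
                if pm[p] != -1:
                    free = False
                    break
            if free:
                if s not in wins:
                    code = 0
                    for p in range(s, s + l0):
                        code = code * 4 + _BASE_IDX[seq[p]]
                    self._win_add(sid, s, code)
            elif s in wins:
                self._win_remove(sid, s)

    def _drop_all_windows(self, sid: int) -> None:
        for start in list(self.windows[sid]):
            self._win_remove(sid, start)

    # -- cluster word bookkeeping -----------------------------------------

    def _cluster_self_pairs(self, d: Dict[int, int]) -> int:
        rc = self.rc_list
        return sum(c * d.get(rc[w], 0) for w, c in d.items())

    def _merge_clusters_words(self, survivor: int, gone: int) -> None:
        da = self.cluster_words[survivor]
        db = self.cluster_words.pop(gone)
        if len(db) > len(da):
            da, db = db, da
            self.cluster_words[survivor] = da
        rc = self.rc_list
        cross = sum(c * da.get(rc[w], 0) for w, c in db.items())
        self.Mc += 2 * cross
        for w, c in db.items():
            da[w] = da.get(w, 0) + c

    def _split_cluster_words(self, old_cid: int, kept_cid: int, new_cid: int) -> None:
        old = self.cluster_words.pop(old_cid)
        kept_members = self.mixture.clusters[kept_cid].strand_ids
        new_members = self.mixture.clusters[new_cid].strand_ids
        # rebuild the smaller side from its strands' windows
        if len(new_members) <= len(kept_members):
            small_members, small_cid, big_cid = new_members, new_cid, kept_cid
        else:
            small_members, small_cid, big_cid = kept_members, kept_cid, new_cid
        small: Dict[int, int] = {}
        for sid in small_members:
            for code in self.windows[sid].values():
                small[code] = small.get(code, 0) + 1
        big = old
        for w, c in small.items():
            r = big[w] - c
            if r:
                big[w] = r
            else:
                del big[w]
        self.cluster_words[small_cid] = small
        self.cluster_words[big_cid] = big
        self.Mc += (self._cluster_self_pairs(small) + self._cluster_self_pairs(big)
                    - self._cluster_self_pairs_combined(small, big))

    def _cluster_self_pairs_combined(self, d1: Dict[int, int], d2: Dict[int, int]) -> int:
        rc = self.rc_list
        total = 0
        for w, c in d1.items():
            total += c * (d1.get(rc[w], 0) + d2.get(rc[w], 0))
        for w, c in d2.items():
            total += c * (d2.get(rc[w], 0) + d1.get(rc[w], 0))
        return total

    # -- helix length spectrum --------------------------------------------

    def _melt_weight(self, length: int) -> float:
        wt = self._melt_wt.get(length)
        if wt is None:
            wt = self._melt_wt[length] = math.exp(
                -(length - self.l0) * self.params.dG_kT)
        return wt

    def _track_helix_length(self, length: int, hid: int) -> None:
        self.helix_lengths.setdefault(length, set()).add(hid)

    def _untrack_helix_length(self, length: int, hid: int) -> None:
        group = self.helix_lengths[length]
        group.discard(hid)
        if not group:
            del self.helix_lengths[length]

    # -- 3' end status ------------------------------------------------------

    def _clear_end(self, sid: int) -> None:
        info = self.ext_info.pop(sid, None)
        if info is not None:
            self.ext[info[2]].discard(sid)
        self.junctions.pop(sid, None)
        for g in self.stall_ext:
            g.discard(sid)

    def refresh_end(self, sid: int) -> None:
        """Recompute extension/ligation eligibility of one strand's 3' end."""
        self._clear_end(sid)
        mixture = self.mixture
        strand = mixture.strands[sid]
        n = strand.n
        cap = self.params.length_cap
        pm = self.pm[sid]
        h = pm[n - 1]
        if h == -1:
            if (strand.stalled_3p and self.params.stalled_rate_factor > 0
                    and sid in self.stalled_cursor):
                tmpl, tpos = self.stalled_cursor[sid]
                if (tpos >= 0 and tmpl in self.pm and self.pm[tmpl][tpos] == -1
                        and not (cap and n >= cap)):
                    tbase = _BASE_IDX[mixture.strands[tmpl].seq[tpos]]
                    self.stall_ext[tbase].add(sid)
            return
        if strand.stalled_3p:
            return
        helix = mixture.helices[h]
        tmpl = helix.partner_of(sid)
        tb = helix.interval_on(tmpl)[0]
        if tb - 1 < 0:
            return
        v = self.pm[tmpl][tb - 1]
        if v == -1:
            if cap and n >= cap:
                return
            tbase = _BASE_IDX[mixture.strands[tmpl].seq[tb - 1]]
            self.ext_info[sid] = (tmpl, tb - 1, tbase)
            self.ext[tbase].add(sid)
            return
        h2 = mixture.helices[v]
        acceptor = h2.partner_of(tmpl)
        if (h2.interval_on(tmpl)[1] - 1 == tb - 1
                and h2.interval_on(acceptor)[0] == 0 and acceptor != sid):
            if cap and n + mixture.strands[acceptor].n > cap:
                return
            self.junctions[sid] = (tmpl, acceptor, h, v)

    def _refresh_primers_at(self, tmpl: int, pos: int) -> None:
        """Refresh the primer (if any) whose next template site is ``pos``:
        the partner of a helix whose interval on ``tmpl`` starts at pos+1."""
        pm = self.pm[tmpl]
        if pos + 1 >= len(pm):
            return
        hid = pm[pos + 1]
        if hid == -1:
            return
        helix = self.mixture.helices[hid]
        if helix.interval_on(tmpl)[0] != pos + 1:
            return
        primer = helix.partner_of(tmpl)
        ps = self.mixture.strands[primer]
        if self.pm[primer][ps.n - 1] == hid:
            self.refresh_end(primer)

    # -- propensities -------------------------------------------------------

    def propensities(self) -> Dict[str, float]:
        """Current channel propensities in h^-1 (the event menu totals)."""
        p = self.params
        if self._monomers_dirty:
            self._refresh_monomer_terms()
        r_nuc = p.k_nuc * self._S_nuc / p.N0 ** p.l0 if p.k_nuc else 0.0
        M = self.Mg - self.Mc
        r_ann = p.k_ann * M / p.N0 if p.k_ann else 0.0
        kadd = p.k_add * self.k_add_mult
        r_add = 0.0
        if kadd:
            for j in range(4):
                r_add += len(self.ext[j]) * self._aw[j]
                if p.stalled_rate_factor:
                    r_add += (p.stalled_rate_factor
                              * len(self.stall_ext[j]) * self._aw[j])
            r_add *= kadd / p.N0
        r_lig = p.k_lig * self.k_lig_mult * len(self.junctions)
        r_melt = 0.0
        if p.k_melt:
            for length, group in self.helix_lengths.items():
                r_melt += len(group) * self._melt_weight(length)
            r_melt *= p.k_melt
        return {"nucleation": r_nuc, "annealing": max(r_ann, 0.0),
                "addition": r_add, "ligation": r_lig, "melt": r_melt}

    # -- the Gillespie step --------------------------------------------------

    def step(self, t_max: float) -> Optional[str]:
        """Execute one Gillespie event; returns the event kind, or None if
        the phase ended (R = 0 or the waiting time crossed ``t_max``)."""
        props = self.propensities()
        R = sum(props.values())
        if R <= 0.0:
            self.time = t_max
            return None
        dt = self.rng.exponential() / R
        if self.time + dt > t_max:
            self.time = t_max
            return None
        self.time += dt
        u = self.rng.random() * R
        for kind in ("nucleation", "annealing", "addition", "ligation", "melt"):
            u -= props[kind]
            if u <= 0.0:
                break
        if kind == "nucleation":
            self._exec_nucleation()
        elif kind == "annealing":
            self._exec_annealing()
        elif kind == "addition":
            kind = self._exec_addition()
        elif kind == "ligation":
            self._exec_ligation()
        else:
            self._exec_melt()
        self.event_counts[kind] += 1
        return kind

    def run(self, t_max: float) -> None:
        while self.time < t_max:
            if self.step(t_max) is None:
                break

    # -- event executors ----------------------------------------------------

    def _new_helix(self, sid_a: int, sid_b: int, sa: int, sb: int,
                   length: int) -> Helix:
        """Create a helix (clusters must differ), maintaining all indices."""
        mixture = self.mixture
        ca = mixture.cluster_of[sid_a]
        cb = mixture.cluster_of[sid_b]
        helix = mixture.add_helix(sid_a, sid_b, sa, sb, length)
        survivor = mixture.cluster_of[sid_a]
        self._merge_clusters_words(survivor, cb if survivor == ca else ca)
        pm_a, pm_b = self.pm[sid_a], self.pm[sid_b]
        for p in range(sa, sa + length):
            pm_a[p] = helix.id
        for p in range(sb, sb + length):
            pm_b[p] = helix.id
        self._track_helix_length(length, helix.id)
        self._scan_windows(sid_a, sa, sa + length)
        self._scan_windows(sid_b, sb, sb + length)
        self.refresh_end(sid_a)
        self.refresh_end(sid_b)
        # a primer abutting the new helix has its next site newly blocked
        # (or gains a ligation junction onto the new partner's 5' end)
        self._refresh_primers_at(sid_a, sa + length - 1)
        self._refresh_primers_at(sid_b, sb + length - 1)
        if self.params.stalled_rate_factor:
            self._refresh_stalled_on(sid_a, sa, sa + length)
            self._refresh_stalled_on(sid_b, sb, sb + length)
        return helix

    def _refresh_stalled_on(self, tmpl: int, lo: int, hi: int) -> None:
        for sid, (t, tpos) in list(self.stalled_cursor.items()):
            if t == tmpl and lo - 1 <= tpos <= hi:
                self.refresh_end(sid)

    def _exec_nucleation(self) -> None:
        rng = self.rng
        weights = self.G * self._f
        total = weights.sum()
        cum = np.cumsum(weights)
        code = int(np.searchsorted(cum, rng.random() * total, side="right"))
        code = min(code, self.n_words - 1)
        sid, start = self.word_windows[code].sample(rng)
        tmpl_strand = self.mixture.strands[sid]
        window = tmpl_strand.seq[start:start + self.l0]
        new_seq = "".join(BASES[3 - _BASE_IDX[b]] for b in reversed(window))
        for b in new_seq:
            self._take_monomer(_BASE_IDX[b])
        strand = self.mixture.new_strand(new_seq, n_start=self.l0)
        self.pm[strand.id] = [-1] * self.l0
        self.windows[strand.id] = {}
        self.cluster_words[self.mixture.cluster_of[strand.id]] = {}
        self._scan_windows(strand.id, 0, self.l0)
        self._new_helix(strand.id, sid, 0, start, self.l0)

    def _exec_annealing(self) -> None:
        rng = self.rng
        rc = self.rc
        weights = self.G * self.G[rc]
        cum = np.cumsum(weights)
        total = cum[-1]
        cluster_of = self.mixture.cluster_of
        pair = None
        for _ in range(60):
            code = int(np.searchsorted(cum, rng.random() * total, side="right"))
            code = min(code, self.n_words - 1)
            w1 = self.word_windows[code].sample(rng)
            w2 = self.word_windows[int(rc[code])].sample(rng)
            if cluster_of[w1[0]] != cluster_of[w2[0]]:
                pair = (w1, w2)
                break
        if pair is None:
            pair = self._enumerate_annealing_pair()
            if pair is None:
                return
        (sid_a, sa), (sid_b, sb) = pair
        a = self.mixture.strands[sid_a]
        b = self.mixture.strands[sid_b]
        a_lo, b_lo, length = zip_extent(a.seq, b.seq, self.pm[sid_a],
                                        self.pm[sid_b], sa, sb, self.l0)
        self._new_helix(sid_a, sid_b, a_lo, b_lo, length)

    def _enumerate_annealing_pair(self):
        """Exhaustive fallback when rejection sampling keeps drawing
        same-cluster pairs (pathological near-depleted menus)."""
        rc = self.rc_list
        cluster_of = self.mixture.cluster_of
        valid = []
        for code, ws in self.word_windows.items():
            if not len(ws):
                continue
            partner = self.word_windows.get(rc[code])
            if partner is None or not len(partner):
                continue
            for w1 in ws:
                for w2 in partner:
                    if cluster_of[w1[0]] != cluster_of[w2[0]]:
                        valid.append((w1, w2))
        if not valid:
            return None
        return valid[int(self.rng.integers(0, len(valid)))]

    def _exec_addition(self) -> str:
        rng = self.rng
        p = self.params
        group_w = []
        groups = []
        for j in range(4):
            group_w.append(len(self.ext[j]) * self._aw[j])
            groups.append((self.ext[j], j, False))
        if p.stalled_rate_factor:
            for j in range(4):
                group_w.append(p.stalled_rate_factor
                               * len(self.stall_ext[j]) * self._aw[j])
                groups.append((self.stall_ext[j], j, True))
        total = sum(group_w)
        u = rng.random() * total
        for gw, (gset, j, stalled_group) in zip(group_w, groups):
            u -= gw
            if u <= 0.0:
                break
        sid = gset.sample(rng)
        # choose the added base ~ coeff[j, i] * N_i
        bw = self.coeff[j] * self.N
        u = rng.random() * bw.sum()
        for i in range(4):
            u -= bw[i]
            if u <= 0.0:
                break
        strand = self.mixture.strands[sid]
        self._take_monomer(i)
        if stalled_group:
            tmpl, tpos = self.stalled_cursor[sid]
            self._append_base(sid, i, paired=False)
            self.stalled_cursor[sid] = (tmpl, tpos - 1)
            self.refresh_end(sid)
            return "mismatch"
        tmpl, tpos, tbase = self.ext_info[sid]
        if i == 3 - tbase:
            self._extend_helix(sid, tmpl, tpos, i)
            return "addition"
        # mismatch: unpaired tail of length 1, growth stalls for this cycle
        self._append_base(sid, i, paired=False)
        strand.stalled_3p = True
        self.stalled_cursor[sid] = (tmpl, tpos - 1)
        self.refresh_end(sid)
        return "mismatch"

    def _append_base(self, sid: int, base_idx: int, paired: bool,
                     helix_id: int = -1) -> None:
        strand = self.mixture.strands[sid]
        strand.seq += BASES[base_idx]
        self.pm[sid].append(helix_id if paired else -1)
        self._scan_windows(sid, strand.n - 1, strand.n)

    def _extend_helix(self, sid: int, tmpl: int, tpos: int, base_idx: int) -> None:
        strand = self.mixture.strands[sid]
        hid = self.pm[sid][strand.n - 1]
        helix = self.mixture.helices[hid]
        self._untrack_helix_length(helix.length, hid)
        helix.length += 1
        if helix.strand_a == tmpl:
            helix.start_a -= 1
        else:
            helix.start_b -= 1
        self._track_helix_length(helix.length, hid)
        self._append_base(sid, base_idx, paired=True, helix_id=hid)
        self.pm[tmpl][tpos] = hid
        self._scan_windows(tmpl, tpos, tpos + 1)
        self.refresh_end(sid)
        if self.params.stalled_rate_factor:
            self._refresh_stalled_on(tmpl, tpos, tpos + 1)

    def _exec_ligation(self) -> None:
        rng = self.rng
        keys = list(self.junctions)
        primer = keys[int(rng.integers(0, len(keys)))]
        tmpl, acceptor, h1_id, h2_id = self.junctions[primer]
        mixture = self.mixture
        a = mixture.strands[primer]
        c = mixture.strands[acceptor]
        h1 = mixture.helices[h1_id]
        h2 = mixture.helices[h2_id]
        nA = a.n
        l2 = h2.length

        # drop window/end records of both strands; rebuilt after the splice
        self._drop_all_windows(primer)
        self._drop_all_windows(acceptor)
        self._clear_end(primer)
        self._clear_end(acceptor)

        # concatenate sequences and pairing maps
        a.seq += c.seq
        self.pm[primer].extend(self.pm.pop(acceptor))
        del self.windows[acceptor]

        # re-anchor every helix of the acceptor onto the product strand
        for helix in list(mixture.helices_on(acceptor)):
            if helix.strand_a == acceptor:
                helix.strand_a = primer
                helix.start_a += nA
            else:
                helix.strand_b = primer
                helix.start_b += nA

        # merge h2 into h1: contiguous duplex on the shared template
        self._untrack_helix_length(h1.length, h1_id)
        self._untrack_helix_length(h2.length, h2_id)
        if h1.strand_a == tmpl:
            h1.start_a -= l2
        else:
            h1.start_b -= l2
        h1.length += l2
        self._track_helix_length(h1.length, h1_id)
        pm_p = self.pm[primer]
        pm_t = self.pm[tmpl]
        s, e = h1.interval_on(primer)
        for pos in range(s, e):
            pm_p[pos] = h1_id
        s, e = h1.interval_on(tmpl)
        for pos in range(s, e):
            pm_t[pos] = h1_id
        del mixture.helices[h2_id]

        # cluster bookkeeping: acceptor strand and helix h2 disappear from
        # the tree (vertex contraction keeps it a tree)
        cid = mixture.cluster_of[primer]
        cluster = mixture.clusters[cid]
        cluster.strand_ids.discard(acceptor)
        cluster.helix_ids.discard(h2_id)
        del mixture.cluster_of[acceptor]
        a.stalled_3p = c.stalled_3p
        cur = self.stalled_cursor.pop(acceptor, None)
        if cur is not None:
            self.stalled_cursor[primer] = cur
        # cursors that referenced the acceptor as a template shift by nA
        for sid2, (t2, tp2) in list(self.stalled_cursor.items()):
            if t2 == acceptor:
                self.stalled_cursor[sid2] = (primer, tp2 + nA)
        del mixture.strands[acceptor]

        self._scan_windows(primer, 0, a.n)
        self.refresh_end(primer)
        self.refresh_end(tmpl)
        # strands paired to the old acceptor now reference the product
        for helix in mixture.helices_on(primer):
            self.refresh_end(helix.partner_of(primer))

    def _exec_melt(self) -> None:
        rng = self.rng
        p = self.params
        weights = []
        lengths = []
        for length, group in self.helix_lengths.items():
            lengths.append(length)
            weights.append(len(group) * self._melt_weight(length))
        total = sum(weights)
        u = rng.random() * total
        for length, wgt in zip(lengths, weights):
            u -= wgt
            if u <= 0.0:
                break
        group = self.helix_lengths[length]
        hid = list(group)[int(rng.integers(0, len(group)))]
        self.melt_helix(hid)

    def melt_helix(self, hid: int) -> None:
        """Remove one helix, split the cluster, refresh all affected state."""
        mixture = self.mixture
        helix = mixture.helices[hid]
        sid_a, sid_b = helix.strand_a, helix.strand_b
        sa, ea = helix.interval_on(sid_a)
        sb, eb = helix.interval_on(sid_b)
        old_cid = mixture.cluster_of[sid_a]
        self._untrack_helix_length(helix.length, hid)
        kept, new = mixture.remove_helix(hid)
        self._split_cluster_words(old_cid, kept.id, new.id)
        pm_a, pm_b = self.pm[sid_a], self.pm[sid_b]
        for pos in range(sa, ea):
            pm_a[pos] = -1
        for pos in range(sb, eb):
            pm_b[pos] = -1
        self._scan_windows(sid_a, sa, ea)
        self._scan_windows(sid_b, sb, eb)
        self.refresh_end(sid_a)
        self.refresh_end(sid_b)
        # a primer whose next template site was inside the freed interval
        if ea < len(pm_a):
            self._refresh_primers_at(sid_a, ea - 1)
        if eb < len(pm_b):
            self._refresh_primers_at(sid_b, eb - 1)
        if p_factor := self.params.stalled_rate_factor:
            self._refresh_stalled_on(sid_a, sa, ea)
            self._refresh_stalled_on(sid_b, sb, eb)

    # -- audits -------------------------------------------------------------

    def audit(self) -> None:
        """Full-rebuild consistency check of all incremental indices."""
        fresh = GrowthEngine(self.mixture, self.params, self.rng,
                             self.k_add_mult, self.k_lig_mult,
                             self.constant_monomers)
        if not np.array_equal(fresh.G, self.G):
            raise InconsistentStateError("window word counts diverged")
        if (fresh.Mg, fresh.Mc) != (self.Mg, self.Mc):
            raise InconsistentStateError(
                f"annealing pair counts diverged: "
                f"{(fresh.Mg, fresh.Mc)} != {(self.Mg, self.Mc)}")
        if fresh.windows != self.windows:
            raise InconsistentStateError("per-strand windows diverged")
        if fresh.ext_info != self.ext_info:
            raise InconsistentStateError("extension-eligible ends diverged")
        if fresh.junctions != self.junctions:
            raise InconsistentStateError("ligation junctions diverged")
        got = {length: set(g) for length, g in self.helix_lengths.items()}
        want = {length: set(g) for length, g in fresh.helix_lengths.items()}
        if got != want:
            raise InconsistentStateError("helix length spectrum diverged")
        self.mixture.check_invariants(self.l0)


def gillespie_step(engine: GrowthEngine, t_max: float) -> Optional[str]:
    """Advance the engine by one Gillespie event (see GrowthEngine.step)."""
    return engine.step(t_max)


def run_growth_phase(mixture: Mixture, params: Parameters,
                     rng: np.random.Generator, k_add_mult: float = 1.0,
                     k_lig_mult: float = 1.0, constant_monomers: bool = False,
                     audit_every: int = 0) -> GrowthEngine:
    """Run one complete growth phase of duration T_grow.

    Resets per-cycle bookkeeping (n_start, stall flags), then repeats
    Gillespie steps until the elapsed phase time reaches T_grow.  Returns
    the engine (whose event counts and final menu are useful diagnostics).
    """
    for strand in mixture.strands.values():
        strand.n_start = strand.n
        strand.stalled_3p = False
    engine = GrowthEngine(mixture, params, rng, k_add_mult, k_lig_mult,
                          constant_monomers)
    if audit_every:
        steps = 0
        while engine.time < params.T_grow:
            if engine.step(params.T_grow) is None:
                break
            steps += 1
            if steps % audit_every == 0:
                engine.audit()
        engine.audit()
    else:
        engine.run(params.T_grow)
    return engine
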