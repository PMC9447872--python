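"""k-mer word-graph statistics for detecting virtual circular genomes.

Every overlapping k-mer (default k = 5, one more than the minimum helix
length) in strands of length >= k is a word token.  Words are nodes of a
directed graph with an edge i -> j when the last k-1 letters of i equal the
first k-1 letters of j and both words are present.  On this graph:

* ``X(n)`` (connectivity): probability that two words drawn from the
  mixture are joined by a directed path of exactly n steps,
  X(n) = sum_ij f_i f_j P^n_ij;
* ``C(n)`` (circularity): fraction of word tokens lying on a circular path
  of exactly n steps, C(n) = sum_i f_i P^n_ii;
* ``S(n)`` (specificity): frequency-weighted mean over start words of the
  relative frequency of the most common word reachable in n steps;
* ``p_circ``: fraction of word tokens lying on a circular path of any
  length; ``D``: the number of distinct words present.

A perfect virtual circle of length L shows X(n) = 1/(2L), S(n) = 1 for all
n, C(n) = 1 exactly at multiples of L, and p_circ = 1; a complete random
mixture shows X(n) = C(n) -> 1 for n >= k and low, decaying S(n).  The path
matrix P^n is the boolean n-step reachability iterated from the transition
matrix T (P^1 = T).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .core import Strand


def word_counts(strands: Iterable, k: int = 5) -> Dict[str, int]:
    """Multiplicity of every k-mer over all strands of length >= k (a
    strand of length n contributes n - k + 1 tokens)."""
    counts: Dict[str, int] = {}
    for strand in strands:
        seq = strand.seq if isinstance(strand, Strand) else str(strand)
        for i in range(len(seq) - k + 1):
            word = seq[i:i + k]
            counts[word] = counts.get(word, 0) + 1
    return counts


def word_frequencies(strands: Iterable, k: int = 5) -> Dict[str, float]:
    """Normalized word frequencies f_i (empty dict if no strand reaches k)."""
    counts = word_counts(strands, k)
    total = sum(counts.values())
    return {w: c / total for w, c in counts.items()} if total else {}


class WordGraphStats:
    """Word frequencies, boolean transition matrix and derived graph
    functions of one mixture."""

    def __init__(self, counts: Dict[str, int], k: int = 5):
        self.k = k
        self.words: List[str] = sorted(counts)
        self.index = {w: i for i, w in enumerate(self.words)}
        self.counts = np.array([counts[w] for w in self.words], dtype=np.int64)
        total = self.counts.sum()
        self.f = self.counts / total if total else self.counts.astype(float)
        self.T = self._transition_matrix()

    @classmethod
    def from_strands(cls, strands: Iterable, k: int = 5) -> "WordGraphStats":
        return cls(word_counts(strands, k), k)

    @property
    def D(self) -> int:
        """Diversity: the number of distinct words present."""
        return len(self.words)

    def _transition_matrix(self) -> np.ndarray:
        D = len(self.words)
        T = np.zeros((D, D), dtype=bool)
        by_prefix: Dict[str, List[int]] = {}
        for j, w in enumerate(self.words):
            by_prefix.setdefault(w[:-1], []).append(j)
        for i, w in enumerate(self.words):
            for j in by_prefix.get(w[1:], ()):
                T[i, j] = True
        return T


def path_matrices(T: np.ndarray, n_max: int) -> List[np.ndarray]:
    """Boolean exact-n-step path matrices P^1..P^n_max,
    P^(n+1)_ij = 1 iff sum_k P^n_ik T_kj > 0."""
    T = np.asarray(T, dtype=bool)
    out = [T.copy()]
    Tf = T.astype(np.float32)
    P = Tf.copy()
    for _ in range(n_max - 1):
        P = (P @ Tf > 0).astype(np.float32)
        out.append(P.astype(bool))
    return out


@dataclass
class GraphFunctions:
    """X, S, C over n = 1..n_cap, plus any-length circularity."""

    n: np.ndarray
    X: np.ndarray
    S: np.ndarray
    C: np.ndarray
    p_circ: float
    on_cycle: np.ndarray   # boolean per present word: P*_ii = 1

    def cycle_lengths(self) -> List[int]:
        """Step counts n (within the computed range) with C(n) > 0."""
        return [int(n) for n, c in zip(self.n, self.C) if c > 0]


def graph_functions(stats: WordGraphStats, n_cap: int = 30,
                    n_cap_circ: Optional[int] = None) -> GraphFunctions:
    """Evaluate X(n), S(n), C(n) for n = 1..n_cap and p_circ.

    ``P*_ii`` (word on a circular path of any length) is established by
    iterating the path matrix for up to ``n_cap_circ`` steps (default D: a
    cycle through distinct present words cannot need more steps, since any
    longer circular path revisits a word).  Iteration stops early once
    every word is known to be on a cycle, the path matrix empties (acyclic
    graph exhausted), or the matrix sequence repeats.
    """
    D = stats.D
    if D == 0:
        empty = np.zeros(0)
        return GraphFunctions(np.arange(1, n_cap + 1),
                              np.zeros(n_cap), np.zeros(n_cap),
                              np.zeros(n_cap), 0.0, empty.astype(bool))
    if n_cap_circ is None:
        n_cap_circ = D
    f = stats.f
    Tf = stats.T.astype(np.float32)
    X = np.zeros(n_cap)
    S = np.zeros(n_cap)
    C = np.zeros(n_cap)
    on_cycle = np.zeros(D, dtype=bool)
    P = Tf.copy()
    seen_hashes = set()
    for n in range(1, max(n_cap, n_cap_circ) + 1):
        B = P > 0
        if n <= n_cap:
            i = n - 1
            X[i] = float(f @ B @ f)
            C[i] = float(f[np.diag(B)].sum())
            A = B * f[None, :]
            tot = A.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                s_i = np.where(tot > 0, A.max(axis=1) / np.where(tot > 0, tot, 1.0), 0.0)
            S[i] = float(f @ s_i)
        on_cycle |= np.diag(B)
        if on_cycle.all() and n >= n_cap:
            break
        if not B.any():
            break
        key = hash(B.tobytes())
        if key in seen_hashes and n >= n_cap:
            break
        seen_hashes.add(key)
        if n < max(n_cap, n_cap_circ):
            P = (P @ Tf > 0).astype(np.float32)
    p_circ = min(1.0, float(f[on_cycle].sum()))
    return GraphFunctions(np.arange(1, n_cap + 1), X, S, C, p_circ, on_cycle)


# ---------------------------------------------------------------------------
# Graph export
# ---------------------------------------------------------------------------

_COLORS = {"cycle": "red", "source": "green", "sink": "blue", "path": "grey"}


def to_networkx(stats: WordGraphStats,
                funcs: Optional[GraphFunctions] = None) -> nx.DiGraph:
    """Directed word graph with node attributes: ``freq``, ``color`` (red =
    on a cycle, green = source, blue = sink, grey otherwise), ``label``
    (the last base; sources carry the full word) and log-frequency
    ``size``."""
    if funcs is None:
        funcs = graph_functions(stats, n_cap=1)
    G = nx.DiGraph()
    T = stats.T
    indeg = T.sum(axis=0)
    outdeg = T.sum(axis=1)
    fmin = stats.f[stats.f > 0].min() if stats.D else 1.0
    for i, w in enumerate(stats.words):
        if funcs.on_cycle[i]:
            color = _COLORS["cycle"]
        elif indeg[i] == 0:
            color = _COLORS["source"]
        elif outdeg[i] == 0:
            color = _COLORS["sink"]
        else:
            color = _COLORS["path"]
        label = w if indeg[i] == 0 else w[-1]
        size = 0.3 + 0.15 * float(np.log(stats.f[i] / fmin) + 1.0)
        G.add_node(w, freq=float(stats.f[i]), color=color, label=label,
                   size=round(size, 4))
    for i, j in zip(*np.nonzero(T)):
        G.add_edge(stats.words[i], stats.words[j])
    return G


def write_dot(G: nx.DiGraph, path: str) -> None:
    """Minimal DOT serialization (nodes with label/color/width, edges)."""
    with open(path, "w") as fh:
        fh.write("digraph words {\n  node [style=filled];\n")
        for node, attrs in G.nodes(data=True):
            fh.write(f'  "{node}" [label="{attrs.get("label", node)}", '
                     f'fillcolor="{attrs.get("color", "grey")}", '
                     f'width={attrs.get("size", 0.3)}];\n')
        for u, v in G.edges():
            fh.write(f'  "{u}" -> "{v}";\n')
        fh.write("}\n")


def write_graphml(G: nx.DiGraph, path: str) -> None:
    nx.write_graphml(G, path)


def export_word_graph(stats: WordGraphStats, dot_path: Optional[str] = None,
                      graphml_path: Optional[str] = None) -> nx.DiGraph:
    """Build the colored word graph and write DOT and/or GraphML files."""
    funcs = graph_functions(stats, n_cap=1)
    G = to_networkx(stats, funcs)
    if dot_path:
        write_dot(G, dot_path)
    if graphml_path:
        write_graphml(G, graphml_path)
    return G
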