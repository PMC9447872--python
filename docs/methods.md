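# Methods

`vcgsim` simulates non-enzymatic, template-directed RNA synthesis in a
well-mixed volume driven by temperature cycling, and provides the word-graph
diagnostics used to ask whether such a system can carry heritable sequence
information as a *virtual circular genome* — a pool of short overlapping
fragments that could in principle be arranged on a circular master sequence
and act as mutual templates.

## The reaction model

The state is a set of explicit RNA strands (5'→3' base strings), a set of
helices (contiguous antiparallel Watson–Crick duplexes between intervals of
two strands, minimum length l₀), the tree-structured clusters those helices
induce, and free monomer counts N_A, N_C, N_G, N_U.  Concentrations are
expressed as counts relative to the initial monomer number N₀ per base, so
every rate constant is in h⁻¹ and no volume needs to be specified.

During the growth phase (duration T_grow) five reaction channels compete
under the exact Gillespie algorithm (one event chosen proportionally to its
rate; time advanced by an exponential increment with mean 1/R):

| channel | rate | effect |
| --- | --- | --- |
| nucleation | k_nuc·N_i1·N_i2·N_i3·N_i4/N₀⁴ per free l₀-window | a new, exactly complementary tetramer strand + length-4 helix; monomers consumed |
| annealing | k_ann·w_tot/N₀ attempted per free window | a new helix if the two windows are exact reverse complements, then zipped both ways |
| addition | k_add·c(i\|j)·N_i/N₀ per eligible paired 3' end | primer extension by one base; the helix grows if the base is Watson–Crick |
| ligation | k_lig per junction | two strands paired at adjacent template sites are joined; their helices merge into one |
| melting | k_melt·e^−(l−l₀)·ΔG/kT per helix | the helix is removed and its cluster splits in two |

A *window* is a run of l₀ contiguous unpaired bases; overlapping windows
count individually, so an unpaired strand of length n has n−l₀+1 of them.
A new helix may only connect strands in *different* clusters; this keeps
every cluster a branching tree (helices = strands − 1) and stands in for the
excluded-volume effects that prevent real molecules from knotting.  Ligation
is the one same-cluster interaction, and it preserves the tree by
contraction.  3-D structure, wobble pairs and sequence-dependent stacking
are outside the model; ΔG/kT is a single average stacking parameter.

Addition models: `basic` admits only the complementary base (c = 1 for
Watson–Crick, else 0); `equal_error` gives every mismatch the relative rate
ε; `scaled_experimental` uses a packaged 4×4 table of measured
nucleotide-addition rates (h⁻¹, normalized to equal 10 mM concentrations; U
rows scaled accordingly) divided by its Watson–Crick mean r_WC = 4.348 h⁻¹,
so that the mean Watson–Crick rate is k_add in all three models.  After a
mismatch the added base becomes an unpaired 3' tail of length 1 and the
strand stalls for the rest of the growth phase (the tail also blocks
ligation).  A `stalled_rate_factor` knob re-enables post-mismatch additions
at a reduced relative rate (further bases stay unpaired); it defaults to 0
because allowing it barely changes outcomes while complicating the
geometry.  The template base opposite a mismatch tail remains an ordinary
unpaired base, available to other strands.

At the end of each growth phase all helices melt regardless of length
(high-temperature step), after which each strand is lost independently with
probability φ, monomer counts relax as N ← round(N(1−φ)) + φN₀, and
N_inflow = φ·N_init fresh random oligomers enter (omitted when oligomer
inflow is disabled).  Inflowing oligomers have i.i.d. uniform bases and
lengths from the truncated geometric P(n) ∝ λⁿ⁻⁴ on 4–10 (mean 4.94 at
λ = 1/2), emulating slow untemplated polymerization outside the volume;
anything longer than 10 therefore demonstrably came from templated
chemistry.  Deterministic rounding (rather than binomial sampling) is used
for the monomer and oligomer inflow counts, since the exchange is specified
by its mean counts and the strand-loss step already supplies demographic
noise.

### Standard parameters

N₀ = 5000 monomers per base, N_init = 500 oligomers, φ = 0.05 (hence
N_inflow = 25), l₀ = 4, λ = 0.5, k_nuc = 0.1 h⁻¹, k_ann = 10 h⁻¹,
k_add = 10 h⁻¹, k_lig = 1 h⁻¹, k_melt = 1 h⁻¹, ΔG/kT = 2, T_grow = 6 h.
These are the defaults of `Parameters()` and of an empty run configuration.

### Annealing bookkeeping

The attempted-annealing process pairs random windows and succeeds only on
an exact reverse-complement match, so almost all attempts in a diverse
mixture are no-ops.  The engine therefore maintains the exact number M of
*ordered* pairs of complementary free windows on strands of different
clusters (global word counts minus per-cluster word counts, updated
event-locally) and fires successful annealings directly at the thinned rate
(k_ann/N₀)·M, drawing a matching pair uniformly.  Because failed attempts
change no state, this is distributionally identical to simulating every
attempt, at a tiny fraction of the cost.  Ordered-pair counting means each
unordered window pair is reachable in two ways; the per-window attempt rate
of the rate law is summed over windows, so a lone complementary tetramer
pair anneals at 2·k_ann/N₀.  All other propensities are kept incrementally
as well (extension-eligible 3' ends grouped by template base, the ligation
junction set, the helix length spectrum for melting), and
`GrowthEngine.audit()` rebuilds everything from scratch and compares —
tests run with `audit_every` to catch any bookkeeping drift.

Within a cycle, each strand records its length n_start at the start of the
growth phase; Δn = n − n_start is reported against n_start.  A ligation
product keeps the identity (and n_start) of its 5'-side fragment and the
3'-side record closes without a Δn sample, which keeps Δn well defined per
surviving strand.  Metrics — mean/max length, strand count N_seq, length
histogram N(n), Δn(n_start), mean helices per strand h(n), mean paired
bases m(n), optionally word diversity D — are recorded at the end of the
growth phase, before melting and outflow.  Steady-state summaries average
the last half of a run.

## Word-graph diagnostics

Words are overlapping k-mers (default k = 5 = l₀+1, the shortest template
length) counted with multiplicity across strands of length ≥ k.  The
boolean transition matrix T links words overlapping by k−1; boolean
iteration gives exact-n-step path matrices Pⁿ, from which the connectivity
X(n) = ΣᵢΣⱼ fᵢfⱼPⁿᵢⱼ, circularity C(n) = Σᵢ fᵢPⁿᵢᵢ, specificity
S(n) = Σᵢ fᵢ·(max accessible frequency / total accessible frequency), and
p_circ = Σᵢ fᵢ P*ᵢᵢ follow.  P*ᵢᵢ is decided by iterating up to D steps — a
circular path through distinct present words needs at most D — with early
exits when every word is on a cycle, the path matrix empties, or the
(eventually periodic) matrix sequence repeats.  A perfect virtual circle of
length L gives X = 1/(2L) and S = 1 for all n and C(n) = 1 exactly at
multiples of L; a complete random 5-mer mixture gives
X(n) = C(n) = 4ⁿ⁻⁵ → 1 and S(n) = 4⁻ⁿ → 4⁻⁵.  Word graphs export to DOT
and GraphML with nodes sized by log-frequency (floored) and coloured red
(on a cycle), green (source, labelled with the full word), blue (sink) or
grey.

## Repeat-free virtual circles

A circular genome is stored as its plus strand only; the minus circle is
always the derived reverse complement.  Both circular strands contribute L
wrap-around windows of length w each, and E = Σᵢ nᵢ(nᵢ−1)/2 counts repeated
word pairs; E = 0 (repeat-free) is required for a virtual circle to copy
without generating off-circle sequences.  Counting words on the circle
(rather than on a linearization) is forced by the combinatorics: only with
wrap-around windows is the refined tetramer limit 114 attainable.

Of the 4⁴ = 256 tetramers, 16 are self-complementary and cannot appear
(they would recur in the complementary circle), giving the naive bound
(256−16)/2 = 120.  Another 12 — concatenations of two self-complementary
dimers (AU, UA, CG, GC) that are not themselves self-complementary, e.g.
CGAU — are also found to be excluded in every zero-energy solution, giving
(256−16−12)/2 = 114.  The search confirms E = 0 is reachable at L = 114 and
not at 115–120 under an equal budget.  For w = 5 there are no
self-complementary words and the bound 1024/2 = 512 is attained.

The minimizer is Metropolis simulated annealing: proposals are single point
mutations (probability 1−p_cut) or cut-and-paste moves (a block of uniform
random length in [w, L/4] deleted and reinserted elsewhere; shorter cuts
are dominated by point mutations), accepted with min(1, e^−ΔE/T) under
geometric cooling (defaults T: 0.5 → 0.03, factor 0.98, 40·L proposals per
temperature), followed by an endgame plateau at the final temperature —
near-zero-temperature diffusion across equal-energy states resolves the
last few repeated pairs far more effectively than further cooling.  During
the plateau a fraction p_repair (default 0.6) of point mutations is
proposed at positions currently covered by a repeated word, which
concentrates the search on the defects without changing the move set
(applying the bias during cooling degrades the quench and is not done).
If a sweep still ends trapped at E > 0, the search re-anneals from the
trapped state — temperature jumps back to reheat_t = 0.25 and cools again
with half the dwell — up to a configurable number of reheats before the
next cold restart.  At the tetramer limit L = 114 and at the 5-mer limit
L = 512 this combination reaches E = 0 reliably within a restart or two;
plain cooling alone strands most runs at E between 2 and 16 at L = 512.
ΔE is maintained incrementally: point
mutations touch w windows; a cut-and-paste splices the cached window codes
and repairs only the 3(w−1) junction windows, falling back to a full
recount when the junction regions overlap.  Randomized tests compare the
incremental state against full recomputation, and every reported E = 0
genome passes an independent rescan of all circular windows.

## Protocells

Each of a fixed number of cells (default 50) runs the same growth-phase
kinetics on its own strand pool with monomer counts held at N₀ (membranes
permeable to monomers only; no strand exchange).  The functional reference
is a synthetic random 100-mer "ribozyme" — a stand-in with the documented
fragment structure, not a published sequence — split into five 20-mer
fragments plus five 20-mer splints, each splint complementary to the last
10 bases of one fragment and the first 10 of the next, closing a virtual
circle.  Cells start with 5 complete copies and 5 copies of each fragment
and splint (total length L_init = 1500).  N_rib counts complete
plus-orientation copies, including copies embedded in longer strands; it is
re-evaluated at the end of each cell's growth phase and sets the next
phase's rates: k_add·(1+N_rib) in polymerase mode, k_lig·(1+N_rib) in
ligase mode.  When a cell's total strand length reaches 2·L_init at the end
of a growth phase it divides (after melting): every strand goes
independently to one of two daughters, and a uniformly random cell other
than the two daughters is eliminated.  g(n) reports the fraction of
length-n strands whose sequence is still a contiguous (circular) substring
of the reference plus or minus sequence.

## What the generators do and do not emulate

The synthetic inputs reproduce the *structure* of the study conditions —
random oligomer pools with the stated length law, virtual-circle fragment
pools, and the fragment/splint assembly geometry — with uniform base
composition and no sequence-specific thermodynamics.  Passing tests
therefore demonstrate the model's combinatorial and kinetic behaviour
(scrambling, diversity conservation, assembly, loss under selection), not
agreement with any particular laboratory sequence; the scaled-experimental
rate table is the only empirically derived ingredient.

## Numerical choices and problem sizes

All stochastic draws flow through one seeded `numpy` generator per run
(sub-streams spawned per target in the acceptance script), making every
output bit-reproducible for a given seed.  Ties between simultaneously
eligible events are resolved only by the Gillespie draw.  Melting weights
are cached per helix length; monomer-dependent propensity terms are
vectorized over the ≤ 4^l₀ window words and refreshed only when monomer
counts change.  Cycling runs used for the headline checks are 100–120
cycles (diversity conservation, the k_ann = 0 ceiling) and 40 cycles for
the rank trends over k_add, k_nuc and k_ann — long enough for the ordering
of steady means to be stable at fixed seeds, chosen as the package's
standard reduced scales; a 500-cycle standard run reproduces the long-run
steady state (mean length ≈ 31) in a few minutes.  An optional hard length
cap (`length_cap`, default off) can emulate setups that truncate the
longest products.

## Known limitations

Wobble pairing, partial or mismatched annealing, helix fraying, dimer and
trimer primers, non-templated joining of strands inside the volume, and
any spatial or thermodynamic detail beyond the single ΔG/kT parameter are
not modelled.  The w = 6 repeat-free limit is bracketed only (the search
slows sharply); the 114 limit itself is an empirical search result, not a
theorem.  Protocell N_rib counts plus-strand copies only.
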