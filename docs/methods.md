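# Methods

## Model

An HP chain is a self-avoiding walk on the simple cubic lattice whose
beads carry types H or P. Two beads i, j are in contact when |i − j| > 1
and their sites are nearest neighbors; the energy is the sum of contact
energies ε(A_i, A_j). Defaults ε = (ε_HH, ε_HP, ε_PP) = (−10, −6, −3):
integer-valued (so the partition function is a polynomial), ordered
ε_HH < ε_HP < ε_PP with ε_HH + ε_PP < 2 ε_HP so hydrophobic collapse
dominates and H/P segregation is favored. Temperatures are reduced
(k_B = 1) and enter through x = e^(1/T).

## Exact enumeration and the counting convention

Conformations are counted with the first bond fixed to +x. Under the
cubic point group this weights each symmetry class by 1 (straight rod),
4 (planar), or 8 (three-dimensional), because a rod has 6 orientations,
a planar class 24, and a chiral 3-D class 48. Consequently a sequence
has a unique native structure exactly when n(E0) = 8, which is the
filter used by the 2^N sequence screen. Two traversal modes share one
depth-first kernel with incremental contact-energy bookkeeping:

- `fixed`: every walk with first step +x, weight 1;
- `symmetry` (default): one representative per class — first step +x,
  first non-x step +y, first out-of-plane step +z — carrying its 1/4/8
  weight. ~8× fewer leaves; both modes return identical counts (tested).

At N = 16 the pass visits ~4.4 × 10⁸ representatives (3,529,191,009
weighted walks) in seconds to minutes; several sequences of equal
length can be scored in the same pass since the conformation set is
sequence-independent. No pruning is applied: the full density of
states, not just the ground state, is required.

Counts are held in 64-bit integers; the largest tally (3.5 × 10⁹ at
N = 16) is far below overflow, and the Python layer converts to
arbitrary-precision integers.

## The sequence screen

The screen needs E0 and n(E0) for all 2^N sequences. One
symmetry-weighted pass records, per conformation, the *set* of contact
pairs as a bitmask over the feasible pair slots (|i − j| odd, ≥ 3; 49
slots at N = 16, so a mask fits one 64-bit word) in a hash table:
~1.8 × 10⁶ distinct signatures at N = 16. Each sequence's energy on a
signature is three popcounts against its induced HH/HP/PP pair masks.
Signatures are scanned densest-first and abandoned once ε_HH × contacts
cannot reach the running minimum. A per-sequence re-enumeration
fallback cross-checks the signature path at small N. The signature
table can be checkpointed so an interrupted screen restarts at the
cheap scoring stage.

## Zeros and heat-capacity decomposition

Roots of Z are seeded by double-precision companion-matrix eigenvalues
(`numpy.roots`) and polished by Newton iteration on the exact integer
polynomial at `precision` + 15 working digits (default precision 60;
the printed six-decimal temperatures require far less, but polishing is
cheap). Conjugate symmetry is enforced by pairing upper/lower
half-plane roots and averaging; near-real roots are snapped to the real
axis at tolerance 10^(−precision/2). Every root must pass a relative
residual bound |Z(x_k)| / (n(E0) · max(1, |x_k|)^M) < 10^(−precision/2),
and reconstruction/Vieta identities are asserted in tests; failures
fall back to mpmath's simultaneous root finder, and persistent failure
raises a convergence error advising higher precision.

C_V is computed two ways: directly from exact polynomial derivatives
(the variance form (ln x)² [x Z′/Z + x² Z″/Z − (x Z′/Z)²], evaluated in
50-digit arithmetic since x^M overflows doubles at low T), and as the
sum of per-zero components. The identity Σ_k C_V,k = C_V holds to
better than 10⁻⁶ relative on dense grids and is a standing test.
Component peaks are located on a 400-point geometric grid over
T ∈ [0.05, 50] and refined by bounded scalar minimization to ~10⁻⁹
relative; a component whose grid maximum sits on the range boundary is
flagged peakless rather than refined. Conjugate pairs are profiled once
with doubled height; lone negative-real roots singly.

### Band assignment (a genuinely open design point)

The zeros of a unique-ground-state 16-mer form an inner (collapse) ring
and an outer (folding) ring, sometimes with intermediate zeros between
them. No published rule delimits the rings, so the package makes the
rule explicit and records it in every report. The sorted moduli are
split at their largest multiplicative gap to separate the folding band
— every candidate sequence has a folding transition, and its ring can
be *diffuse*, so this split is unconditional (all-equal moduli remain a
single band). A middle band is split off only where the second-largest
gap exceeds `gap_factor` (default 1.08, configurable). A fixed
threshold applied to *both* splits was tried first and fails for
fast folders whose outer ring blends into the inner one (largest gap
≈ 1.065 for the fast-folding exemplar), leaving the folding temperature
undefined; the asymmetric rule reproduces all published six-decimal
temperatures and band counts.

Within a band the *first zero* is the root of minimal |arg x_k|; T_θ
and T_f are the peak temperatures of the collapse and folding first-zero
components, and σ = (T_θ − T_f)/T_θ.

### Crossover score and classification

The crossover score S is the largest peak height among components
(excluding the two first-zero components) peaking strictly inside
(T_f, T_θ), normalized by the folding component's peak height; S = 0 if
none exists. Group 2 (slow folder) when S ≥ `threshold` (default 0.5).
The published classification is explicitly qualitative, so S is the
primary, continuous output and the label is derived; both the threshold
and the gap factor are echoed into every report.

## Kinetic Monte Carlo

Rejection-free Gillespie dynamics with the restricted physical move
set: corner flips (interior bead with perpendicular bonds hops to the
free diagonal site) and 90° end flips (terminal bead to a free site
adjacent to its pivot, the 180° reversal excluded). Each event moves
one bead by a lattice diagonal. Rates are Metropolis,
W_i = min(1, e^(−ΔE/T)); the waiting time is −ln ξ / W_T with
W_T = Σ W_i and ξ uniform on (0, 1) (a raw zero is redrawn); the move
is chosen with probability W_i / W_T and the catalog is rebuilt after
every event. The attempt-frequency prefactor is fixed to 1, so times
are reduced; only ratios and curve shapes are compared. Forward and
reverse moves always coexist and their rate ratio is e^(−ΔE/T)
(detailed balance, tested).

First passage: trajectories start from the straight rod and stop when
the running energy first equals E0. Energy equality is equivalent to
native attainment because candidates have n(E0) = 8 — a unique
structure up to lattice symmetry — and energy is symmetry-invariant;
sequences without a unique ground state are refused. Runs exceeding
`max_events` (default 10⁸, never reached in practice on 16-mers at
T ≥ 3) are reported censored, never dropped silently. A trapped state
(empty catalog) raises an error; none has ever been observed with this
move set at N = 16.

Randomness comes from an explicit xoshiro256++ generator seeded via
splitmix64 from (base seed, temperature index, run index), so sweeps
are reproducible, order-independent, and bit-identical across
platforms. The compiled trajectory kernel is cross-checked against a
pure-Python move generator, and an optional in-kernel audit recomputes
the total energy every k events.

## Problem sizes

The published mean-first-passage curves use 10,000 trajectories per
grid temperature with ~1% relative error. This package's default test
and reproduction runs use 64 and 96 trajectories per point
respectively — enough to resolve the U-shape and locate its optimum to
one 0.5-wide grid step (means carry ~10% standard errors at this size).
Anyone wanting the published precision can pass `runs=10000`; a full
two-sequence sweep then takes a few CPU-hours.

## Synthetic and reference inputs

All inputs are generated or embedded: HP sequences are plain strings,
small-N reference densities of states come from a deliberately naive
enumerator (no symmetry weighting, energies recomputed per walk) that
serves as the oracle for the production kernel, toy polynomials with
closed-form roots exercise the zero finder, and the twenty published
16-mer reference rows are embedded as a machine-readable table (one
known typo in the published row 20 is documented in the module). What
the small-N oracle cannot exercise — the sheer scale of the N = 16
conformation set — is covered by exact invariants instead: the
sequence-independent total count, mode equivalence, and the published
ground-state energies and temperatures themselves.

## Known limitations

- Exhaustive enumeration is exponential in N; N = 16 is comfortable,
  N ≳ 20 is not. Stochastic density-of-states estimation is out of
  scope.
- The band rule and crossover threshold are explicit stand-ins for a
  judgment the source figures made by eye; both are configurable and
  recorded, and the continuous score should be preferred to the label
  near the threshold.
- The screen's signature table holds every distinct contact set in
  memory (~2 × 10⁶ entries at N = 16, growing steeply with N).
- Ergodicity of corner+end flips at N = 16 is supported empirically
  (every run reaches the native state); it is not proven, and a trapped
  state would surface as an explicit error.
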