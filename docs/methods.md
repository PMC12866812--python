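# Methods

This note documents the models implemented in `dnastore`, the defaults they
ship with, and the design choices made where the problem left room.

## Codec family

An `R_N-B#` rule encodes a payload in three steps: (i) prepend a guard
1-bit and read the bit string as a big integer (most significant bit
first); (ii) rewrite the integer in radix `#`, most significant digit
first; (iii) emit the initiator unit, then one unit per digit, looked up in
the table row of the current *context* — the last emitted base. The
decoder inverts each step; because each row is a bijection and the context
is reconstructible from the emitted bases, decoding is exact.

**Guard bit.** Without it, leading payload zeros would vanish in the
integer round trip. It also pins the integer's magnitude, so the digit
count — hence encoded length — depends only on the payload bit length at
the payload sizes of interest (16384 bits: 4097 base-16 digits, 8193
base-4, 5169 base-9, 10338 base-3, 4571 base-12). At arbitrary lengths a
radix boundary can fall between the all-zero and all-one extremes; the
length guarantee is stated for the canonical payload size.

**Constraint enforcement.** Run-length limits are properties of the unit
sets, not of a scan: R1-B12 admits only non-homodimers (no run can exceed
2 nt however units abut), R0-B9 additionally forbids units starting with
the context base, R0-B3 forbids the context monomer. Table validation
checks each unit against its context, so user-supplied overrides cannot
silently break the guarantee.

**Digit→unit tables.** The randomization of a rule lives entirely in the
digit→unit assignment. A lexicographic assignment for B16 would be the
identity map (base-16 digits are nibbles; lexicographically ordered dimers
are bit pairs), reducing R∞-B16 to simple mapping and leaving payload
structure intact — defeating the purpose of the rule. The shipped defaults
therefore scramble every context row with a fixed permutation seeded from
`crc32("dnastore:<scheme>:<context>")`: arbitrary, but fully deterministic
and documented. R∞-B4 is the exception: its five worked-example
assignments (context A: 3→C; C: 1→G, 2→C; G: 3→T; T: 0→G) are pinned and
the remainder fills lexicographically. Alternative tables load bit-exactly
from JSON via `build_rule_table(..., overrides=...)` or `RuleTable.load`.

**Initiators** default to `AT` (dimer schemes) and `A` (monomer schemes);
the start context is the initiator's last base. Initiators are arbitrary
and configurable; they add 2 or 1 nt to every encoded length.

**Strands.** Payload sequences are cut into 57-nt chunks and wrapped as
`forward primer (20 nt) + index (8 nt) + payload + reverse primer (21 nt)`,
106 nt when full. The index is the strand ordinal as a 16-bit big-endian
integer passed through the 2-bit map — the layout fixes the primers but
not the index encoding, so this is this package's convention, documented
here. `sequence_identity` compares positionally (the layout is fixed, no
alignment), returns `100 × matches / max(len)`, and counts a length
difference as errors. Note the quantity is a match fraction: the
experimental convention it mirrors divides *errors* by length yet reports
the result as an identity of 95–98%, which is only consistent with the
match-fraction reading used here.

## Translational trajectory model

Deterministic map: base → unit step (A = (L,0), C = (0,L), G = (−L,0),
T = (0,−L)), one step per nt, origin prepended; L = 1 internally. The MSD
at lag Δn ∈ {1..20} averages the squared displacement over windows that
start every `stride = 1` nt; with the canonical 8020-nt analysis prefix
and 20-nt windows, `n_windows = 8000` (8001 would fit; the first 8000 are
used, keeping the canonical count). The curve is fitted to
`4D·Δn + V²·Δn²` by non-negative least squares (`scipy.optimize.nnls`) on
the basis {Δn, Δn²}, so `V = √(quadratic coefficient)` is always real;
`nonneg=False` exposes a plain least-squares variant with clipping at
zero. Ballistic (`MSD = Δn²`) and diffusive (`MSD = Δn`) closed forms are
recovered to machine precision: V = 1, D = 0 and V = 0, D = 1/4.

## Rotational trajectory model

Bases occupy the cube vertices in antipodal pairs — A: ±(1,1,1),
C: ±(−1,1,1), G: ±(1,−1,1), T: ±(1,1,−1) — the unique antipodal
4-labeling up to rotation; every vertex's three neighbors carry the three
other bases, so "move to the adjacent vertex with the next base" is well
defined. The first base places the particle at its upper-plane (z = +1)
vertex at time 0; each later base either parks the particle (repeated
base: zero angular increment, time still advances) or slides it along one
edge. An edge move flips one coordinate and advances the azimuth of the
position by ±π/2 in the two planes containing that coordinate's axis —
e.g. A→C flips x and rotates about Y and Z. Per-axis cumulative angles are
windowed exactly like the MSD (an 8020-nt sequence has 8019 moves and
yields exactly 8000 windows) and fitted to `2D_R·Δn + ω²·Δn²`; total ω and
D_R are Euclidean norms of the per-axis values. A pure ATGC repeat
circulates one cube face, giving one exactly ballistic axis
(`MSAD = (π/2)²Δn²`, fitted ω = π/2); which named axis carries it depends
on the (conventional) labeling, so tests assert "exactly one axis", not an
axis name.

## Inverse Ising factors

The sequence is turned into bits by the 2-bit map and the first `n·m` bits
(default 128×128; an 8196-nt sequence yields 16392 bits, 8 discarded) form
a ±1 spin lattice on the 4-connected grid. With `N_T` nodes, `N_n` edges
and mean spin γ = Σσ/N_T:

* interaction factor: `λ = (⟨σσ⟩ − γ²) / (1 − γ²)²`, the first-order
  small-correlation (independent-pair) inversion of `C ≈ (1−m²)J(1−m²)`
  for a uniform coupling;
* bias factor: `h = atanh(γ) − z·λ·γ` with mean coordination
  `z = 2N_n/N_T`, the mean-field self-consistency `m = tanh(h + zλm)`
  solved for the field.

On the canonical 2×2 example [1,0;0,0] (Σσ = −2, Σσσ = 0, N_n = 4,
N_t = 8) these give γ = −1/2, λ = −(1/4)/(9/16) = −4/9 ≈ −0.444 and
h ≈ −0.994; these values are pinned as regression fixtures. λ is signed
(negative = anticorrelated neighbors); comparisons across schemes use
|λ|. The touching-connection count `N_t = 12(N−1)(M−1) − 4` equals the
number of ordered pairs of distinct edges sharing a node
(Σ_v d_v(d_v − 1)); it is carried in `SpinSums` for completeness but the
shipped closed forms do not need it. A fully polarized lattice
(γ = ±1) returns λ = 0 and h = ±∞ by convention. The inversion is
pluggable (`ising_params(sums, interaction_bias=...)`) so an alternative
formula can be swapped in without touching callers.

This is deliberately *not* a general inverse-Ising solver (no Boltzmann
learning or pseudolikelihood): the factors are closed-form summaries for
randomness assessment.

## Logic statistics

Inputs are horizontal bit triplets `(r, c..c+2)`, output the bit at
`(r+1, c+1)`; the measurable region has exactly `(n−1)(m−2)` evaluations
(72 for 10×10). α(input) = N₀/(N₀+N₁), β(input) = (N₀+N₁)/Σ(N₀+N₁).
RMS summaries are deviations about the ideal values 0.5 and 0.125 — the
reading under which "lower RMS = more random" is coherent — with the
literal `√mean(x²)` variant behind `about_zero=True`. Inputs that never
occur have undefined α and are excluded from RMS(α); their β = 0 is
included in RMS(β).

## Synthetic data

Test payloads are (i) elementary-cellular-automaton pattern images
(Wolfram rule numbering, circular boundary — the boundary choice is ours;
row 0 is a seeded uniform random row or a single centered 1) and (ii)
seeded uniform random bit strings. The ECA images emulate the structured,
low-entropy payloads (large uniform regions → long homopolymer runs under
simple mapping) that make the codec comparison meaningful; random bits
emulate incompressible payloads. Neither reproduces the pixel content of
any particular photograph, and none of the synthetic inputs exercises
synthesis/sequencing error processes — passing tests show the codecs'
combinatorial guarantees and the models' discriminative behaviour, not
wet-lab decoding fidelity.

## Problem sizes and numerics

Analyses use the canonical sizes throughout: 16384-bit payloads, 8020-nt
trajectory prefixes with 20-nt windows and 8000 windows, 128×128 lattices.
The test suite runs the same sizes (the full 256-rule ECA oracle check
runs at 8×8; fuzzed round-trip payloads span 1–2048 bits). Fits are exact
on their closed-form inputs; NNLS is deterministic; all randomness is
seeded, so every reported number is bit-reproducible.

## Known limitations

* The shipped digit→unit tables are canonical reconstructions, not a
  transcription of any published table; sequences are therefore
  scheme-compatible but not byte-identical to externally generated ones
  (load such tables via JSON overrides for that).
* `sequence_identity` is positional; it is not meaningful for reads with
  indels.
* The rotational model's axis names are conventional (see above).
* Encoding/decoding is O(payload) Python with big-integer radix
  conversion; fine for the ~16-kbit payloads it targets, not tuned for
  megabyte payloads.
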