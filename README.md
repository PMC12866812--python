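# dnastore

Run-length-constrained DNA data-storage codecs with physics-based
sequence-randomness assessment.

DNA is an attractive medium for archival digital storage, but naive
bit-to-base mappings inherit every bias of the payload: long homopolymer
runs and skewed GC content destabilize synthesis, PCR and sequencing, and
degrade decoding accuracy. `dnastore` implements a family of randomized,
run-length-limited design rules `R_N-B#` that convert a binary payload into
a constrained DNA sequence, plus three physical models that *quantify* how
random the resulting sequence actually is. It is aimed at people designing
or evaluating DNA storage codecs: encode a payload, decode it back
losslessly, package it into sequencing-ready strands, and score any
sequence's randomness with interpretable physical parameters.

## The codecs

*Simple mapping* converts bit pairs positionally (00→A, 01→C, 10→G, 11→T):
2 bits/nt, but payload structure passes straight through into the DNA.

An `R_N-B#` rule instead reads the payload (with a leading guard 1-bit) as
one big integer, rewrites it in radix `#`, and emits one nucleotide
monomer or dimer per digit, chosen from a context-dependent table keyed on
the last emitted base. `N` is the maximum homopolymer run length the rule
can emit:

| rule     | unit  | radix | max run | encoded length of 16384 bits |
|----------|-------|-------|---------|------------------------------|
| simple   | —     | —     | ∞       | 8192 nt                      |
| R∞-B16   | dimer | 16    | ∞       | 8196 nt                      |
| R∞-B4    | mono  | 4     | ∞       | 8194 nt                      |
| R1-B12   | dimer | 12    | 2 nt    | 9144 nt                      |
| R0-B9    | dimer | 9     | 1 nt    | 10340 nt                     |
| R0-B3    | mono  | 3     | 1 nt    | 10339 nt                     |

R0-B9, for example, allows only the 9 non-homodimers that do not start
with the previous base, so the output provably never repeats a base — at
the cost of ~1.58 instead of 2 bits/nt.

## The randomness models

* **Active-particle trajectories.** Each base is a unit step in the plane
  (A = (L,0), C = (0,L), G = (−L,0), T = (0,−L)); the mean squared
  displacement over sliding 20-nt windows is fitted to
  `⟨(Δr)²⟩ = 4D·Δn + V²·Δn²`. Velocity `V` exposes homopolymer-driven
  ballistic bias, `D` the diffusive randomness. A rotational variant walks
  the cube whose vertices carry the bases in antipodal pairs and fits
  `⟨(Δθ)²⟩ = 2D_R·Δn + ω²·Δn²` per axis; periodic 4-base repeats show up
  as steady rotation (large ω).
* **Inverse Ising factors.** The sequence's bit lattice (via the 2-bit
  map, reshaped 128×128) is summarized by the polarization factor
  γ = Σσ/N_T, the nearest-neighbor interaction factor
  λ = (⟨σσ⟩ − γ²)/(1 − γ²)² and the bias factor
  h = atanh(γ) − (2N_n/N_T)·λ·γ. Random lattices give γ, λ, h ≈ 0;
  clustering inflates |λ|, bit imbalance inflates |γ| and |h|.
* **3-input/1-output logic statistics.** Every horizontal bit triplet is an
  input whose output is the bit below its center; α(input) is the
  zero-output ratio (ideal 1/2) and β(input) the input occurrence fraction
  (ideal 1/8). RMS deviations from the ideals summarize matrix randomness.

## Worked example

```python
>>> import dnastore as ds
>>> bits = ds.flatten(ds.eca_matrix(182, 128, 128, init="center"))  # a 128x128 pattern image
>>> seq = ds.encode(bits, "R0-B9")
>>> len(seq), ds.gc_ratio(seq), ds.longest_homopolymer(seq)
(10340, 0.5007, 1)
>>> ds.decode(seq, "R0-B9") == bits
True
>>> strands = ds.assemble_strands(seq)     # 106-nt sequencing-ready strands
>>> len(strands), len(strands[0])
(182, 106)
```

The 16384-bit image encodes to 10340 nt with balanced GC (0.5007) and no
homopolymers, and splits into 182 strands of at most 106 nt. The same
payload through simple mapping is 8192 nt but carries a 64-nt homopolymer
run and a strongly biased trajectory:

```python
>>> from dnastore import apt
>>> apt.fit_translational(apt.msd_curve(seq[:8020])).V            # R0-B9
0.0
>>> simple = ds.encode(bits, "simple")
>>> round(apt.fit_translational(apt.msd_curve(simple[:8020])).V, 4)
0.7653
```

`V = 0` says the constrained sequence moves like a pure random walk;
`V ≈ 0.77 L/nt` says simple mapping is dominated by self-propelled,
homopolymer-driven motion. The `dnastore` CLI wraps the same pipeline
(`dnastore encode`, `decode`, `strands`, `stats`, `identity`,
`assess apt|ising|logic3|all`, `report`).

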