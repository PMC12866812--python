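"""Inverse-Ising randomness factors for bit matrices derived from DNA.

An encoded sequence is turned back into bits by the 2-bit positional map
(A→00, C→01, G→10, T→11), the first ``n·m`` bits are reshaped into an
``n×m`` lattice, and each bit becomes a spin: 1 ↦ +1 (up), 0 ↦ −1 (down).
Three scalar factors summarize the lattice as an inverse Ising problem on
the 4-connected nearest-neighbor graph:

polarization factor γ ∈ [−1, 1]
    ``γ = (Σᵢ σᵢ) / N_T`` — the mean spin; which bit dominates, and by how
    much.  A well-randomized sequence gives γ ≈ 0.

interaction factor λ ∈ [−1, ∞)
    The uniform nearest-neighbor coupling recovered from the lattice by the
    first-order small-correlation (independent-pair) inversion
    ``C ≈ (1 − m²)·λ·(1 − m²)``, i.e.

        λ = (⟨σᵢσⱼ⟩ − γ²) / (1 − γ²)²,

    with ⟨σᵢσⱼ⟩ = (Σ_{⟨i,j⟩} σᵢσⱼ)/N_n the mean nearest-neighbor product.
    Positive λ means like bits cluster, negative λ means they alternate,
    λ ≈ 0 means a well-mixed lattice.

bias factor h ∈ (−∞, ∞)
    The external field recovered from the mean-field self-consistency
    ``m = tanh(h + z·λ·m)`` with mean coordination ``z = 2·N_n/N_T``:

        h = atanh(γ) − z·λ·γ.

The lattice bookkeeping counts are ``N_T = N·M`` nodes,
``N_n = (N−1)·M + (M−1)·N`` node connections, and
``N_t = 12·(N−1)·(M−1) − 4`` touching node connections (ordered pairs of
distinct edges sharing a node, ``Σ_v d_v(d_v−1)``).

On the worked 2×2 lattice [1,0;0,0] these formulas give γ = −0.5,
λ = −1/4 ÷ 9/16 = −4/9 ≈ −0.444 and h ≈ −0.994.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import fixtures
from .codec import simple_unmap
from .errors import InsufficientDataError

__all__ = ["SpinSums", "IsingParams", "to_spin_matrix", "spin_sums", "ising_params"]


@dataclass(frozen=True)
class SpinSums:
    """Raw spin and pair sums plus the lattice counts they are normalized by."""

    sum_spin: int          # Σᵢ σᵢ
    sum_pair: int          # Σ_{⟨i,j⟩} σᵢσⱼ over unordered 4-neighbor pairs
    n_t: int               # N_T: total nodes
    n_n: int               # N_n: node connections (lattice edges)
    n_touch: int           # N_t: touching node connections

    def __post_init__(self) -> None:
        if abs(self.sum_spin) > self.n_t or abs(self.sum_pair) > self.n_n:
            raise InsufficientDataError("spin sums inconsistent with lattice counts")


@dataclass(frozen=True)
class IsingParams:
    gamma: float
    lam: float
    h: float


def to_spin_matrix(seq: str, n_rows: int = 128, n_cols: int = 128) -> np.ndarray:
    """Bit lattice of a sequence: 2-bit unmap, keep the first n·m bits.

    Returned as a 0/1 matrix; 1 means spin up.  An 8196-nt sequence yields
    16392 bits of which the first 16384 fill a 128×128 lattice.
    """
    bits = simple_unmap(seq)
    return fixtures.reshape(bits, n_rows, n_cols)


def spin_sums(matrix) -> SpinSums:
    """Spin sum, nearest-neighbor pair sum, and lattice counts of a bit matrix."""
    m = np.asarray(matrix, dtype=np.int64)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise InsufficientDataError("spin lattice must be at least 2x2")
    n, cols = m.shape
    s = 2 * m - 1
    sum_pair = int((s[:-1] * s[1:]).sum() + (s[:, :-1] * s[:, 1:]).sum())
    return SpinSums(
        sum_spin=int(s.sum()),
        sum_pair=sum_pair,
        n_t=n * cols,
        n_n=(n - 1) * cols + (cols - 1) * n,
        n_touch=12 * (n - 1) * (cols - 1) - 4,
    )


def _interaction_bias(sums: SpinSums, gamma: float) -> tuple[float, float]:
    """Default λ/h closed forms (small-correlation + mean-field inversion)."""
    mean_pair = sums.sum_pair / sums.n_n
    var = 1.0 - gamma * gamma
    if var == 0.0:  # fully polarized lattice: coupling indeterminate, field saturates
        return 0.0, math.copysign(math.inf, gamma)
    lam = (mean_pair - gamma * gamma) / (var * var)
    z = 2.0 * sums.n_n / sums.n_t
    h = math.atanh(gamma) - z * lam * gamma
    return lam, h


def ising_params(
    sums: SpinSums,
    interaction_bias: Callable[[SpinSums, float], tuple[float, float]] | None = None,
) -> IsingParams:
    """Compute (γ, λ, h) from spin sums.

    ``γ = sum_spin / N_T`` exactly; λ and h come from ``interaction_bias``
    (default: the closed forms in the module docstring), kept pluggable so
    an alternative inversion can be swapped in without touching callers.
    """
    gamma = sums.sum_spin / sums.n_t
    lam, h = (interaction_bias or _interaction_bias)(sums, gamma)
    return IsingParams(gamma=gamma, lam=lam, h=h)


def assess(seq: str, n_rows: int = 128, n_cols: int = 128) -> tuple[SpinSums, IsingParams]:
    """Full pipeline: sequence → spin lattice → sums → (γ, λ, h)."""
    sums = spin_sums(to_spin_matrix(seq, n_rows, n_cols))
    return sums, ising_params(sums)
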