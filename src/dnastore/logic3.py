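"""3-input/1-output logic statistics of a bit matrix.

Every horizontal bit triplet of a matrix row is read as a 3-bit input
(000..111) whose output is the bit directly below the triplet's center in
the next row.  Over the *measurable* region — rows 0..n−2 crossed with
triplet starts 0..m−3, hence (n−1)·(m−2) input/output pairs — two per-input
statistics are collected:

    α(i) = N₀(i) / (N₀(i) + N₁(i))      zero-output ratio of input i
    β(i) = (N₀(i) + N₁(i)) / Σ(N₀+N₁)   occurrence fraction of input i

For a perfectly random matrix every α → 1/2 and every β → 1/8, so the RMS
deviations √mean((α−0.5)²) and √mean((β−0.125)²) summarize how far the
matrix is from ideal randomness (lower = more random).  Inputs that never
occur have no α and are excluded from RMS(α); their β = 0 is included in
RMS(β).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError

__all__ = ["LogicStats", "logic_stats", "INPUT_LABELS"]

INPUT_LABELS = tuple(format(i, "03b") for i in range(8))

ALPHA_EXPECTED = 0.5
BETA_EXPECTED = 0.125


@dataclass(frozen=True)
class LogicStats:
    """Per-input counts and ratios with RMS summaries.

    ``alpha`` is NaN for inputs that never occur.  ``rms_alpha`` and
    ``rms_beta`` are deviations about the random-matrix expectations (0.5
    and 0.125) unless built with ``about_zero=True``, in which case they
    are the literal root mean squares.
    """

    n0: np.ndarray
    n1: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    rms_alpha: float
    rms_beta: float

    @property
    def n_evaluations(self) -> int:
        return int(self.n0.sum() + self.n1.sum())


def logic_stats(matrix, about_zero: bool = False) -> LogicStats:
    """Scan a bit matrix and compute the α/β logic statistics.

    Requires at least 2 rows and 3 columns.  The evaluation count is
    exactly ``(n_rows − 1)·(n_cols − 2)`` — 72 for a 10×10 matrix.
    """
    m = np.asarray(matrix, dtype=np.int64)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 3:
        raise InsufficientDataError("logic scan needs a matrix of at least 2x3")
    inputs = 4 * m[:-1, :-2] + 2 * m[:-1, 1:-1] + m[:-1, 2:]
    outputs = m[1:, 1:-1]
    counts = np.bincount((2 * inputs + outputs).ravel(), minlength=16)
    n0 = counts[0::2].astype(np.int64)
    n1 = counts[1::2].astype(np.int64)
    totals = n0 + n1
    with np.errstate(invalid="ignore"):
        alpha = np.where(totals > 0, n0 / np.where(totals > 0, totals, 1), np.nan)
    beta = totals / totals.sum()
    if about_zero:
        rms_alpha = float(np.sqrt(np.nanmean(alpha**2)))
        rms_beta = float(np.sqrt(np.mean(beta**2)))
    else:
        rms_alpha = float(np.sqrt(np.nanmean((alpha - ALPHA_EXPECTED) ** 2)))
        rms_beta = float(np.sqrt(np.mean((beta - BETA_EXPECTED) ** 2)))
    return LogicStats(n0=n0, n1=n1, alpha=alpha, beta=beta,
                      rms_alpha=rms_alpha, rms_beta=rms_beta)
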