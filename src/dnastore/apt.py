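"""Active-particle trajectory models for sequence-randomness assessment.

A DNA sequence is read as the itinerary of a self-propelled particle, one
base per unit time step (1 nt).

Translational (2D) model
    Each base is a unit step: A = (L, 0), C = (0, L), G = (−L, 0),
    T = (0, −L).  Homopolymer stretches push the particle ballistically in
    one direction; a well-randomized sequence performs a lattice random
    walk.  The mean squared displacement over short lags obeys
    ``⟨(Δr)²⟩ = 4·D·Δn + V²·Δn²``, so fitting the MSD curve on the basis
    {Δn, Δn²} yields a velocity V (directional bias, units L/nt) and a
    diffusion coefficient D (units L²/nt).

Rotational (3D) model
    The four bases sit in antipodal pairs on the vertices of a cube; the
    particle starts at the first base's vertex in the upper (z = +1) plane
    and, per step, either stays put (repeated base) or slides along the
    unique edge to the vertex carrying the next base.  Each edge move
    advances the particle's angular position by ±π/2 about exactly two of
    the coordinate axes.  Periodic 4-base repeats circulate around one cube
    face — steady rotation about one axis — while random sequences perform
    an angular random walk.  The per-axis mean squared angular displacement
    obeys ``⟨(Δθ)²⟩ = 2·D_R·Δn + ω²·Δn²``; total ω and D_R are the
    Euclidean norms of the per-axis fits.

Both models slide a 20-nt window along the sequence with 1-nt stride
(19-nt overlap) and average the squared (angular) displacement over a fixed
number of windows, 8000 by default, so an 8020-nt input is the canonical
analysis length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .errors import AlphabetError, InsufficientDataError

__all__ = [
    "trajectory2d",
    "trajectory3d",
    "msd_curve",
    "msad_curves",
    "fit_translational",
    "fit_rotational",
    "MSDCurve",
    "TranslationalFit",
    "RotationalFit",
    "CUBE_VERTEX_UPPER",
    "VERTEX_BASE",
]

_STEPS = {"A": (1, 0), "C": (0, 1), "G": (-1, 0), "T": (0, -1)}

# Antipodal base→vertex labeling of the cube (the unique such labeling up to
# rotation).  Every vertex's three neighbors carry the three other bases, so
# the "slide to the adjacent vertex with the next base" move is well defined.
CUBE_VERTEX_UPPER = {
    "A": (1, 1, 1),
    "C": (-1, 1, 1),
    "G": (1, -1, 1),
    "T": (-1, -1, 1),
}
VERTEX_BASE = {}
for _b, _v in CUBE_VERTEX_UPPER.items():
    VERTEX_BASE[_v] = _b
    VERTEX_BASE[tuple(-c for c in _v)] = _b


@dataclass
class MSDCurve:
    """Mean squared (angular) displacement per lag Δn = 1..window."""

    lags: np.ndarray
    values: np.ndarray
    window: int
    stride: int
    n_windows: int


@dataclass
class TranslationalFit:
    """MSD fit ⟨(Δr)²⟩ = 4·D·Δn + V²·Δn²; V in L/nt, D in L²/nt."""

    V: float
    D: float
    residual: float


@dataclass
class RotationalFit:
    """Per-axis MSAD fits ⟨(Δθ)²⟩ = 2·D_R·Δn + ω²·Δn² and their magnitudes."""

    omega_axis: tuple[float, float, float]
    dr_axis: tuple[float, float, float]
    omega: float
    d_r: float
    residual: float


def _check_seq(seq: str) -> None:
    if not seq:
        raise AlphabetError("sequence must be non-empty")
    if set(seq) - set("ACGT"):
        bad = next(c for c in seq if c not in "ACGT")
        raise AlphabetError(f"invalid base {bad!r}")


def trajectory2d(seq: str) -> np.ndarray:
    """Positions (len+1, 2) in units of L, step 0 at the origin."""
    _check_seq(seq)
    steps = np.array([_STEPS[b] for b in seq], dtype=np.int64)
    pos = np.zeros((len(seq) + 1, 2), dtype=np.int64)
    np.cumsum(steps, axis=0, out=pos[1:])
    return pos


def trajectory3d(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Cube-vertex path and cumulative per-axis angles of the rotational model.

    The first base places the particle at its upper-plane vertex (time 0);
    each of the remaining ``len−1`` bases is one time step, so an ``n``-nt
    sequence yields ``n`` time points.  Returns ``(vertices, angles)``:
    vertices is (n, 3) over {−1, +1}³ and angles is (n, 3) cumulative
    signed radians about the X, Y, Z axes.  A repeated base leaves both the
    vertex and all angles unchanged for that step — the particle is parked.

    The per-axis increment for a move is the change of the position's
    azimuth in the plane perpendicular to that axis; because an edge move
    flips exactly one coordinate, it is ±π/2 about two axes and 0 about the
    axis of the flipped coordinate.
    """
    _check_seq(seq)
    n = len(seq)
    vertices = np.empty((n, 3), dtype=np.int64)
    angles = np.zeros((n, 3), dtype=np.float64)
    current = CUBE_VERTEX_UPPER[seq[0]]
    vertices[0] = current
    current_base = seq[0]
    # azimuth pairs: about X use (y, z); about Y use (z, x); about Z use (x, y)
    planes = ((1, 2), (2, 0), (0, 1))
    for t, base in enumerate(seq[1:], start=1):
        if base == current_base:
            vertices[t] = current
            angles[t] = angles[t - 1]
            continue
        nxt = None
        for axis in range(3):
            cand = list(current)
            cand[axis] = -cand[axis]
            cand_t = tuple(cand)
            if VERTEX_BASE[cand_t] == base:
                nxt = cand_t
                break
        assert nxt is not None  # guaranteed by the antipodal labeling
        angles[t] = angles[t - 1]
        for ax, (u, v) in enumerate(planes):
            before = math.atan2(current[v], current[u])
            after = math.atan2(nxt[v], nxt[u])
            delta = after - before
            if delta > math.pi:
                delta -= 2 * math.pi
            elif delta < -math.pi:
                delta += 2 * math.pi
            angles[t, ax] += delta
        vertices[t] = nxt
        current, current_base = nxt, base
    return vertices, angles


def _window_count(n_points: int, window: int, stride: int, n_windows: int) -> int:
    """Number of windows a series of ``n_points`` time points supports."""
    if n_points - 1 < window:
        raise InsufficientDataError(
            f"series of {n_points - 1} steps is shorter than the {window}-nt window"
        )
    available = (n_points - 1 - window) // stride + 1
    return min(n_windows, available)


def _msd_of_series(series: np.ndarray, window: int, stride: int, n_windows: int) -> np.ndarray:
    """Mean over windows of squared displacement of a cumulative series.

    ``series`` has one entry per time point (len n_steps+1, any number of
    components); window k starts at time offset k·stride and its lag-Δn
    displacement is ``series[k·stride + Δn] − series[k·stride]``.
    """
    starts = np.arange(n_windows) * stride
    out = np.empty(window, dtype=np.float64)
    base = series[starts]
    for i, lag in enumerate(range(1, window + 1)):
        disp = series[starts + lag] - base
        if disp.ndim == 1:
            out[i] = np.mean(disp * disp)
        else:
            out[i] = np.mean(np.sum(disp * disp, axis=1))
    return out


def msd_curve(seq: str, window: int = 20, stride: int = 1, n_windows: int = 8000) -> MSDCurve:
    """Translational MSD over sliding windows.

    If the sequence supports fewer than ``n_windows`` windows the count is
    reduced to the maximum available; if it supports more, only the first
    ``n_windows`` are used (an 8020-nt sequence admits 8001 but the
    canonical analysis takes 8000).
    """
    _check_seq(seq)
    pos = trajectory2d(seq).astype(np.float64)
    used = _window_count(len(pos), window, stride, n_windows)
    values = _msd_of_series(pos, window, stride, used)
    return MSDCurve(np.arange(1, window + 1), values, window, stride, used)


def msad_curves(
    seq: str, window: int = 20, stride: int = 1, n_windows: int = 8000
) -> tuple[MSDCurve, MSDCurve, MSDCurve]:
    """Per-axis (X, Y, Z) mean squared angular displacement curves."""
    _check_seq(seq)
    _, angles = trajectory3d(seq)
    used = _window_count(len(angles), window, stride, n_windows)
    lags = np.arange(1, window + 1)
    curves = []
    for ax in range(3):
        values = _msd_of_series(angles[:, ax], window, stride, used)
        curves.append(MSDCurve(lags, values, window, stride, used))
    return tuple(curves)


def _fit_linear_quadratic(
    lags: np.ndarray, values: np.ndarray, nonneg: bool
) -> tuple[float, float, float]:
    """Least-squares coefficients (a, b) of a·Δn + b·Δn² with b ≥ 0 for √b."""
    A = np.column_stack([lags, lags.astype(np.float64) ** 2])
    if nonneg:
        coef, residual = nnls(A, values)
        return float(coef[0]), float(coef[1]), float(residual)
    coef, *_ = np.linalg.lstsq(A, values, rcond=None)
    residual = float(np.linalg.norm(A @ coef - values))
    return float(max(coef[0], 0.0)), float(max(coef[1], 0.0)), residual


def fit_translational(curve: MSDCurve, nonneg: bool = True) -> TranslationalFit:
    """Fit ⟨(Δr)²⟩ = 4·D·Δn + V²·Δn²: V = √(quadratic), D = linear / 4.

    Non-negative least squares by default so that V is real; with
    ``nonneg=False`` plain least squares is used and negative coefficients
    are clipped at zero.
    """
    if len(curve.lags) < 2:
        raise InsufficientDataError("need at least two MSD points to fit")
    a, b, residual = _fit_linear_quadratic(curve.lags, curve.values, nonneg)
    return TranslationalFit(V=math.sqrt(b), D=a / 4.0, residual=residual)


def fit_rotational(curves, nonneg: bool = True) -> RotationalFit:
    """Per-axis fit ⟨(Δθ)²⟩ = 2·D_R·Δn + ω²·Δn²; magnitudes are Euclidean norms."""
    if len(curves) != 3:
        raise InsufficientDataError("rotational fit needs the three per-axis curves")
    omega_axis, dr_axis, residuals = [], [], []
    for curve in curves:
        if len(curve.lags) < 2:
            raise InsufficientDataError("need at least two MSAD points to fit")
        a, b, res = _fit_linear_quadratic(curve.lags, curve.values, nonneg)
        omega_axis.append(math.sqrt(b))
        dr_axis.append(a / 2.0)
        residuals.append(res)
    return RotationalFit(
        omega_axis=tuple(omega_axis),
        dr_axis=tuple(dr_axis),
        omega=float(np.linalg.norm(omega_axis)),
        d_r=float(np.linalg.norm(dr_axis)),
        residual=float(np.linalg.norm(residuals)),
    )


def write_trajectory_tsv(seq: str, path) -> None:
    """Step-by-step 2D positions and 3D vertex/angle table."""
    pos = trajectory2d(seq)
    vertices, angles = trajectory3d(seq)
    with open(path, "w") as fh:
        fh.write("step\tx\ty\tvx\tvy\tvz\ttheta_x\ttheta_y\ttheta_z\n")
        for t in range(len(seq) + 1):
            row = f"{t}\t{pos[t,0]}\t{pos[t,1]}"
            if t < len(vertices):  # 3D clock starts at the first base
                row += (
                    f"\t{vertices[t,0]}\t{vertices[t,1]}\t{vertices[t,2]}"
                    f"\t{angles[t,0]:.6f}\t{angles[t,1]:.6f}\t{angles[t,2]:.6f}"
                )
            else:
                row += "\t" * 6
            fh.write(row + "\n")


def write_curves_tsv(curve: MSDCurve, msad, path) -> None:
    """Lag table: Δn, MSD, MSAD per axis."""
    with open(path, "w") as fh:
        fh.write("lag\tmsd\tmsad_x\tmsad_y\tmsad_z\n")
        for i, lag in enumerate(curve.lags):
            fh.write(
                f"{int(lag)}\t{curve.values[i]:.8f}\t{msad[0].values[i]:.8f}"
                f"\t{msad[1].values[i]:.8f}\t{msad[2].values[i]:.8f}\n"
            )
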