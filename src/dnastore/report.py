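"""Cross-scheme assessment reports.

``assess_all`` runs one payload through every requested encoding scheme and
all three physics-based randomness models, collecting the comparison surface
(length, information density, GC ratio, longest homopolymer, V, D, ω, D_R,
γ, λ, h, RMS(α), RMS(β)) into one deterministic JSON-serializable dict.
"""

from __future__ import annotations

import math
from typing import Sequence

from . import apt, codec, ising, logic3, seqstats
from .errors import FormatError

#: analysis defaults: 20-nt windows slid 1 nt at a time over the first
#: 8020 nt, 8000 windows; 128×128 bit lattice for the matrix models.
APT_LENGTH = 8020
WINDOW = 20
N_WINDOWS = 8000
SHAPE = (128, 128)


def assess_scheme(
    bits: str,
    scheme: str,
    window: int = WINDOW,
    n_windows: int = N_WINDOWS,
    apt_length: int = APT_LENGTH,
    shape: tuple[int, int] = SHAPE,
) -> dict:
    """Encode ``bits`` under one scheme and run all three assessment models."""
    scheme = codec.canonical_scheme(scheme)
    seq = codec.encode(bits, scheme)
    prefix = seq[:apt_length]
    msd = apt.msd_curve(prefix, window=window, n_windows=n_windows)
    tfit = apt.fit_translational(msd)
    msad = apt.msad_curves(prefix, window=window, n_windows=n_windows)
    rfit = apt.fit_rotational(msad)
    sums, params = ising.assess(seq, *shape)
    lstats = logic3.logic_stats(ising.to_spin_matrix(seq, *shape))
    return {
        "scheme": scheme,
        "length_nt": len(seq),
        "information_density": len(bits) / len(seq),
        "gc_ratio": seqstats.gc_ratio(seq),
        "longest_homopolymer": seqstats.longest_homopolymer(seq),
        "V": tfit.V,
        "D": tfit.D,
        "omega": rfit.omega,
        "D_R": rfit.d_r,
        "gamma": params.gamma,
        "lambda": params.lam,
        "h": params.h,
        "rms_alpha": lstats.rms_alpha,
        "rms_beta": lstats.rms_beta,
    }


def assess_all(
    bits: str,
    schemes: Sequence[str] = codec.SCHEMES,
    window: int = WINDOW,
    n_windows: int = N_WINDOWS,
    apt_length: int = APT_LENGTH,
    shape: tuple[int, int] = SHAPE,
) -> dict:
    """Full comparison report for one payload across several schemes."""
    if not schemes:
        raise FormatError("at least one encoding scheme is required")
    if not bits:
        raise FormatError("nothing to encode: empty payload")
    rows = [
        assess_scheme(bits, s, window, n_windows, apt_length, shape)
        for s in schemes
    ]
    for row in rows:
        for key, value in row.items():
            if isinstance(value, float) and not math.isfinite(value):
                raise FormatError(f"non-finite metric {key} for scheme {row['scheme']}")
    return {
        "config": {
            "payload_bits": len(bits),
            "window": window,
            "n_windows": n_windows,
            "apt_length": apt_length,
            "shape": list(shape),
            "schemes": [codec.canonical_scheme(s) for s in schemes],
        },
        "schemes": rows,
    }


REPORT_COLUMNS = (
    "scheme", "length_nt", "information_density", "gc_ratio",
    "longest_homopolymer", "V", "D", "omega", "D_R",
    "gamma", "lambda", "h", "rms_alpha", "rms_beta",
)


def report_tsv(report: dict) -> str:
    """Render an assess_all report as a TSV table."""
    lines = ["\t".join(REPORT_COLUMNS)]
    for row in report["schemes"]:
        cells = []
        for col in REPORT_COLUMNS:
            v = row[col]
            cells.append(f"{v:.6g}" if isinstance(v, float) else str(v))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
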