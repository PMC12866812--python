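"""Binary test-pattern generation and bit-matrix plumbing.

The storage experiments use 128×128 black-white images as payloads.  Four of
them are algorithmic patterns produced by 3-input/1-output logic rules
(elementary cellular automata, Wolfram numbering): each cell of row ``r+1``
is the rule's output for the three cells above it.  This module generates
those patterns, converts between bit matrices and bit strings (row-major,
origin top-left), and reads/writes plain-text PBM (P1) plus thresholded PNG
import for photographic inputs.

Convention used throughout the package: black pixel = 1-bit = spin-up,
white pixel = 0-bit = spin-down.
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError, InsufficientDataError

__all__ = [
    "eca_matrix",
    "eca_matrix_reference",
    "flatten",
    "reshape",
    "random_bits",
    "random_matrix",
    "read_pbm",
    "write_pbm",
    "read_image",
]


def _as_matrix(matrix) -> np.ndarray:
    m = np.asarray(matrix, dtype=np.uint8)
    if m.ndim != 2:
        raise FormatError("binary matrix must be 2-D")
    if not np.isin(m, (0, 1)).all():
        raise FormatError("binary matrix cells must be 0 or 1")
    return m


def _initial_row(init, n_cols: int, rng_seed_offset: int = 0) -> np.ndarray:
    """Resolve the init argument: an integer seed, the string 'center', or a row."""
    if isinstance(init, str):
        if init != "center":
            raise FormatError(f"unknown init value {init!r}")
        row = np.zeros(n_cols, dtype=np.uint8)
        row[n_cols // 2] = 1
        return row
    if isinstance(init, (int, np.integer)):
        rng = np.random.default_rng(int(init) + rng_seed_offset)
        return rng.integers(0, 2, size=n_cols, dtype=np.uint8)
    row = np.asarray(init, dtype=np.uint8).ravel()
    if row.size != n_cols:
        raise FormatError(f"initial row has {row.size} cells, expected {n_cols}")
    return row


def eca_matrix(rule_number: int, n_rows: int, n_cols: int, init=0) -> np.ndarray:
    """Evolve an elementary cellular automaton into an ``n_rows×n_cols`` matrix.

    Row 0 comes from ``init`` (an RNG seed for a uniform random row, the
    string ``'center'`` for a single centered 1, or an explicit row).  Cell
    ``c`` of row ``r+1`` is bit ``4a + 2b + d`` of ``rule_number``, where
    ``(a, b, d)`` are row ``r`` cells ``c−1, c, c+1`` with circular boundary.
    """
    if not 0 <= rule_number <= 255:
        raise FormatError(f"rule number must be in 0..255, got {rule_number}")
    if n_rows < 1 or n_cols < 1:
        raise FormatError("matrix must have at least one row and column")
    out = np.empty((n_rows, n_cols), dtype=np.uint8)
    out[0] = _initial_row(init, n_cols)
    rule_bits = np.array([(rule_number >> k) & 1 for k in range(8)], dtype=np.uint8)
    for r in range(n_rows - 1):
        row = out[r]
        idx = 4 * np.roll(row, 1) + 2 * row + np.roll(row, -1)
        out[r + 1] = rule_bits[idx]
    return out


def eca_matrix_reference(rule_number: int, n_rows: int, n_cols: int, init=0) -> np.ndarray:
    """Scalar truth-table evolution, cell by cell; cross-check for eca_matrix."""
    if not 0 <= rule_number <= 255:
        raise FormatError(f"rule number must be in 0..255, got {rule_number}")
    table = {
        (a, b, d): (rule_number >> (4 * a + 2 * b + d)) & 1
        for a in (0, 1) for b in (0, 1) for d in (0, 1)
    }
    out = [list(_initial_row(init, n_cols))]
    for _ in range(n_rows - 1):
        prev = out[-1]
        out.append(
            [
                table[(prev[(c - 1) % n_cols], prev[c], prev[(c + 1) % n_cols])]
                for c in range(n_cols)
            ]
        )
    return np.array(out, dtype=np.uint8)


def flatten(matrix) -> str:
    """Row-major bit string of a binary matrix."""
    m = _as_matrix(matrix)
    return "".join("01"[b] for b in m.ravel())


def reshape(bits: str, n_rows: int, n_cols: int) -> np.ndarray:
    """First ``n_rows·n_cols`` bits into a matrix; surplus bits are dropped.

    Decoded payloads carry a few trailing bits beyond the image (e.g. 16392
    bits reshaped to 128×128 drops 8), so truncation is the intended
    behaviour, not an error.
    """
    need = n_rows * n_cols
    if len(bits) < need:
        raise InsufficientDataError(
            f"need {need} bits for a {n_rows}x{n_cols} matrix, got {len(bits)}"
        )
    arr = np.frombuffer(bits[:need].encode(), dtype=np.uint8) - ord("0")
    if not np.isin(arr, (0, 1)).all():
        raise FormatError("bit string contains non-binary characters")
    return arr.reshape(n_rows, n_cols).astype(np.uint8)


def random_bits(n: int, seed: int = 0) -> str:
    """Uniform random bit string (fixture payloads)."""
    rng = np.random.default_rng(seed)
    return "".join("01"[b] for b in rng.integers(0, 2, size=n))


def random_matrix(n_rows: int, n_cols: int, seed: int = 0, p: float = 0.5) -> np.ndarray:
    """iid Bernoulli(p) binary matrix."""
    rng = np.random.default_rng(seed)
    return (rng.random((n_rows, n_cols)) < p).astype(np.uint8)


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def write_pbm(matrix, path) -> None:
    """Write a binary matrix as plain-text PBM (P1); 1 = black."""
    m = _as_matrix(matrix)
    with open(path, "w") as fh:
        fh.write(f"P1\n{m.shape[1]} {m.shape[0]}\n")
        for row in m:
            fh.write(" ".join(str(int(b)) for b in row) + "\n")


def read_pbm(path) -> np.ndarray:
    """Read a plain-text PBM (P1) file into a binary matrix."""
    with open(path) as fh:
        tokens: list[str] = []
        for line in fh:
            line = line.split("#", 1)[0]
            tokens.extend(line.split())
    if not tokens or tokens[0] != "P1":
        raise FormatError("not a plain PBM (P1) file")
    try:
        n_cols, n_rows = int(tokens[1]), int(tokens[2])
        cells = [int(t) for t in tokens[3 : 3 + n_rows * n_cols]]
    except (IndexError, ValueError) as exc:
        raise FormatError("malformed PBM file") from exc
    if len(cells) != n_rows * n_cols:
        raise FormatError("PBM pixel count does not match header")
    return _as_matrix(np.array(cells, dtype=np.uint8).reshape(n_rows, n_cols))


def read_image(path) -> np.ndarray:
    """Read any Pillow-supported image, thresholding luminance at 0.5.

    Plain-text PBM is handled natively; everything else (PNG photographs
    and the like) is converted to grayscale and pixels darker than half
    scale become 1-bits.
    """
    p = str(path)
    if p.lower().endswith(".pbm"):
        with open(p, "rb") as fh:
            if fh.read(2) == b"P1":
                return read_pbm(p)
    from PIL import Image

    with Image.open(p) as img:
        gray = np.asarray(img.convert("L"), dtype=np.float64) / 255.0
    return (gray < 0.5).astype(np.uint8)
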