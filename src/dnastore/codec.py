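"""Constrained DNA codecs for binary data storage.

Binary payloads are stored in DNA either by direct 2-bit positional mapping
(00→A, 01→C, 10→G, 11→T) or through a run-length-limited design rule,
written ``R_N-B#``: the payload is read as one big integer, converted to a
radix-``#`` digit string, and each digit is emitted as a nucleotide monomer
or dimer chosen from a context-dependent table.  ``N`` is the maximum
homopolymer run length the emitted sequence may contain (``inf``, 2 or 1 nt);
``#`` is the radix, equal to the number of encoding units available in any
context.

The five shipped rules and their unit sets, given the last emitted base
``c`` (the *context*):

============  =====  ======  ========  ==============================
scheme        units  radix   max run   allowed units
============  =====  ======  ========  ==============================
``Rinf-B16``  dimer    16     inf      all 16 dimers
``R1-B12``    dimer    12     2        the 12 non-homodimers
``R0-B9``     dimer     9     1        non-homodimers not starting with ``c``
``Rinf-B4``   mono      4     inf      all 4 monomers
``R0-B3``     mono      3     1        the 3 monomers differing from ``c``
============  =====  ======  ========  ==============================

A guard ``1``-bit is prepended before radix conversion so that leading
payload zeros survive the integer round trip; it also makes the digit count
(hence the encoded length) depend only on the payload bit length.  A
16384-bit payload therefore always encodes to 8196 nt (Rinf-B16), 9144 nt
(R1-B12), 10340 nt (R0-B9), 8194 nt (Rinf-B4) or 10339 nt (R0-B3),
initiator included.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import (
    AlphabetError,
    CorruptSequenceError,
    FormatError,
    IndexOverflowError,
    InvalidRadixError,
    InvalidTableError,
    PaddingError,
    UndefinedMetricError,
)

BASES = "ACGT"
DIMERS = tuple(a + b for a in BASES for b in BASES)

#: 2-bit positional mapping used by ``simple_map`` and the strand index.
SIMPLE_FORWARD = {"00": "A", "01": "C", "10": "G", "11": "T"}
SIMPLE_REVERSE = {v: k for k, v in SIMPLE_FORWARD.items()}

FORWARD_PRIMER = "ACACGACGCTCTTCCGATCT"  # 20 nt
REVERSE_PRIMER = "AGATCGGAAGAGCACACGTCT"  # 21 nt

SCHEME_ALIASES = {
    "simple": "simple",
    "rinf-b16": "Rinf-B16",
    "r∞-b16": "Rinf-B16",
    "r16": "Rinf-B16",
    "rinf-b4": "Rinf-B4",
    "r∞-b4": "Rinf-B4",
    "r4": "Rinf-B4",
    "r1-b12": "R1-B12",
    "r12": "R1-B12",
    "r0-b9": "R0-B9",
    "r9": "R0-B9",
    "r0-b3": "R0-B3",
    "r3": "R0-B3",
}

#: All scheme names accepted by :func:`build_rule_table` (canonical forms).
SCHEMES = ("simple", "Rinf-B16", "Rinf-B4", "R1-B12", "R0-B9", "R0-B3")
RULE_SCHEMES = tuple(s for s in SCHEMES if s != "simple")


def canonical_scheme(name: str) -> str:
    """Resolve a scheme name or alias (``R9``, ``r0-b9`` ...) to its canonical form."""
    key = name.strip().lower()
    if key not in SCHEME_ALIASES:
        raise FormatError(f"unknown encoding scheme: {name!r}")
    return SCHEME_ALIASES[key]


def _check_bits(bits: str) -> None:
    if bits.strip("01"):
        bad = next(c for c in bits if c not in "01")
        raise AlphabetError(f"bit string contains non-binary character {bad!r}")


def _check_bases(seq: str) -> None:
    if seq.strip(BASES):
        bad = next(c for c in seq if c not in BASES)
        raise AlphabetError(f"sequence contains invalid base {bad!r}")


# ---------------------------------------------------------------------------
# radix conversion
# ---------------------------------------------------------------------------

def bits_to_digits(bits: str, radix: int, guard: bool = True) -> list[int]:
    """Convert a bit string to its canonical radix-``radix`` digit list.

    The bit string is interpreted most-significant-bit first as one big
    integer.  With ``guard=True`` a ``1``-bit is prepended first, so leading
    zeros are preserved and the digit count is a function of bit length
    alone.  Digits are returned most significant first.
    """
    if radix < 2:
        raise InvalidRadixError(f"radix must be >= 2, got {radix}")
    _check_bits(bits)
    if guard:
        bits = "1" + bits
    elif not bits:
        raise FormatError("empty bit string requires guard=True")
    value = int(bits, 2)
    if value == 0:
        return [0]
    digits: list[int] = []
    while value:
        value, d = divmod(value, radix)
        digits.append(d)
    digits.reverse()
    return digits


def digits_to_bits(digits: Sequence[int], radix: int, guard: bool = True) -> str:
    """Exact inverse of :func:`bits_to_digits`.

    With ``guard=True`` the recovered binary form must start with the guard
    ``1``-bit, which is stripped; what remains is the original payload,
    leading zeros included.
    """
    if radix < 2:
        raise InvalidRadixError(f"radix must be >= 2, got {radix}")
    value = 0
    for d in digits:
        if not 0 <= d < radix:
            raise CorruptSequenceError(f"digit {d} out of range for radix {radix}")
        value = value * radix + d
    bits = format(value, "b")
    if guard:
        if bits == "0" or bits[0] != "1":
            raise CorruptSequenceError("guarded value lost its leading 1-bit")
        return bits[1:]
    return bits if value else "0" * bool(len(digits))


# ---------------------------------------------------------------------------
# rule tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RuleTable:
    """A randomized design rule R_N-B#: context-dependent digit→unit tables.

    ``rows`` maps each context base (the last emitted base) to the ordered
    tuple of units, indexed by digit.  The start context is the last base of
    the initiator, so no separate "start" row is needed.
    """

    scheme_id: str
    unit_len: int
    radix: int
    max_run: float  # math.inf, 2 or 1
    initiator: str
    guard: bool
    rows: Mapping[str, tuple[str, ...]]
    inverse: Mapping[str, Mapping[str, int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.validate()
        inv = {c: {u: d for d, u in enumerate(row)} for c, row in self.rows.items()}
        object.__setattr__(self, "inverse", inv)

    def validate(self) -> None:
        if len(self.initiator) != self.unit_len:
            raise InvalidTableError("initiator length must equal unit length")
        _check_bases(self.initiator)
        if set(self.rows) != set(BASES):
            raise InvalidTableError("rows must cover contexts A, C, G, T")
        for context, row in self.rows.items():
            if len(row) != self.radix or len(set(row)) != self.radix:
                raise InvalidTableError(
                    f"context {context}: row must be a bijection onto {self.radix} units"
                )
            for unit in row:
                if len(unit) != self.unit_len:
                    raise InvalidTableError(f"unit {unit!r} has wrong length")
                _check_bases(unit)
                if _max_run_with_context(context, unit) > self.max_run:
                    raise InvalidTableError(
                        f"unit {unit!r} violates max homopolymer run "
                        f"{self.max_run} after context {context}"
                    )

    def to_json(self) -> dict:
        return {
            "scheme": self.scheme_id,
            "unit_len": self.unit_len,
            "radix": self.radix,
            "max_run": None if math.isinf(self.max_run) else int(self.max_run),
            "initiator": self.initiator,
            "guard": self.guard,
            "rows": {c: list(row) for c, row in self.rows.items()},
        }

    @classmethod
    def from_json(cls, data: Mapping) -> "RuleTable":
        max_run = data.get("max_run")
        return cls(
            scheme_id=data["scheme"],
            unit_len=int(data["unit_len"]),
            radix=int(data["radix"]),
            max_run=math.inf if max_run is None else float(max_run),
            initiator=data["initiator"],
            guard=bool(data["guard"]),
            rows={c: tuple(row) for c, row in data["rows"].items()},
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "RuleTable":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


def _max_run_with_context(context: str, unit: str) -> int:
    """Longest homopolymer run inside ``context + unit`` that involves the unit."""
    s = context + unit
    best = 1
    for _, grp in itertools.groupby(s):
        best = max(best, len(list(grp)))
    return best


def _allowed_units(scheme: str, context: str) -> tuple[str, ...]:
    if scheme == "Rinf-B16":
        return DIMERS
    if scheme == "R1-B12":
        return tuple(u for u in DIMERS if u[0] != u[1])
    if scheme == "R0-B9":
        return tuple(u for u in DIMERS if u[0] != u[1] and u[0] != context)
    if scheme == "Rinf-B4":
        return tuple(BASES)
    if scheme == "R0-B3":
        return tuple(b for b in BASES if b != context)
    raise FormatError(f"no unit set for scheme {scheme!r}")

def _scrambled_row(scheme: str, context: str, units: Sequence[str]) -> tuple[str, ...]:
    """Fixed pseudo-random digit→unit assignment for one context.

    The randomization of an R_N-B# rule lives in the digit→unit tables: an
    identity (lexicographic) assignment for B16 would reduce the rule to
    the 2-bit positional mapping and leave payload structure — homopolymers
    included — intact.  The shipped defaults therefore scramble each
    context row with a permutation seeded from the scheme and context
    names, so the tables are arbitrary but reproducible; bit-exact
    alternative tables can be supplied via ``overrides``.
    """
    import zlib

    import numpy as np

    seed = zlib.crc32(f"dnastore:{scheme}:{context}".encode())
    perm = np.random.default_rng(seed).permutation(len(units))
    return tuple(units[i] for i in perm)


# The shipped Rinf-B4 default is pinned by a worked conversion
# (1110011100 in binary -> 32130 in base 4 -> ACCGTG from initiator A);
# the five digit assignments it implies are fixed, the rest fill in
# lexicographic order.
_B4_PINNED: dict[str, dict[int, str]] = {
    "A": {3: "C"},
    "C": {1: "G", 2: "C"},
    "G": {3: "T"},
    "T": {0: "G"},
}

_SCHEME_PARAMS = {
    "Rinf-B16": dict(unit_len=2, radix=16, max_run=math.inf, initiator="AT"),
    "R1-B12": dict(unit_len=2, radix=12, max_run=2, initiator="AT"),
    "R0-B9": dict(unit_len=2, radix=9, max_run=1, initiator="AT"),
    "Rinf-B4": dict(unit_len=1, radix=4, max_run=math.inf, initiator="A"),
    "R0-B3": dict(unit_len=1, radix=3, max_run=1, initiator="A"),
}


def build_rule_table(
    scheme_id: str,
    overrides: Mapping[str, Sequence[str]] | None = None,
    initiator: str | None = None,
) -> RuleTable:
    """Build the canonical table for a design rule, optionally overriding rows.

    Each context row is a fixed scrambled assignment of digits onto the
    allowed units (see :func:`_scrambled_row`), except the shipped
    ``Rinf-B4`` default, which embeds the five assignments its worked
    example pins down and fills the rest lexicographically.  ``overrides``
    replaces whole rows (context → ordered unit list) and must preserve
    the table invariants.
    """
    scheme = canonical_scheme(scheme_id)
    if scheme == "simple":
        raise FormatError("simple mapping has no rule table; use simple_map")
    params = dict(_SCHEME_PARAMS[scheme])
    if initiator is not None:
        params["initiator"] = initiator
    rows: dict[str, tuple[str, ...]] = {}
    for context in BASES:
        units = sorted(_allowed_units(scheme, context))
        if scheme == "Rinf-B4":
            pinned = _B4_PINNED[context]
            rest = [u for u in units if u not in pinned.values()]
            row: list[str] = []
            for digit in range(4):
                row.append(pinned[digit] if digit in pinned else rest.pop(0))
            rows[context] = tuple(row)
        else:
            rows[context] = _scrambled_row(scheme, context, units)
    if overrides:
        for context, row in overrides.items():
            rows[context] = tuple(row)
    return RuleTable(scheme_id=scheme, guard=True, rows=rows, **params)


# ---------------------------------------------------------------------------
# encode / decode
# ---------------------------------------------------------------------------

def encode_sequence(bits: str, table: RuleTable, guard: bool | None = None) -> str:
    """Encode a bit string into a constrained DNA sequence under ``table``.

    The output is ``initiator`` followed by one unit per digit of the
    radix-converted (optionally guarded) payload.  ``guard`` overrides the
    table default, which is needed only to reproduce unguarded worked
    conversions.
    """
    use_guard = table.guard if guard is None else guard
    digits = bits_to_digits(bits, table.radix, guard=use_guard)
    parts = [table.initiator]
    context = table.initiator[-1]
    rows = table.rows
    for d in digits:
        unit = rows[context][d]
        parts.append(unit)
        context = unit[-1]
    return "".join(parts)


def decode_sequence(seq: str, table: RuleTable, guard: bool | None = None) -> str:
    """Exact inverse of :func:`encode_sequence`.

    Raises :class:`FormatError` for a wrong initiator or length, and
    :class:`CorruptSequenceError` (with the offending position) when a unit
    is not in the context's row — e.g. a homopolymer in an R0 sequence.
    """
    use_guard = table.guard if guard is None else guard
    _check_bases(seq)
    init = table.initiator
    if not seq.startswith(init):
        raise FormatError(f"sequence does not start with initiator {init!r}")
    body = seq[len(init):]
    if len(body) % table.unit_len:
        raise FormatError(
            f"sequence body length {len(body)} is not a multiple of "
            f"unit length {table.unit_len}"
        )
    digits: list[int] = []
    context = init[-1]
    inverse = table.inverse
    for pos in range(0, len(body), table.unit_len):
        unit = body[pos : pos + table.unit_len]
        try:
            digit = inverse[context][unit]
        except KeyError:
            raise CorruptSequenceError(
                f"unit {unit!r} at position {len(init) + pos} not allowed "
                f"after context {context!r}"
            ) from None
        digits.append(digit)
        context = unit[-1]
    return digits_to_bits(digits, table.radix, guard=use_guard)


def simple_map(bits: str) -> str:
    """Map bit pairs positionally to bases (00→A, 01→C, 10→G, 11→T)."""
    _check_bits(bits)
    if len(bits) % 2:
        raise PaddingError("simple mapping requires an even number of bits")
    return "".join(SIMPLE_FORWARD[bits[i : i + 2]] for i in range(0, len(bits), 2))


def simple_unmap(seq: str) -> str:
    """Inverse of :func:`simple_map`: each base back to its bit pair."""
    _check_bases(seq)
    return "".join(SIMPLE_REVERSE[b] for b in seq)


def encode(bits: str, scheme: str, table: RuleTable | None = None) -> str:
    """Encode under a scheme name (``simple`` or any R_N-B# rule)."""
    if canonical_scheme(scheme) == "simple":
        return simple_map(bits)
    return encode_sequence(bits, table or build_rule_table(scheme))


def decode(seq: str, scheme: str, table: RuleTable | None = None) -> str:
    """Decode a sequence produced by :func:`encode`."""
    if canonical_scheme(scheme) == "simple":
        return simple_unmap(seq)
    return decode_sequence(seq, table or build_rule_table(scheme))


# ---------------------------------------------------------------------------
# strands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Strand:
    """A sequencing-ready strand: primers, 8-nt index, ≤57-nt payload.

    The full strand is ``forward_region + index_region + payload +
    reverse_region``; with a full 57-nt payload that is 106 nt.
    """

    ordinal: int
    payload: str
    forward_region: str = FORWARD_PRIMER
    reverse_region: str = REVERSE_PRIMER

    @property
    def index_region(self) -> str:
        return simple_map(format(self.ordinal, "016b"))

    @property
    def sequence(self) -> str:
        return self.forward_region + self.index_region + self.payload + self.reverse_region

    def __len__(self) -> int:
        return len(self.sequence)


def assemble_strands(payload: str, chunk: int = 57) -> list[Strand]:
    """Split a payload sequence into strands of ``chunk``-nt payload each.

    Strand ``i`` carries the 16-bit big-endian ordinal ``i``, simple-mapped
    into the 8-nt index region.  The final chunk may be short.
    """
    if chunk < 1:
        raise FormatError("chunk must be >= 1")
    _check_bases(payload)
    n = -(-len(payload) // chunk) if payload else 0
    if n > 0xFFFF + 1:
        raise IndexOverflowError(f"{n} chunks exceed the 16-bit strand index")
    return [Strand(i, payload[i * chunk : (i + 1) * chunk]) for i in range(n)]


def sequence_identity(read: str, reference: str) -> float:
    """Percent identity between a read and its reference payload.

    Positional comparison (the strand layout is fixed, so no alignment is
    attempted).  Unequal lengths are compared over the overlap and the
    length difference counts as errors, i.e. the denominator is the longer
    of the two lengths.  Returns a value on the 0–100 scale.
    """
    if not reference:
        raise UndefinedMetricError("identity is undefined for an empty reference")
    if not read:
        raise UndefinedMetricError("identity is undefined for an empty read")
    _check_bases(read)
    _check_bases(reference)
    n = min(len(read), len(reference))
    matches = sum(a == b for a, b in zip(read[:n], reference[:n]))
    return 100.0 * matches / max(len(read), len(reference))


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O (Biopython-backed)
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    seqio_write(recs, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into ``(id, sequence)`` pairs (uppercased)."""
    from Bio.SeqIO import parse

    return [(rec.id, str(rec.seq).upper()) for rec in parse(str(path), "fasta")]


def read_seqs(path) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ (by extension; qualities ignored)."""
    from Bio.SeqIO import parse

    fmt = "fastq" if str(path).lower().endswith(("fastq", "fq")) else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in parse(str(path), fmt)]


def write_strands_fasta(strands: Sequence[Strand], path, scheme: str = "strand") -> None:
    """One record per strand, ID ``<scheme>_<ordinal>``."""
    write_fasta(((f"{scheme}_{s.ordinal}", s.sequence) for s in strands), path)
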