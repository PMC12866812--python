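"""Elementary composition metrics for encoded DNA sequences.

GC ratio and longest homopolymer run are the two sequence-level quantities
the randomized design rules are meant to control: balanced GC content and a
hard cap on run length (2 nt under R1, 1 nt under R0)."""

from __future__ import annotations

import itertools
from typing import Iterable

from .errors import AlphabetError, UndefinedMetricError

GC_BASES = frozenset("GC")


def gc_ratio(seq: str) -> float:
    """Fraction of G and C bases, in [0, 1]."""
    if not seq:
        raise UndefinedMetricError("GC ratio is undefined for an empty sequence")
    if set(seq) - set("ACGT"):
        raise AlphabetError("sequence contains invalid bases")
    return sum(b in GC_BASES for b in seq) / len(seq)


def longest_homopolymer(seq: str) -> int:
    """Length in nt of the longest run of a single base."""
    if not seq:
        raise UndefinedMetricError("homopolymer length is undefined for an empty sequence")
    if set(seq) - set("ACGT"):
        raise AlphabetError("sequence contains invalid bases")
    return max(len(list(grp)) for _, grp in itertools.groupby(seq))


def stats_table(records: Iterable[tuple[str, str]]) -> list[dict]:
    """Per-record composition stats: id, length, gc_ratio, longest_homopolymer."""
    return [
        {
            "id": name,
            "length": len(seq),
            "gc_ratio": gc_ratio(seq),
            "longest_homopolymer": longest_homopolymer(seq),
        }
        for name, seq in records
    ]


def write_stats_tsv(records: Iterable[tuple[str, str]], path) -> None:
    rows = stats_table(records)
    with open(path, "w") as fh:
        fh.write("id\tlength\tgc_ratio\tlongest_homopolymer\n")
        for r in rows:
            fh.write(
                f"{r['id']}\t{r['length']}\t{r['gc_ratio']:.6f}\t{r['longest_homopolymer']}\n"
            )


def heatmap_codes(seq: str) -> list[int]:
    """Map bases to integer codes 0–3 (A, C, G, T) for heat-map rendering."""
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    try:
        return [order[b] for b in seq]
    except KeyError as exc:
        raise AlphabetError(f"invalid base {exc.args[0]!r}") from None


def write_heatmap_tsv(seq: str, path, width: int = 128) -> None:
    """Write the 0–3 base codes wrapped to ``width`` columns, one row per line."""
    codes = heatmap_codes(seq)
    with open(path, "w") as fh:
        for start in range(0, len(codes), width):
            fh.write("\t".join(map(str, codes[start : start + width])) + "\n")
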