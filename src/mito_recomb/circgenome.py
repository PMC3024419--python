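"""Circular-genome sequence types and coordinate primitives.

Plant mitochondrial genomes typically map as circles, and the conventional
coordinate system for them (GenBank, GFF3, published repeat tables) is
1-based and inclusive.  Everything in this package speaks that convention;
conversion to 0-based half-open happens only inside BED writers.

An interval with ``start > end`` wraps through the origin, i.e. it runs
``start .. L`` and continues ``1 .. end``.  That is the single encoding used
for origin-spanning features (negative coordinates are never used).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CircularGenome",
    "CircInterval",
    "CoordinateError",
    "TopologyError",
    "SequenceError",
    "reverse_complement",
    "interval_length",
    "extract",
    "gc_content",
]

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class CoordinateError(ValueError):
    """A coordinate lies outside ``[1, L]`` or an interval is malformed."""


class TopologyError(ValueError):
    """A wrapping interval was requested on a non-circular sequence."""


class SequenceError(ValueError):
    """A sequence violates the {A, C, G, T, N} alphabet or is degenerate."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircInterval:
    """A 1-based inclusive interval on a (possibly circular) sequence.

    ``start > end`` encodes an interval wrapping through the origin.
    ``strand`` is ``'+'`` or ``'-'``; extraction on ``'-'`` reverse
    complements.
    """

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise CoordinateError(
                f"coordinates are 1-based; got start={self.start}, end={self.end}"
            )
        if self.strand not in ("+", "-"):
            raise CoordinateError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, L: int) -> int:
        return interval_length(self, L)

    def validate(self, L: int) -> None:
        if self.start > L or self.end > L:
            raise CoordinateError(
                f"interval {self.start}..{self.end} outside genome of length {L}"
            )

    def positions(self, L: int):
        """Yield every 1-based position covered, in 5'→3' order on '+'."""
        self.validate(L)
        if self.wraps:
            yield from range(self.start, L + 1)
            yield from range(1, self.end + 1)
        else:
            yield from range(self.start, self.end + 1)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.start}..{self.end}({self.strand})"


@dataclass
class CircularGenome:
    """A DNA sequence with an identifier and a circularity flag.

    The sequence is normalised to upper case on construction; characters
    outside {A, C, G, T, N} are rejected.
    """

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise SequenceError("genome sequence must be non-empty")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise SequenceError(f"invalid characters in sequence: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def extract(self, iv: CircInterval) -> str:
        return extract(self, iv)

    def gc_content(self) -> float:
        return gc_content(self.seq)


def interval_length(iv: CircInterval, L: int) -> int:
    """Length in nt of a 1-based inclusive interval on a circle of length L.

    ``end - start + 1``, plus ``L`` when the interval wraps the origin.
    """
    iv.validate(L)
    n = iv.end - iv.start + 1
    if iv.wraps:
        n += L
    return n


def extract(g: CircularGenome, iv: CircInterval) -> str:
    """Subsequence covered by ``iv``; reverse-complemented on the '-' strand.

    Wrapping intervals are only legal on circular genomes.
    """
    iv.validate(g.length)
    if iv.wraps:
        if not g.circular:
            raise TopologyError(
                f"interval {iv} wraps the origin but genome {g.id!r} is linear"
            )
        s = g.seq[iv.start - 1 :] + g.seq[: iv.end]
    else:
        s = g.seq[iv.start - 1 : iv.end]
    if iv.strand == "-":
        s = reverse_complement(s)
    return s


def gc_content(seq: str) -> float:
    """GC percentage over unambiguous bases; N is excluded from both sides."""
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise SequenceError("GC content undefined: no unambiguous bases")
    return 100.0 * gc / (gc + at)
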