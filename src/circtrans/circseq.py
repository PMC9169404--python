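"""Circular-coordinate sequence model.

A circRNA is represented as a linear DNA string whose origin (position 0)
is the first base downstream of the back-splice junction; all position
arithmetic is modulo the sequence length ``L``.  The junction therefore
sits between positions ``L - 1`` and ``0``, and an interval "spans the
junction" iff it covers both of them.

Reading codons around the circle partitions the positions into *codon
orbits*: stepping 3 nt at a time returns to the starting phase after
``L`` nt when ``3 | L`` (three orbits, one per frame), but visits every
position exactly once before closing after ``3 L`` nt when ``3 ∤ L``
(a single orbit, because gcd(3, L) = 1).  The orbit structure is what
makes rolling-circle translation frame-stable or frame-shifting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "CircularSequence",
    "GenomicLocus",
    "CodonOrbit",
    "normalize_sequence",
    "codon_orbits",
]

_VALID_BASES = frozenset("ACGT")


def normalize_sequence(raw: str, record_id: str = "<sequence>") -> str:
    """Uppercase, map U/u to T, and reject any non-ACGT character.

    Degenerate bases (N, R, Y, ...) are rejected with an error naming the
    record rather than silently skipped.
    """
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(
            f"record {record_id!r} contains illegal characters "
            f"{sorted(bad)}; only A/C/G/T/U are accepted"
        )
    return seq


@dataclass(frozen=True)
class GenomicLocus:
    """Genomic exon structure of a circRNA.

    ``exon_intervals`` are 0-based half-open genomic intervals ordered
    5'->3' along the *transcript* (for minus-strand loci they therefore
    descend genomically).  Their total length must equal the circRNA
    length.
    """

    chrom: str
    strand: str
    exon_intervals: tuple[tuple[int, int], ...]
    assembly: str
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ivals = tuple((int(a), int(b)) for a, b in self.exon_intervals)
        object.__setattr__(self, "exon_intervals", ivals)
        for a, b in ivals:
            if b <= a or a < 0:
                raise ValueError(f"invalid exon interval [{a}, {b})")
        genomic_order = sorted(ivals)
        for (a1, b1), (a2, b2) in zip(genomic_order, genomic_order[1:]):
            if a2 < b1:
                raise ValueError("exon intervals overlap")
        expected = genomic_order if self.strand == "+" else genomic_order[::-1]
        if ivals != tuple(expected):
            raise ValueError(
                "exon intervals must be ordered 5'->3' along the transcript"
            )

    @property
    def total_length(self) -> int:
        return sum(b - a for a, b in self.exon_intervals)


@dataclass(frozen=True)
class CircularSequence:
    """A circRNA sequence linearized at its back-splice junction."""

    id: str
    seq: str
    gene: Optional[str] = None
    locus: Optional[GenomicLocus] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_sequence(self.seq, self.id))
        if len(self.seq) < 1:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.locus is not None and self.locus.total_length != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: exon intervals sum to "
                f"{self.locus.total_length} nt but the sequence is "
                f"{len(self.seq)} nt"
            )

    @property
    def L(self) -> int:
        return len(self.seq)

    def nt_at(self, i: int) -> str:
        """Base at circular position ``i`` (any integer; wraps modulo L)."""
        return self.seq[i % self.L]

    def subseq(self, start: int, n: int) -> str:
        """``n`` bases starting at ``start mod L``, wrapping as needed.

        ``n`` may exceed L, in which case the sequence repeats (the view a
        rolling-circle ribosome sees).
        """
        if n < 0:
            raise ValueError(f"subsequence length must be >= 0, got {n}")
        L = self.L
        start %= L
        reps = (start + n + L - 1) // L  # enough copies to cover the slice
        return (self.seq * max(reps, 1))[start : start + n]

    def spans_junction(self, start: int, n: int) -> bool:
        """Whether the n-base interval at ``start`` covers the L-1 -> 0 join."""
        return (start % self.L) + n > self.L


@dataclass(frozen=True)
class CodonOrbit:
    """The cyclic sequence of codon start positions for one reading phase.

    ``codon_starts`` are listed in translation order beginning at the
    orbit's smallest circle position; walking them once and returning to
    the first element traverses exactly ``period_nt`` nucleotides.
    """

    orbit_id: int
    codon_starts: tuple[int, ...]
    period_nt: int


def codon_orbits(circ: CircularSequence) -> list[CodonOrbit]:
    """Partition circle positions into codon orbits.

    Three orbits (one per frame, period L) when ``L % 3 == 0``; a single
    orbit visiting every position (period 3L) otherwise.
    """
    L = circ.L
    if L < 3:
        raise ValueError(f"no codon fits on a circle of length {L} (< 3)")
    if L % 3 == 0:
        return [
            CodonOrbit(
                orbit_id=phase,
                codon_starts=tuple(range(phase, L, 3)),
                period_nt=L,
            )
            for phase in range(3)
        ]
    starts = []
    pos = 0
    for _ in range(L):
        starts.append(pos)
        pos = (pos + 3) % L
    return [CodonOrbit(orbit_id=0, codon_starts=tuple(starts), period_nt=3 * L)]
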