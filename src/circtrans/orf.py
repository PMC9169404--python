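"""ORF prediction on circular sequences, including rolling-circle ORFs.

Two situations arise on a circle of length L.  When ``3 | L`` the reading
frame is stable under wraparound, so a finite ORF can be at most L nt long
and a stop-free frame translates a repeating peptide whose repeat unit is
exactly L nt.  When ``3 ∤ L`` the frame shifts at every junction crossing;
the single codon orbit has period 3L, so a finite ORF can reach 3L nt and
the repeat unit of an infinite ORF is exactly 3L nt.

Within an orbit, each stop codon terminates at most one maximal ORF: among
the in-frame start codons upstream of it (back to the previous stop), the
one farthest from the stop is chosen as the start, and the nearer ones are
reported as *inner starts* (in-frame downstream AUGs, which can themselves
drive translation).  When the farthest start puts the ORF across the
back-splice junction, the farthest start that keeps the ORF linear (if any)
is additionally reported as its own call, so that the junction-free calls
coincide exactly with a conventional linear 3-frame ORF finder.  An orbit
with at least one start and no stop yields one infinite ORF anchored at its
smallest-position start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .circseq import CircularSequence, CodonOrbit, codon_orbits

__all__ = [
    "OrfCall",
    "STOP_CODONS",
    "translate_circular",
    "find_orfs",
    "find_linear_orfs",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_START_CODONS = frozenset({"ATG"})
DEFAULT_MIN_NT_LENGTH = 75

_TABLE = unambiguous_dna_by_id[1].forward_table


def _aa(codon: str) -> str:
    return _TABLE.get(codon, "*")


@dataclass(frozen=True)
class OrfCall:
    """One predicted ORF.

    Finite calls carry ``nt_length`` (stop codon included) and the peptide
    excluding the stop; infinite (rolling-circle) calls carry
    ``repeat_nt_length`` and the peptide of one repeat unit.  ``laps``
    counts back-splice-junction crossings while reading the ORF (one
    repeat unit for infinite calls); ``inner_starts`` are in-frame start
    codons strictly inside the ORF.
    """

    orf_id: str
    start_pos: int
    stop_pos: Optional[int]
    nt_length: Optional[int]
    is_infinite: bool
    repeat_nt_length: Optional[int]
    laps: int
    spans_junction: bool
    inner_starts: tuple[int, ...]
    peptide: str
    orbit_id: int

    def length_label(self) -> str:
        """Length as displayed in reports: ``"<n> × n"`` for infinite ORFs."""
        if self.is_infinite:
            return f"{self.repeat_nt_length} × n"
        return str(self.nt_length)


def translate_circular(
    circ: CircularSequence, start_pos: int, max_codons: int
) -> tuple[str, bool, int]:
    """Translate codon-by-codon around the circle from ``start_pos``.

    Stops at the first stop codon or after ``max_codons`` codons.
    Returns ``(peptide, stopped, nt_consumed)`` where ``nt_consumed``
    includes the stop codon when one was reached and the peptide does not
    include it.
    """
    if max_codons < 1:
        raise ValueError(f"max_codons must be >= 1, got {max_codons}")
    peptide: list[str] = []
    pos = start_pos % circ.L
    consumed = 0
    for _ in range(max_codons):
        codon = circ.subseq(pos, 3)
        consumed += 3
        if codon in STOP_CODONS:
            return "".join(peptide), True, consumed
        peptide.append(_aa(codon))
        pos = (pos + 3) % circ.L
    return "".join(peptide), False, consumed


def _laps(start_pos: int, nt_length: int, L: int) -> int:
    """Junction crossings while reading nt_length bases from start_pos."""
    return (start_pos % L + nt_length - 1) // L


def _sort_and_label(calls: list[OrfCall]) -> list[OrfCall]:
    """Infinite first (longest repeat first), then finite by length."""

    def key(c: OrfCall):
        if c.is_infinite:
            return (0, -c.repeat_nt_length, c.start_pos)
        return (1, -c.nt_length, c.start_pos)

    out = []
    for i, call in enumerate(sorted(calls, key=key), start=1):
        out.append(
            OrfCall(
                orf_id=f"ORF{i}",
                start_pos=call.start_pos,
                stop_pos=call.stop_pos,
                nt_length=call.nt_length,
                is_infinite=call.is_infinite,
                repeat_nt_length=call.repeat_nt_length,
                laps=call.laps,
                spans_junction=call.spans_junction,
                inner_starts=call.inner_starts,
                peptide=call.peptide,
                orbit_id=call.orbit_id,
            )
        )
    return out


def _finite_call(
    circ: CircularSequence,
    orbit: CodonOrbit,
    start_idx: int,
    stop_idx: int,
    inner_idx: Iterable[int],
) -> OrfCall:
    n = len(orbit.codon_starts)
    codons = (stop_idx - start_idx) % n + 1
    nt_length = 3 * codons
    start_pos = orbit.codon_starts[start_idx]
    peptide, stopped, consumed = translate_circular(circ, start_pos, codons)
    assert stopped and consumed == nt_length
    laps = _laps(start_pos, nt_length, circ.L)
    return OrfCall(
        orf_id="",
        start_pos=start_pos,
        stop_pos=orbit.codon_starts[stop_idx],
        nt_length=nt_length,
        is_infinite=False,
        repeat_nt_length=None,
        laps=laps,
        spans_junction=laps >= 1,
        inner_starts=tuple(orbit.codon_starts[i] for i in inner_idx),
        peptide=peptide,
        orbit_id=orbit.orbit_id,
    )


def find_orfs(
    circ: CircularSequence,
    min_nt_length: int = DEFAULT_MIN_NT_LENGTH,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
) -> list[OrfCall]:
    """Predict all finite and infinite ORFs on a circular sequence.

    Finite calls shorter than ``min_nt_length`` (stop codon included) are
    discarded; infinite calls are always reported.  Output is sorted with
    infinite ORFs first, then by decreasing length, and labelled ORF1,
    ORF2, ...
    """
    starts_set = frozenset(s.upper().replace("U", "T") for s in start_codons)
    calls: list[OrfCall] = []
    for orbit in codon_orbits(circ):
        pos = orbit.codon_starts
        n = len(pos)
        codons = [circ.subseq(p, 3) for p in pos]
        stop_idx = [i for i, c in enumerate(codons) if c in STOP_CODONS]
        start_idx = [i for i, c in enumerate(codons) if c in starts_set]
        if not start_idx:
            continue
        if not stop_idx:
            # rolling-circle ORF: anchored at the smallest-position start
            anchor = min(start_idx, key=lambda i: pos[i])
            repeat = orbit.period_nt
            peptide, stopped, consumed = translate_circular(
                circ, pos[anchor], repeat // 3
            )
            assert not stopped and consumed == repeat
            laps = repeat // circ.L  # crossings per repeat cycle: 1 or 3
            calls.append(
                OrfCall(
                    orf_id="",
                    start_pos=pos[anchor],
                    stop_pos=None,
                    nt_length=None,
                    is_infinite=True,
                    repeat_nt_length=repeat,
                    laps=laps,
                    spans_junction=True,
                    inner_starts=tuple(
                        sorted(pos[i] for i in start_idx if i != anchor)
                    ),
                    peptide=peptide,
                    orbit_id=orbit.orbit_id,
                )
            )
            continue
        start_in_orbit = set(start_idx)
        for k, j in enumerate(stop_idx):
            prev = stop_idx[k - 1]  # wraps to the last stop when k == 0
            m = (j - prev) % n or n  # arc length incl. the stop itself
            arc = [(prev + 1 + t) % n for t in range(m)]
            arc_starts = [i for i in arc if i in start_in_orbit]
            if not arc_starts:
                continue
            primary = arc_starts[0]  # farthest from the stop
            call = _finite_call(circ, orbit, primary, j, arc_starts[1:])
            calls.append(call)
            if call.laps >= 1:
                # the farthest start puts the ORF across the junction; also
                # report the farthest start that keeps it junction-free, so
                # junction-free calls match a linear 3-frame finder
                for rank, i in enumerate(arc_starts[1:], start=1):
                    sub = _finite_call(
                        circ, orbit, i, j, arc_starts[rank + 1 :]
                    )
                    if sub.laps == 0:
                        calls.append(sub)
                        break
    kept = [
        c
        for c in calls
        if c.is_infinite or c.nt_length >= min_nt_length
    ]
    return _sort_and_label(kept)


def find_linear_orfs(
    seq: str,
    min_nt_length: int = DEFAULT_MIN_NT_LENGTH,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
) -> list[OrfCall]:
    """Conventional linear 3-frame ORF enumeration with the farthest-start
    rule; ORFs lacking a stop codon are excluded."""
    from .circseq import normalize_sequence

    s = normalize_sequence(seq, "<linear>")
    starts_set = frozenset(c.upper().replace("U", "T") for c in start_codons)
    calls: list[OrfCall] = []
    for frame in range(3):
        pending: list[int] = []
        for p in range(frame, len(s) - 2, 3):
            codon = s[p : p + 3]
            if codon in STOP_CODONS:
                if pending:
                    start = pending[0]
                    nt_length = p + 3 - start
                    peptide = "".join(
                        _aa(s[q : q + 3]) for q in range(start, p, 3)
                    )
                    calls.append(
                        OrfCall(
                            orf_id="",
                            start_pos=start,
                            stop_pos=p,
                            nt_length=nt_length,
                            is_infinite=False,
                            repeat_nt_length=None,
                            laps=0,
                            spans_junction=False,
                            inner_starts=tuple(pending[1:]),
                            peptide=peptide,
                            orbit_id=frame,
                        )
                    )
                pending = []
            elif codon in starts_set:
                pending.append(p)
        # ORFs without a stop codon are dropped
    kept = [c for c in calls if c.nt_length >= min_nt_length]
    return _sort_and_label(kept)
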