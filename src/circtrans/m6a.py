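"""DRACH/RRACH m6A motif scanning and known-site mapping.

N6-methyladenosine occurs within the consensus pentamer D-R-A-C-H
(D = A/G/U, R = G/A, H = A/C/U on the RNA alphabet; U == T here), the
methylated base being the central A.  Since R is a subset of D, every
RRACH occurrence is also a DRACH occurrence; a hit is classified ``BOTH``
when its first base satisfies R and ``DRACH`` otherwise.

Known-site intersection consumes an already-lifted table of genomic m6A
positions (e.g. an m6A-Atlas export) and converts in-exon sites to
circle coordinates; it performs no liftover of its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .circseq import CircularSequence, GenomicLocus

__all__ = ["MotifHit", "KnownSite", "scan_motifs", "map_known_sites"]

_D = frozenset("AGT")
_R = frozenset("GA")
_H = frozenset("ACT")


@dataclass(frozen=True)
class MotifHit:
    """One DRACH/RRACH occurrence; ``m6a_pos`` is the methylated A."""

    motif_start: int
    m6a_pos: int
    pentamer: str
    kind: str  # "DRACH" (D-only) or "BOTH" (also RRACH)
    spans_junction: bool


@dataclass(frozen=True)
class KnownSite:
    """A known m6A site in genomic coordinates (0-based)."""

    chrom: str
    genomic_pos: int
    strand: str
    assembly: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def _classify(pentamer: str) -> Optional[str]:
    if (
        pentamer[0] in _D
        and pentamer[1] in _R
        and pentamer[2] == "A"
        and pentamer[3] == "C"
        and pentamer[4] in _H
    ):
        return "BOTH" if pentamer[0] in _R else "DRACH"
    return None


def scan_motifs(circ: CircularSequence, kind: str = "BOTH") -> list[MotifHit]:
    """Enumerate DRACH/RRACH motifs, testing every circle position as a
    motif start (wrapping up to 4 nt past the back-splice junction).

    ``kind`` selects the reported set: ``"DRACH"`` or ``"BOTH"`` return all
    DRACH hits (RRACH is a subset of DRACH), ``"RRACH"`` returns only hits
    whose first base is G/A.  Hits are sorted by ``motif_start``.
    """
    if kind not in ("DRACH", "RRACH", "BOTH"):
        raise ValueError(f"kind must be DRACH, RRACH or BOTH, got {kind!r}")
    L = circ.L
    if L < 5:
        return []
    padded = circ.subseq(0, L + 4)
    hits: list[MotifHit] = []
    for start in range(L):
        cls = _classify(padded[start : start + 5])
        if cls is None:
            continue
        if kind == "RRACH" and cls != "BOTH":
            continue
        hits.append(
            MotifHit(
                motif_start=start,
                m6a_pos=(start + 2) % L,
                pentamer=padded[start : start + 5],
                kind=cls,
                spans_junction=start + 5 > L,
            )
        )
    return hits


def map_known_sites(
    locus: GenomicLocus,
    sites: Iterable[KnownSite],
    ignore_strand: bool = False,
) -> list[tuple[KnownSite, int]]:
    """Convert known genomic m6A sites inside the locus exons to circle
    coordinates (0-based, 5'->3' along the transcript).

    Sites on the wrong strand are excluded unless ``ignore_strand`` is
    set; a site with a different assembly tag is an error.
    """
    out: list[tuple[KnownSite, int]] = []
    for site in sites:
        if site.assembly != locus.assembly:
            raise ValueError(
                f"assembly mismatch: locus is {locus.assembly!r} but site "
                f"{site.chrom}:{site.genomic_pos} is {site.assembly!r}"
            )
        if site.chrom != locus.chrom:
            continue
        if not ignore_strand and site.strand != locus.strand:
            continue
        offset = 0
        for a, b in locus.exon_intervals:
            if a <= site.genomic_pos < b:
                if locus.strand == "+":
                    circ_pos = offset + (site.genomic_pos - a)
                else:
                    circ_pos = offset + (b - 1 - site.genomic_pos)
                out.append((site, circ_pos))
                break
            offset += b - a
    out.sort(key=lambda t: t[1])
    return out
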