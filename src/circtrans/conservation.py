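"""Conserved ("homeotic") circRNA pairing between species.

A human-mouse circRNA pair is called conserved when (1) both circRNAs
derive from the same gene, (2) their sequence lengths are identical, and
(3) their sequence identity is strictly greater than 80%.  Identity is
computed from a global end-to-end alignment (match +1, mismatch -1,
linear gap -2) as matched columns over alignment columns; although the
lengths are equal, indel pairs can still outscore positional matching,
which is why an alignment is used.  Both sequences are assumed to be
linearized at their annotated back-splice junctions; no rotational
realignment is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from .circseq import CircularSequence, normalize_sequence

__all__ = ["ConservedPair", "percent_identity", "find_homeotic_pairs"]

logger = logging.getLogger(__name__)

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_SCORE = -2
DEFAULT_MIN_IDENTITY_PCT = 80.0


@dataclass(frozen=True)
class ConservedPair:
    """A cross-species conserved circRNA pair (identity strictly > 80%)."""

    id_a: str
    id_b: str
    gene: str
    length: int
    identity_pct: float


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    return aligner


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment percent identity (0..100).

    The highest-scoring end-to-end alignment is taken (the aligner's first
    optimal alignment when several tie); identity is 100 x matched columns
    / alignment columns.
    """
    a = normalize_sequence(seq_a, "seq_a")
    b = normalize_sequence(seq_b, "seq_b")
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    alignment = _aligner().align(a, b)[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


def find_homeotic_pairs(
    set_a: Sequence[CircularSequence],
    set_b: Sequence[CircularSequence],
    min_identity_pct: float = DEFAULT_MIN_IDENTITY_PCT,
) -> list[ConservedPair]:
    """All cross-set pairs with equal (case-folded) gene symbol, identical
    length, and identity strictly above ``min_identity_pct``.

    Records without a gene symbol are skipped with a logged warning.
    Output is sorted by gene, then identity descending, then record ids.
    """

    def usable(records: Sequence[CircularSequence], label: str):
        kept = []
        for rec in records:
            if not rec.gene:
                logger.warning(
                    "record %r in %s has no gene symbol; skipped", rec.id, label
                )
                continue
            kept.append(rec)
        return kept

    pairs: list[ConservedPair] = []
    by_key: dict[tuple[str, int], list[CircularSequence]] = {}
    for rec in usable(set_b, "set_b"):
        by_key.setdefault((rec.gene.casefold(), rec.L), []).append(rec)
    for rec_a in usable(set_a, "set_a"):
        for rec_b in by_key.get((rec_a.gene.casefold(), rec_a.L), []):
            identity = percent_identity(rec_a.seq, rec_b.seq)
            if identity > min_identity_pct:
                pairs.append(
                    ConservedPair(
                        id_a=rec_a.id,
                        id_b=rec_b.id,
                        gene=rec_a.gene.casefold(),
                        length=rec_a.L,
                        identity_pct=identity,
                    )
                )
    pairs.sort(key=lambda p: (p.gene, -p.identity_pct, p.id_a, p.id_b))
    return pairs
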