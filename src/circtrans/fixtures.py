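"""Deterministic synthetic-data generators with planted ground truth.

Every generator takes a seed and returns both the constructed input and
the truth it was built to contain, so the analysis modules can be tested
end to end without any external download.  The ORF fixtures engineer the
codon-orbit content directly: filler material is chosen so that no start
or stop codon can arise anywhere except where planted (G/C filler for the
single-orbit case; glycine GGN codons for the frame-stable case, which
cannot create ATG or a stop in any reading phase, even across codon
boundaries).  The IRES fixture emulates the statistical shape of a
native IRES training set — fixed-length labelled fragments whose positive
class is enriched for a small set of tetramers — not real IRES sequence
composition.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .circseq import CircularSequence

__all__ = [
    "PlantedTruth",
    "make_orf_fixture",
    "make_ires_training_fixture",
    "make_conservation_fixture",
    "PLANTED_TETRAMERS",
]

# Gly codons: no A followed by T anywhere, so no frame can read ATG; the
# only stops/starts on the circle are the planted ones.
_FILLER_CODONS = ("GGA", "GGC", "GGG", "GGT")
_GC = "GC"

PLANTED_TETRAMERS = ("TACG", "GATC", "CCGA", "TGCA", "AGGT", "CTTG")


@dataclass(frozen=True)
class PlantedTruth:
    """A generated circular sequence plus the calls it must produce."""

    circ: CircularSequence
    expected_orfs: tuple[dict, ...] = ()
    notes: str = ""


def _finite_truth(start_pos: int, stop_pos: int, nt_length: int, L: int,
                  inner_starts: tuple[int, ...] = ()) -> dict:
    laps = (start_pos + nt_length - 1) // L
    return {
        "is_infinite": False,
        "start_pos": start_pos,
        "stop_pos": stop_pos,
        "nt_length": nt_length,
        "laps": laps,
        "spans_junction": laps >= 1,
        "inner_starts": inner_starts,
    }


def _infinite_truth(start_pos: int, repeat_nt_length: int, L: int,
                    inner_starts: tuple[int, ...] = ()) -> dict:
    return {
        "is_infinite": True,
        "start_pos": start_pos,
        "repeat_nt_length": repeat_nt_length,
        "laps": repeat_nt_length // L,
        "spans_junction": True,
        "inner_starts": inner_starts,
    }


def make_orf_fixture(
    L: int,
    divisible_by_3: bool,
    want_infinite: bool,
    want_junction_span: bool = False,
    maximal: bool = False,
    seed: int = 0,
) -> PlantedTruth:
    """Engineer a circle with exactly the requested ORF topology.

    ``maximal`` (finite, non-divisible case) places the single start at
    the orbit position immediately after the single stop, realizing the
    3L-nt maximum ORF.
    """
    if L < 10:
        raise ValueError(f"L must be >= 10, got {L}")
    if (L % 3 == 0) != divisible_by_3:
        raise ValueError(
            f"divisible_by_3={divisible_by_3} inconsistent with L={L}"
        )
    rng = random.Random(seed)
    if divisible_by_3:
        return _orf_fixture_divisible(L, want_infinite, want_junction_span,
                                      maximal, rng)
    return _orf_fixture_single_orbit(L, want_infinite, want_junction_span,
                                     maximal, rng)


def _orf_fixture_single_orbit(
    L: int, want_infinite: bool, want_junction_span: bool, maximal: bool,
    rng: random.Random,
) -> PlantedTruth:
    """L % 3 != 0: every trinucleotide of the circle is an orbit codon, so
    the sequence itself must contain exactly the planted ATG/stop."""
    filler = lambda n: "".join(rng.choice(_GC) for _ in range(n))
    if want_infinite:
        if maximal:
            raise ValueError("maximal applies to finite fixtures only")
        seq = "ATG" + filler(L - 3)
        truth = _infinite_truth(0, 3 * L, L)
        circ = CircularSequence(id=f"inf{L}", seq=seq)
        return PlantedTruth(circ, (truth,), notes="single orbit, no stop")
    if maximal:
        # stop TAG at 0, start ATG at the next orbit position (3):
        # the only in-orbit start after the only stop -> a 3L-nt ORF
        seq = "TAG" + "ATG" + filler(L - 6)
        truth = _finite_truth(3, 0, 3 * L, L)
        circ = CircularSequence(id=f"max{L}", seq=seq)
        return PlantedTruth(circ, (truth,), notes="maximal 3L ORF")
    if want_junction_span:
        # start near the circle end so translation crosses the junction;
        # pick enough codons to wrap exactly once
        start = L - 4  # codon occupies L-4..L-2
        k = rng.randrange(2, max(3, min(10, (L - 6) // 3)))  # codons before stop
        stop = (start + 3 * k) % L
        nt_length = 3 * (k + 1)
        assert stop + 3 <= start  # stop codon must not reach the start
        seq = list(filler(L))
        seq[start : start + 3] = "ATG"
        seq[stop : stop + 3] = "TAG"
        circ = CircularSequence(id=f"span{L}", seq="".join(seq))
        truth = _finite_truth(start, stop, nt_length, L)
        return PlantedTruth(circ, (truth,), notes="junction-spanning finite")
    # plain finite, junction-free: ATG at 0, stop well inside the circle
    k = rng.randrange(2, max(3, (L - 6) // 3))  # codons before the stop
    stop = 3 * k
    seq = "ATG" + filler(stop - 3) + "TAG" + filler(L - stop - 3)
    circ = CircularSequence(id=f"fin{L}", seq=seq)
    truth = _finite_truth(0, stop, stop + 3, L)
    return PlantedTruth(circ, (truth,), notes="junction-free finite")


def _orf_fixture_divisible(
    L: int, want_infinite: bool, want_junction_span: bool, maximal: bool,
    rng: random.Random,
) -> PlantedTruth:
    """L % 3 == 0: engineer phase-0 orbit slots; GGN filler keeps the other
    two orbits free of start codons."""
    n = L // 3
    slots = [rng.choice(_FILLER_CODONS) for _ in range(n)]
    if want_infinite:
        if maximal:
            raise ValueError("maximal applies to finite fixtures only")
        anchor_slot = rng.randrange(n)
        slots[anchor_slot] = "ATG"
        seq = "".join(slots)
        truth = _infinite_truth(3 * anchor_slot, L, L)
        circ = CircularSequence(id=f"inf{L}", seq=seq)
        return PlantedTruth(circ, (truth,), notes="frame-stable infinite")
    if maximal or want_junction_span:
        # stop in slot s, start in the next slot: ORF covers the whole
        # orbit (L nt) and wraps the junction unless it starts at 0
        s = rng.randrange(1, n - 1) if want_junction_span else n - 1
        slots[s] = "TAG"
        slots[(s + 1) % n] = "ATG"
        seq = "".join(slots)
        start_pos = 3 * ((s + 1) % n)
        truth = _finite_truth(start_pos, 3 * s, L, L)
        circ = CircularSequence(id=f"max{L}", seq=seq)
        return PlantedTruth(circ, (truth,), notes="maximal L-nt ORF")
    k = rng.randrange(2, n - 1)  # start slot 0, stop slot k
    slots[0] = "ATG"
    slots[k] = "TAG"
    seq = "".join(slots)
    truth = _finite_truth(0, 3 * k, 3 * (k + 1), L)
    circ = CircularSequence(id=f"fin{L}", seq=seq)
    return PlantedTruth(circ, (truth,), notes="frame-stable finite")


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def make_ires_training_fixture(
    n_pos: int,
    n_neg: int,
    frag_len: int = 174,
    effect: str = "strong",
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Labelled fixed-length fragments with a planted-kmer class signal.

    Negatives are uniform random.  With ``effect="strong"`` each positive
    carries one guaranteed copy of each of six fixed tetramers plus a
    second copy half the time (about 3x the background tetramer
    frequency); with ``effect="none"`` positives are drawn from the same
    distribution as negatives (a no-signal null).
    """
    if effect not in ("strong", "none"):
        raise ValueError(f"effect must be 'strong' or 'none', got {effect!r}")
    rng = random.Random(seed)
    negatives = [_random_seq(rng, frag_len) for _ in range(n_neg)]
    positives = []
    for _ in range(n_pos):
        seq = list(_random_seq(rng, frag_len))
        if effect == "strong":
            # non-overlapping 4-nt slots, shuffled, one planted per insertion
            slots = list(range(0, frag_len - 3, 4))
            rng.shuffle(slots)
            si = 0
            for tet in PLANTED_TETRAMERS:
                copies = 1 + (1 if rng.random() < 0.5 else 0)
                for _ in range(copies):
                    pos = slots[si]
                    si += 1
                    seq[pos : pos + 4] = tet
        positives.append("".join(seq))
    return positives, negatives


def make_conservation_fixture(
    L: int, target_identity_pct: float, seed: int = 0
) -> tuple[str, str, float]:
    """A sequence pair differing by substitutions only.

    Mutates ``floor(L * (1 - target/100))`` distinct positions of a random
    sequence; returns ``(seq_a, seq_b, identity_pct)``.  Mutation patterns
    that a gapped alignment could partially repair (raising the measured
    identity above the planted one) are screened out and re-rolled, so the
    returned identity is exact under both gapless comparison and global
    alignment.
    """
    from .conservation import percent_identity

    if not 0 <= target_identity_pct <= 100:
        raise ValueError("target_identity_pct must be in [0, 100]")
    rng = random.Random(seed)
    # floor of L * (1 - target/100), computed without float cancellation
    n_mut = int(L * (100.0 - target_identity_pct) / 100.0 + 1e-9)
    identity = 100.0 * (L - n_mut) / L
    for _ in range(100):
        seq_a = _random_seq(rng, L)
        positions = rng.sample(range(L), n_mut)
        seq_b = list(seq_a)
        for p in positions:
            seq_b[p] = rng.choice([b for b in "ACGT" if b != seq_a[p]])
        pair = seq_a, "".join(seq_b)
        if n_mut == 0 or percent_identity(*pair) == identity:
            return pair[0], pair[1], identity
    raise RuntimeError(
        f"could not realize an alignment-exact pair at {target_identity_pct}%"
    )
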