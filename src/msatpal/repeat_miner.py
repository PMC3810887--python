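"""Detection of maximal perfect tetra-nucleotide tandem repeats.

A hit is a maximal run of a repeated 4-base motif whose tandem array has
minimal period exactly the unit length: homopolymer runs (AAAA...) and
dinucleotide repeats in tetramer disguise (ACAC...) are rejected even when
long.  Motifs are grouped into canonical classes closed under cyclic
rotation and reverse complement, the convention used when naming SSR loci
(e.g. GATA, ATAG and ATCT all belong to class AGAT).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np

from msatpal.dna import UNAMBIGUOUS, revcomp, rotations


@dataclass(frozen=True)
class RepeatHit:
    """A maximal perfect tandem repeat in one (MID-trimmed) read.

    ``start``/``end`` are 0-based half-open coordinates of the maximal exact
    repeat region; ``end`` includes trailing bases that continue the period
    without completing a unit, while ``unit_count`` counts complete units
    only.  ``left_flank``/``right_flank`` are the sequence lengths outside
    the region.
    """

    read_id: str
    motif: str
    canonical_motif: str
    unit_count: int
    start: int
    end: int
    left_flank: int
    right_flank: int

    @property
    def read_length(self) -> int:
        return self.end + self.right_flank


@lru_cache(maxsize=None)
def canonical_motif(motif: str) -> str:
    """Canonical representative of a motif's rotation/reverse-complement class.

    Returns the lexicographically smallest string among the rotations of the
    motif and the rotations of its reverse complement.  Idempotent.
    """
    motif = motif.upper()
    if set(motif) - UNAMBIGUOUS:
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    return min(rotations(motif) + rotations(revcomp(motif)))


def has_minimal_period(motif: str, period: int) -> bool:
    """True iff the tandem array of ``motif`` has minimal period ``period``.

    For a run of at least two units the minimal period of the array divides
    the unit length, so it suffices to reject motifs that are themselves a
    repetition of a proper divisor-length block (for tetramers: period 1
    homopolymers and period 2 dinucleotide doubles).
    """
    if len(motif) != period:
        return False
    for d in range(1, period):
        if period % d == 0 and motif == motif[:d] * (period // d):
            return False
    return True


_BASE_CODES = {ord(b): i for i, b in enumerate("ACGT")}


def find_perfect_repeats(
    sequence: str,
    unit_len: int = 4,
    min_units: int = 10,
    read_id: str = "",
) -> list[RepeatHit]:
    """Find every maximal perfect repeat with >= ``min_units`` complete units.

    A position j extends the periodic pattern when sequence[j] ==
    sequence[j + unit_len] and both bases are unambiguous (N never matches
    inside a repeat).  Maximal runs of such positions define the repeat
    regions; each physical run is reported once, at its leftmost phase.
    Hits are sorted by start.
    """
    s = sequence.upper()
    n = len(s)
    if n < unit_len * min_units:
        return []
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    valid = (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (
        arr == ord("T")
    )
    match = (arr[:-unit_len] == arr[unit_len:]) & valid[:-unit_len]
    if not match.any():
        return []
    # maximal runs of True in the match array
    padded = np.concatenate(([False], match, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[::2], edges[1::2]  # ends exclusive in match coords
    hits: list[RepeatHit] = []
    for i, e in zip(starts.tolist(), ends.tolist()):
        region_len = (e - i) + unit_len
        units = region_len // unit_len
        if units < min_units:
            continue
        motif = s[i : i + unit_len]
        if not has_minimal_period(motif, unit_len):
            continue
        end = i + region_len
        hits.append(
            RepeatHit(
                read_id=read_id,
                motif=motif,
                canonical_motif=canonical_motif(motif),
                unit_count=units,
                start=i,
                end=end,
                left_flank=i,
                right_flank=n - end,
            )
        )
    return hits


def select_primary_hit(hits: list[RepeatHit]) -> Optional[RepeatHit]:
    """The hit carried forward for a read: most units, ties at smallest start.

    The pipeline designs one primer pair per read, so multi-repeat reads are
    represented by their longest repeat.
    """
    if not hits:
        return None
    if len({h.read_id for h in hits}) > 1:
        raise ValueError("hits from different reads passed to select_primary_hit")
    return max(hits, key=lambda h: (h.unit_count, -h.start))
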