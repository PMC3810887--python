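"""Sequence I/O and MID-tag demultiplexing for 454-style reads.

Reads arrive either as FASTA with an optional matching QUAL file (the 454
convention: whitespace-separated integer Phred scores per record) or as
Sanger-offset FASTQ.  Each read in a pooled run carries a species-specific
MID (Multiplex Identifier) barcode at its 5' end; demultiplexing assigns
reads to species by exact prefix match and trims the tag so downstream
repeat mining never counts tag bases as flanking sequence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from msatpal.dna import VALID_BASES

logger = logging.getLogger(__name__)

#: 454 quality ceiling; FASTQ values above this are clipped on input.
MAX_QUALITY = 40

UNASSIGNED = "unassigned"


class InputConsistencyError(ValueError):
    """FASTA and QUAL files disagree (IDs, order, or lengths)."""


class TagConfigError(ValueError):
    """MID tag configuration is ambiguous or malformed."""


@dataclass(frozen=True)
class Read:
    """One sequencing read.

    Attributes
    ----------
    read_id : str
        Record identifier.
    sequence : str
        Uppercase DNA over {A, C, G, T, N}; never empty.
    quality : list of int, optional
        Per-base Phred-like scores in [0, 40], one per base.
    species : str, optional
        Species label attached after demultiplexing.
    """

    read_id: str
    sequence: str
    quality: Optional[tuple[int, ...]] = None
    species: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        seq = self.sequence.upper()
        if seq != self.sequence:
            object.__setattr__(self, "sequence", seq)
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"read {self.read_id!r}: invalid characters {sorted(bad)}"
            )
        if self.quality is not None:
            qual = tuple(int(q) for q in self.quality)
            if len(qual) != len(seq):
                raise ValueError(
                    f"read {self.read_id!r}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            if any(q < 0 or q > MAX_QUALITY for q in qual):
                raise ValueError(
                    f"read {self.read_id!r}: quality values outside [0, {MAX_QUALITY}]"
                )
            object.__setattr__(self, "quality", qual)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> Optional[float]:
        if self.quality is None:
            return None
        return sum(self.quality) / len(self.quality)


@dataclass(frozen=True)
class MidTag:
    """A species-specific MID barcode (11 bp in the Roche rapid-library set)."""

    species: str
    tag: str

    def __post_init__(self):
        tag = self.tag.upper()
        if not tag or set(tag) - VALID_BASES:
            raise TagConfigError(f"invalid MID tag {self.tag!r}")
        object.__setattr__(self, "tag", tag)


def validate_tags(tags: Iterable[MidTag]) -> list[MidTag]:
    """Check the prefix-ambiguity invariant of a MID configuration.

    No tag may be a prefix of another (which includes duplicate tags); a
    duplicate tag shared by two species is a configuration error.
    """
    tags = list(tags)
    for i, a in enumerate(tags):
        for b in tags[i + 1 :]:
            if a.tag.startswith(b.tag) or b.tag.startswith(a.tag):
                raise TagConfigError(
                    f"ambiguous MID configuration: {a.species!r} tag {a.tag} and "
                    f"{b.species!r} tag {b.tag} are prefix-compatible"
                )
    return tags


def _prefix_mismatches(sequence: str, tag: str) -> Optional[int]:
    """Mismatch count of ``tag`` against the start of ``sequence``.

    Returns None when the read is shorter than the tag.  N never matches
    any tag base.
    """
    if len(sequence) < len(tag):
        return None
    mm = 0
    for s, t in zip(sequence, tag):
        if s == "N" or s != t:
            mm += 1
    return mm


def assign_species(
    read: Read, tags: list[MidTag], max_mismatches: int = 0
) -> str:
    """Assign a read to a species by MID prefix match.

    Exact prefix (0 mismatches) by default.  With ``max_mismatches`` > 0 the
    best-matching tag wins; a mismatch-count tie between different species
    leaves the read unassigned.
    """
    validate_tags(tags)
    best: list[tuple[int, MidTag]] = []
    for t in tags:
        mm = _prefix_mismatches(read.sequence, t.tag)
        if mm is not None and mm <= max_mismatches:
            best.append((mm, t))
    if not best:
        return UNASSIGNED
    best.sort(key=lambda x: x[0])
    top = [t for mm, t in best if mm == best[0][0]]
    if len({t.species for t in top}) > 1:
        return UNASSIGNED
    return top[0].species


def trim_mid(read: Read, tag: MidTag) -> Read:
    """Remove the MID prefix (and its quality positions) from a read."""
    if not read.sequence.startswith(tag.tag):
        raise ValueError(
            f"read {read.read_id!r}: tag {tag.tag} is not a prefix of the sequence"
        )
    n = len(tag.tag)
    qual = read.quality[n:] if read.quality is not None else None
    return replace(read, sequence=read.sequence[n:], quality=qual,
                   species=tag.species)


def demultiplex(
    reads: Iterable[Read],
    tags: list[MidTag],
    max_mismatches: int = 0,
    trim: bool = True,
) -> tuple[dict[str, list[Read]], list[Read]]:
    """Partition reads into per-species buckets plus an unassigned list.

    Every input read lands in exactly one bucket; file order is preserved
    within buckets.  Assigned reads have their MID trimmed by default.
    """
    tags = validate_tags(tags)
    by_species: dict[str, list[Read]] = {}
    for t in tags:
        by_species.setdefault(t.species, [])
    tag_lookup = {t.species: t for t in tags}  # any tag of the species for trim
    unassigned: list[Read] = []
    for read in reads:
        sp = assign_species(read, tags, max_mismatches=max_mismatches)
        if sp == UNASSIGNED:
            unassigned.append(read)
            continue
        if trim:
            # pick the tag of this species that actually matched
            matched = None
            for t in tags:
                if t.species != sp:
                    continue
                mm = _prefix_mismatches(read.sequence, t.tag)
                if mm is not None and mm <= max_mismatches:
                    if matched is None or mm < matched[0]:
                        matched = (mm, t)
            t = matched[1] if matched else tag_lookup[sp]
            if read.sequence.startswith(t.tag):
                read = trim_mid(read, t)
            else:  # mismatch-tolerant hit: trim by length
                n = len(t.tag)
                read = replace(
                    read,
                    sequence=read.sequence[n:],
                    quality=read.quality[n:] if read.quality is not None else None,
                    species=sp,
                )
        else:
            read = replace(read, species=sp)
        by_species[sp].append(read)
    return by_species, unassigned


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_sequences(path_fasta, path_qual=None) -> list[Read]:
    """Read FASTA (+ optional 454-style QUAL) into a list of Reads.

    When a QUAL file is given, record IDs, order, and lengths must match the
    FASTA one-to-one.
    """
    try:
        fasta = list(SeqIO.parse(str(path_fasta), "fasta"))
    except ValueError as exc:  # pragma: no cover - biopython names the record
        raise ValueError(f"malformed FASTA {path_fasta}: {exc}") from exc
    quals = None
    if path_qual is not None:
        quals = list(SeqIO.parse(str(path_qual), "qual"))
        if len(quals) != len(fasta):
            raise InputConsistencyError(
                f"{path_fasta} has {len(fasta)} records but {path_qual} has "
                f"{len(quals)}"
            )
    reads = []
    for i, rec in enumerate(fasta):
        qual = None
        if quals is not None:
            qrec = quals[i]
            if qrec.id != rec.id:
                raise InputConsistencyError(
                    f"record {i}: FASTA id {rec.id!r} != QUAL id {qrec.id!r}"
                )
            scores = qrec.letter_annotations["phred_quality"]
            if len(scores) != len(rec.seq):
                raise InputConsistencyError(
                    f"record {rec.id!r}: sequence length {len(rec.seq)} != "
                    f"quality length {len(scores)}"
                )
            qual = tuple(scores)
        reads.append(Read(rec.id, str(rec.seq).upper(), qual))
    return reads


def read_fastq(path) -> list[Read]:
    """Read Sanger-offset FASTQ; qualities above 40 are clipped to 40."""
    reads = []
    clipped = 0
    for rec in SeqIO.parse(str(path), "fastq"):
        scores = rec.letter_annotations["phred_quality"]
        if any(q > MAX_QUALITY for q in scores):
            clipped += 1
            scores = [min(q, MAX_QUALITY) for q in scores]
        reads.append(Read(rec.id, str(rec.seq).upper(), tuple(scores)))
    if clipped:
        logger.warning(
            "%s: clipped qualities above %d in %d record(s)", path, MAX_QUALITY,
            clipped,
        )
    return reads


def _to_record(read: Read) -> SeqRecord:
    rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
    if read.quality is not None:
        rec.letter_annotations["phred_quality"] = list(read.quality)
    return rec


def write_sequences(reads: Iterable[Read], path_fasta, path_qual=None) -> None:
    """Write reads as FASTA, optionally with a matching QUAL file."""
    reads = list(reads)
    SeqIO.write([_to_record(r) for r in reads], str(path_fasta), "fasta")
    if path_qual is not None:
        recs = []
        for r in reads:
            if r.quality is None:
                raise ValueError(f"read {r.read_id!r} has no quality to write")
            recs.append(_to_record(r))
        SeqIO.write(recs, str(path_qual), "qual")


def write_fastq(reads: Iterable[Read], path) -> None:
    """Write reads as Sanger-offset FASTQ (qualities required)."""
    recs = []
    for r in reads:
        if r.quality is None:
            raise ValueError(f"read {r.read_id!r} has no quality to write")
        recs.append(_to_record(r))
    SeqIO.write(recs, str(path), "fastq")


def load_mid_table(path) -> list[MidTag]:
    """Load a MID configuration from two-column TSV or JSON.

    TSV: one ``species<TAB>tag`` pair per line (``#`` comments allowed).
    JSON: mapping species -> tag or list of tags.
    """
    path = Path(path)
    tags: list[MidTag] = []
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        for species, value in data.items():
            for tag in ([value] if isinstance(value, str) else value):
                tags.append(MidTag(species, tag))
    else:
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TagConfigError(f"{path}: expected 2 columns, got {line!r}")
            tags.append(MidTag(parts[0], parts[1]))
    return validate_tags(tags)


#: MID configuration of the three-species newt run this pipeline models.
DEFAULT_MID_TAGS = [
    MidTag("T. cristatus", "ACACTACTCGT"),
    MidTag("T. cristatus", "ACGACACGTAT"),
    MidTag("C. asper", "ACGAGTAGACT"),
    MidTag("C. asper", "ACGCGTCTAGT"),
    MidTag("L. helveticus", "ACGTACACACT"),
    MidTag("L. helveticus", "ACGTACTGTGT"),
]
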