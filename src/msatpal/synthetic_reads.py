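"""Synthetic 454-like reads with planted repeats and a ground-truth manifest.

The generator emulates the enriched-library pyrosequencing run the pipeline
was built for: MID-prefixed reads of 200-600 bp with Phred-like qualities
capped at 40, a small fraction carrying a perfect tetra-nucleotide repeat
drawn from the enrichment-probe motif pool, and margin-separated decoy
classes that each violate exactly one cascade filter.  Because background
flanks are rejection-sampled to contain no qualifying repeat and no
homopolymer longer than five bases, the fate of every read under the filter
cascade is provable from the manifest alone, making the generator an exact
end-to-end oracle.

Decoy classes (margins chosen so classification is unambiguous):

- ``low_unit``           planted repeat of 5-9 units (below the 10-unit rule)
- ``interrupted``        two 5-9-unit halves split by one period-breaking base
- ``short_flank``        qualifying repeat but one flank of exactly 24 bp
- ``homopolymer_flank``  qualifying repeat but a 6-base run in one flank
- ``low_quality``        qualifying read with mean quality drawn from 12-17
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from msatpal.candidate_filter import CascadeConfig, StageCounts
from msatpal.dna import longest_run
from msatpal.repeat_miner import find_perfect_repeats
from msatpal.seqio_demux import DEFAULT_MID_TAGS, Read

#: Motifs of the 13 tetra-nucleotide enrichment probes used to build the libraries.
PROBE_MOTIFS = (
    "AAGT", "AGAT", "ACAT", "AAAT", "AACT", "AAAC", "AAAG",
    "AATC", "ACAG", "ACTC", "ACTG", "AATG", "ACCT",
)

DECOY_CLASSES = (
    "low_unit", "interrupted", "short_flank", "homopolymer_flank", "low_quality"
)

FATES = ("no_repeat", "flank", "homopolymer", "quality", "candidate")


class SimConfigError(ValueError):
    """The simulation configuration is infeasible or inconsistent."""


@dataclass(frozen=True)
class SpeciesSim:
    label: str
    tags: tuple[str, ...]
    n_reads: int


def _default_species() -> tuple[SpeciesSim, ...]:
    by_label: dict[str, list[str]] = {}
    for t in DEFAULT_MID_TAGS:
        by_label.setdefault(t.species, []).append(t.tag)
    return tuple(
        SpeciesSim(label, tuple(tags), 1000) for label, tags in by_label.items()
    )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated run; defaults mirror the modeled study design.

    ``repeat_incidence`` is the fraction of reads carrying a planted passing
    repeat (a few percent, as in enriched tetra-nucleotide libraries);
    ``decoy_mix`` assigns read fractions to the decoy classes and must sum
    with the incidence to at most 1.  Remaining reads are pure background.
    """

    seed: int = 0
    species: tuple[SpeciesSim, ...] = field(default_factory=_default_species)
    read_length: tuple[int, int] = (200, 600)
    repeat_incidence: float = 0.03
    motif_pool: tuple[str, ...] = PROBE_MOTIFS
    unit_count: tuple[int, int] = (10, 30)
    decoy_units: tuple[int, int] = (5, 9)
    pass_flank_min: int = 26
    fail_flank: int = 24
    decoy_mix: dict = field(
        default_factory=lambda: {
            "low_unit": 0.02,
            "interrupted": 0.01,
            "short_flank": 0.01,
            "homopolymer_flank": 0.01,
            "low_quality": 0.01,
        }
    )
    pass_quality_range: tuple[float, float] = (28.0, 36.0)
    low_quality_range: tuple[float, float] = (12.0, 17.0)
    quality_jitter_sd: float = 2.0

    def validate(self) -> None:
        fractions = [self.repeat_incidence] + [
            self.decoy_mix.get(c, 0.0) for c in DECOY_CLASSES
        ]
        if any(f < 0 or f > 1 for f in fractions) or sum(fractions) > 1 + 1e-12:
            raise SimConfigError("class fractions must lie in [0,1] and sum to <= 1")
        unknown = set(self.decoy_mix) - set(DECOY_CLASSES)
        if unknown:
            raise SimConfigError(f"unknown decoy classes: {sorted(unknown)}")
        mid_len = max((len(t) for sp in self.species for t in sp.tags), default=0)
        need = (
            mid_len
            + 4 * self.unit_count[1]
            + 2 * self.pass_flank_min
        )
        if self.read_length[0] < need:
            raise SimConfigError(
                f"read_length[0]={self.read_length[0]} cannot hold MID + "
                f"{self.unit_count[1]} units + two {self.pass_flank_min} bp flanks "
                f"(needs >= {need})"
            )
        for m in self.motif_pool:
            if len(m) != 4 or m[:2] == m[2:]:
                raise SimConfigError(f"motif {m!r} is not a minimal-period-4 tetramer")


# ---------------------------------------------------------------------------
# Sequence assembly helpers
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_flank(
    rng: np.random.Generator,
    length: int,
    left_junction_base: Optional[str] = None,
    right_junction_base: Optional[str] = None,
    min_units_guard: int = 10,
) -> str:
    """Background flank with no qualifying repeat and no homopolymer > 5.

    ``left_junction_base`` / ``right_junction_base`` are bases the flank's
    first / last position must differ from, which prevents the flank from
    extending the period of an adjacent planted repeat.
    """
    if length == 0:
        return ""
    while True:
        flank = "".join(rng.choice(_BASES, size=length))
        if right_junction_base is not None and flank[-1] == right_junction_base:
            continue
        if left_junction_base is not None and flank[0] == left_junction_base:
            continue
        if longest_run(flank) > 5:
            continue
        if find_perfect_repeats(flank, min_units=min_units_guard):
            continue
        return flank


def _plant_homopolymer(rng: np.random.Generator, flank: str) -> str:
    """Overwrite a 6-base window of the flank with one repeated base.

    The window is kept >= 1 bp away from both flank ends so junction
    constraints and neighboring segments are untouched; retries until the
    result still contains no qualifying repeat and exactly one >5 run.
    """
    if len(flank) < 8:
        raise SimConfigError("flank too short to plant a homopolymer run")
    while True:
        pos = int(rng.integers(1, len(flank) - 7 + 1))
        base = str(rng.choice(_BASES))
        new = flank[:pos] + base * 6 + flank[pos + 6 :]
        if new[0] != flank[0] or new[-1] != flank[-1]:
            continue
        if longest_run(new) != 6:
            continue
        if find_perfect_repeats(new, min_units=10):
            continue
        return new


def _interrupter(rng: np.random.Generator, motif: str) -> str:
    """A base that breaks the repeat period between two same-phase halves.

    Placed between ``motif * u1`` and ``motif * u2`` it must differ from
    motif[0] (else it continues the first half / left-extends the second
    half's trailing partials) and from motif[3] (else the second half's
    region extends left across it).
    """
    banned = {motif[0], motif[3]}
    choices = [b for b in "ACGT" if b not in banned]
    return str(rng.choice(np.array(choices)))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate(config: SimConfig) -> tuple[list[Read], pd.DataFrame]:
    """Generate reads plus a one-row-per-read truth manifest.

    Reads carry the MID prefix and full-length qualities; manifest
    coordinates (``start``, ``end``, flanks) refer to the MID-trimmed read,
    matching what the cascade sees after demultiplexing.  Reproducible:
    identical configs (including seed) give identical reads and manifest.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    class_labels = ["candidate"] + list(DECOY_CLASSES) + ["background"]
    probs = [config.repeat_incidence] + [
        config.decoy_mix.get(c, 0.0) for c in DECOY_CLASSES
    ]
    probs.append(max(0.0, 1.0 - sum(probs)))
    reads: list[Read] = []
    rows: list[dict] = []
    counter = 0
    for sp in config.species:
        for _ in range(sp.n_reads):
            counter += 1
            read_id = f"sim{counter:06d}"
            tag = str(rng.choice(np.array(sp.tags)))
            cls = class_labels[int(rng.choice(len(class_labels), p=probs))]
            total_len = int(rng.integers(config.read_length[0],
                                         config.read_length[1] + 1))
            body_len = total_len - len(tag)
            row = {
                "read_id": read_id,
                "species": sp.label,
                "tag": tag,
                "decoy_class": cls,
                "has_repeat": False,
                "motif": None,
                "unit_count": 0,
                "start": -1,
                "end": -1,
                "left_flank": -1,
                "right_flank": -1,
                "homopolymer_planted": False,
            }
            if cls == "background":
                body = _random_flank(rng, body_len)
            else:
                motif = str(rng.choice(np.array(config.motif_pool)))
                lo_d, hi_d = config.decoy_units
                if cls == "low_unit":
                    units = int(rng.integers(lo_d, hi_d + 1))
                    repeat = motif * units
                elif cls == "interrupted":
                    u1 = int(rng.integers(lo_d, hi_d + 1))
                    u2 = int(rng.integers(lo_d, hi_d + 1))
                    repeat = motif * u1 + _interrupter(rng, motif) + motif * u2
                    units = max(u1, u2)
                else:
                    units = int(rng.integers(config.unit_count[0],
                                             config.unit_count[1] + 1))
                    repeat = motif * units
                flank_total = body_len - len(repeat)
                min_f = config.pass_flank_min
                if flank_total < 2 * min_f:  # long repeat in a short read
                    body_len = len(repeat) + 2 * min_f + 10
                    flank_total = body_len - len(repeat)
                    total_len = body_len + len(tag)
                if cls == "short_flank":
                    # one flank exactly fail_flank bp, the other takes the rest
                    if int(rng.integers(0, 2)) == 0:
                        left_len = config.fail_flank
                    else:
                        left_len = flank_total - config.fail_flank
                else:
                    left_len = int(rng.integers(min_f, flank_total - min_f + 1))
                right_len = flank_total - left_len
                left = _random_flank(
                    rng, left_len, right_junction_base=repeat[3] if len(repeat) >= 4
                    else None
                )
                right = _random_flank(
                    rng, right_len,
                    left_junction_base=repeat[-4] if len(repeat) >= 4 else None,
                )
                if cls == "homopolymer_flank":
                    if int(rng.integers(0, 2)) == 0 and left_len >= 8:
                        left = _plant_homopolymer(rng, left)
                    else:
                        right = _plant_homopolymer(rng, right)
                    row["homopolymer_planted"] = True
                body = left + repeat + right
                if cls == "interrupted":
                    row.update(
                        {"has_repeat": False, "motif": motif, "unit_count": units}
                    )
                elif cls == "low_unit":
                    row.update(
                        {"has_repeat": False, "motif": motif, "unit_count": units}
                    )
                else:
                    row.update(
                        {
                            "has_repeat": True,
                            "motif": motif,
                            "unit_count": units,
                            "start": len(left),
                            "end": len(left) + len(repeat),
                            "left_flank": len(left),
                            "right_flank": len(right),
                        }
                    )
            # qualities over the full read (MID included)
            if cls == "low_quality":
                mean_q = rng.uniform(*config.low_quality_range)
            else:
                mean_q = rng.uniform(*config.pass_quality_range)
            qual = np.clip(
                np.rint(rng.normal(mean_q, config.quality_jitter_sd,
                                   size=len(tag) + len(body))),
                0, 40,
            ).astype(int)
            read = Read(read_id, tag + body, tuple(int(q) for q in qual))
            reads.append(read)
            row["mean_quality"] = float(np.mean(qual[len(tag):]))
            rows.append(row)
    manifest = pd.DataFrame(rows)
    if not manifest.empty:
        thresholds = CascadeConfig()
        manifest["expected_fate"] = [
            _expected_fate(r, thresholds) for r in manifest.to_dict("records")
        ]
    else:
        manifest["expected_fate"] = pd.Series(dtype=object)
    return reads, manifest


def _expected_fate(row: dict, thresholds: CascadeConfig) -> str:
    """Cascade fate implied by planted attributes alone (primer stage excluded)."""
    if not row["has_repeat"] or row["unit_count"] < thresholds.min_units:
        return "no_repeat"
    if min(row["left_flank"], row["right_flank"]) < thresholds.min_flank:
        return "flank"
    if row["homopolymer_planted"]:
        return "homopolymer"
    if row["mean_quality"] < thresholds.min_quality:
        return "quality"
    return "candidate"


def expected_tally(
    manifest: pd.DataFrame, thresholds: Optional[CascadeConfig] = None
) -> dict[str, StageCounts]:
    """Stage counts the cascade must produce, from planted attributes only.

    The primer-design stage is excluded: background flanks carry no
    engineered primer sites, so primer success is not predictable from the
    manifest.
    """
    thresholds = thresholds or CascadeConfig()
    out: dict[str, StageCounts] = {}
    if manifest.empty:
        return out
    for row in manifest.to_dict("records"):
        tally = out.setdefault(row["species"], StageCounts())
        tally.n_reads += 1
        fate_rank = {
            "no_repeat": 0, "flank": 1, "homopolymer": 2, "quality": 3,
            "candidate": 4,
        }[_expected_fate(row, thresholds)]
        if fate_rank >= 1:
            tally.mined += 1
        if fate_rank >= 2:
            tally.flank_pass += 1
        if fate_rank >= 3:
            tally.clean_flanks += 1
        if fate_rank >= 4:
            tally.quality_pass += 1
    return out


def write_outputs(
    reads: list[Read],
    manifest: pd.DataFrame,
    outdir,
) -> dict[str, str]:
    """Write FASTA+QUAL, FASTQ, and the manifest TSV under ``outdir``."""
    from pathlib import Path

    from msatpal.seqio_demux import write_fastq, write_sequences

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": str(outdir / "reads.fasta"),
        "qual": str(outdir / "reads.qual"),
        "fastq": str(outdir / "reads.fastq"),
        "manifest": str(outdir / "manifest.tsv"),
    }
    write_sequences(reads, paths["fasta"], paths["qual"])
    write_fastq(reads, paths["fastq"])
    manifest.to_csv(paths["manifest"], sep="\t", index=False)
    return paths
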