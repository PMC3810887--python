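"""Filter cascade turning repeat hits into primer-ready candidate loci.

Stages, in order, per repeat-bearing read:

1. flank length      — >= 25 bp of sequence on each side of the repeat
2. clean flanks      — no homopolymer run longer than 5 bp in either flank
3. read quality      — mean per-base Phred-like score >= 20
4. primer screen     — a simplified primer-suitability scan of both flanks

The primer screen is deliberately a compact, fully pinned stand-in for a
general primer-design tool: it slides windows of 18-27 bp over each flank,
computes nearest-neighbor melting temperatures (Allawi & SantaLucia 1997
table, 50 mM Na+, 250 nM primer, entropy salt correction), and returns the
pair whose Tm values are jointly closest to the 60 degC optimum subject to
Tm, GC, homopolymer and 3'-complementarity constraints.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.SeqUtils import MeltingTemp as mt

from msatpal.dna import COMPLEMENT, longest_run, revcomp
from msatpal.repeat_miner import RepeatHit, find_perfect_repeats, select_primary_hit
from msatpal.seqio_demux import Read

logger = logging.getLogger(__name__)

STAGES = ("mined", "flank_pass", "clean_flanks", "quality_pass", "primer_designed")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimerScreenConfig:
    """All thresholds of the primer-suitability screen, in one place.

    Tm parameters are pinned so results are reproducible: nearest-neighbor
    table DNA_NN3, monovalent salt ``na_mM`` (mM), equal strand
    concentrations ``dnac_nM`` (nM), salt correction applied to entropy.
    """

    min_len: int = 18
    max_len: int = 27
    tm_opt: float = 60.0
    tm_min: float = 57.0
    tm_max: float = 63.0
    gc_min: float = 0.20
    gc_max: float = 0.80
    max_homopolymer: int = 4
    gc_clamp: bool = False
    max_3prime_complementarity: int = 3
    na_mM: float = 50.0
    dnac_nM: float = 250.0
    max_candidates_per_flank: int = 50


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds of the full cascade; defaults are the pipeline's standard run."""

    unit_len: int = 4
    min_units: int = 10
    min_flank: int = 25
    max_homopolymer: int = 5
    min_quality: int = 20
    quality_mode: str = "mean_read"  # or "min_flank"
    screen_primers: bool = True
    primer: PrimerScreenConfig = field(default_factory=PrimerScreenConfig)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair spanning the repeat.

    ``reverse`` is given 5'->3' on the opposite strand; ``fwd_start`` and
    ``rev_end`` delimit the amplicon in read coordinates (half-open).
    """

    forward: str
    reverse: str
    fwd_start: int
    rev_end: int
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float

    @property
    def amplicon_length(self) -> int:
        return self.rev_end - self.fwd_start


@dataclass
class CandidateLocus:
    """A repeat hit annotated with its progress through the cascade."""

    hit: RepeatHit
    read: Read
    flank_ok: bool = False
    homopolymer_ok: bool = False
    quality_ok: bool = False
    primer_pair: Optional[PrimerPair] = None
    stage_reached: str = "mined"


@dataclass
class StageCounts:
    """Per-species survivor counts at every cascade stage."""

    n_reads: int = 0
    mined: int = 0
    flank_pass: int = 0
    clean_flanks: int = 0
    quality_pass: int = 0
    primer_designed: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "n_reads": self.n_reads,
            "mined": self.mined,
            "flank_pass": self.flank_pass,
            "clean_flanks": self.clean_flanks,
            "quality_pass": self.quality_pass,
            "primer_designed": self.primer_designed,
        }


# ---------------------------------------------------------------------------
# Individual filters
# ---------------------------------------------------------------------------

def check_flanks(hit: RepeatHit, min_flank: int = 25) -> bool:
    """True iff both flanks are at least ``min_flank`` bp ("at least" = inclusive)."""
    return hit.left_flank >= min_flank and hit.right_flank >= min_flank


def check_homopolymer(hit: RepeatHit, read: Read, max_run: int = 5) -> bool:
    """True iff neither flank contains a single-base run longer than ``max_run``.

    Only the flanks are scanned: a perfect minimal-period-4 repeat region
    cannot itself contain a run longer than 5.
    """
    left = read.sequence[: hit.start]
    right = read.sequence[hit.end :]
    return longest_run(left) <= max_run and longest_run(right) <= max_run


def check_quality(
    read: Read,
    min_score: int = 20,
    hit: Optional[RepeatHit] = None,
    mode: str = "mean_read",
) -> bool:
    """Quality filter for one read.

    Default mode ``mean_read``: mean per-base score over the (MID-trimmed)
    read >= ``min_score``; the boundary is kept (scores *below* the cutoff
    are discarded).  Mode ``min_flank``: minimum per-base score over the
    flanks must reach the cutoff (requires ``hit``).  Reads without quality
    values pass with a logged warning.
    """
    if read.quality is None:
        logger.warning("read %s has no quality values; quality filter passed",
                       read.read_id)
        return True
    if mode == "mean_read":
        return read.mean_quality >= min_score
    if mode == "min_flank":
        if hit is None:
            raise ValueError("min_flank quality mode requires the repeat hit")
        flank_scores = read.quality[: hit.start] + read.quality[hit.end :]
        return bool(flank_scores) and min(flank_scores) >= min_score
    raise ValueError(f"unknown quality mode {mode!r}")


# ---------------------------------------------------------------------------
# Melting temperature (vectorized nearest-neighbor model)
# ---------------------------------------------------------------------------

_NN_TABLE = mt.DNA_NN3
_R_GAS = 1.987  # cal / (K mol)


def _stack_params() -> tuple[np.ndarray, np.ndarray]:
    """(dH, dS) for each of the 16 dinucleotide stacks, indexed 4*b1+b2."""
    dh = np.zeros(16)
    ds = np.zeros(16)
    bases = "ACGT"
    for i, b1 in enumerate(bases):
        for j, b2 in enumerate(bases):
            dinuc = b1 + b2
            key = dinuc + "/" + COMPLEMENT[b1] + COMPLEMENT[b2]
            if key not in _NN_TABLE:
                key = key[::-1]
            dh[4 * i + j], ds[4 * i + j] = _NN_TABLE[key]
    return dh, ds


_STACK_DH, _STACK_DS = _stack_params()
_INIT = _NN_TABLE["init"]
_INIT_AT = _NN_TABLE["init_A/T"]
_INIT_GC = _NN_TABLE["init_G/C"]
_INIT_ALL_AT = _NN_TABLE["init_allA/T"]
_INIT_ONE_GC = _NN_TABLE["init_oneG/C"]
_INIT_5T = _NN_TABLE["init_5T/A"]


class _FlankScanner:
    """Vectorized window scan of one flank sequence.

    Precomputes cumulative stack enthalpies/entropies so that the melting
    temperature of every window of every length costs O(1); numerically
    identical to Bio.SeqUtils.MeltingTemp.Tm_NN with the same parameters.
    """

    def __init__(self, seq: str, cfg: PrimerScreenConfig):
        self.seq = seq.upper()
        self.cfg = cfg
        n = len(self.seq)
        codes = np.full(n, -1, dtype=np.int64)
        for i, b in enumerate("ACGT"):
            codes[np.frombuffer(self.seq.encode(), dtype=np.uint8) == ord(b)] = i
        self.codes = codes
        self.valid = codes >= 0
        gc = (codes == 1) | (codes == 2)
        self.cum_gc = np.concatenate(([0], np.cumsum(gc)))
        self.cum_valid = np.concatenate(([0], np.cumsum(self.valid)))
        if n >= 2:
            dinuc = 4 * codes[:-1] + codes[1:]
            ok = (codes[:-1] >= 0) & (codes[1:] >= 0)
            dinuc = np.where(ok, dinuc, 0)
            self.cum_dh = np.concatenate(([0.0], np.cumsum(_STACK_DH[dinuc])))
            self.cum_ds = np.concatenate(([0.0], np.cumsum(_STACK_DS[dinuc])))
        else:
            self.cum_dh = np.zeros(1)
            self.cum_ds = np.zeros(1)
        # bad5[i] = disallowed run (max_homopolymer + 1 identical bases) ends at i
        bad_len = cfg.max_homopolymer + 1
        bad5 = np.zeros(n, dtype=bool)
        if n >= bad_len:
            same = codes[1:] == codes[:-1]
            run = np.zeros(n, dtype=np.int64)
            run[0] = 1
            for i in range(1, n):  # short flanks; plain loop is fine
                run[i] = run[i - 1] + 1 if same[i - 1] else 1
            bad5 = run >= bad_len
        self.cum_bad5 = np.concatenate(([0], np.cumsum(bad5)))
        self.mon = cfg.na_mM * 1e-3
        self.log_k = math.log((cfg.dnac_nM - cfg.dnac_nM / 2.0) * 1e-9)


def _window_arrays(sc: _FlankScanner, length: int):
    """(offsets, tm, gc_frac, constraint_mask) for all windows of ``length``."""
    n = len(sc.seq)
    cfg = sc.cfg
    if n < length:
        e = np.empty(0)
        return e.astype(int), e, e, e.astype(bool)
    offs = np.arange(0, n - length + 1)
    all_acgt = (sc.cum_valid[offs + length] - sc.cum_valid[offs]) == length
    gc_count = sc.cum_gc[offs + length] - sc.cum_gc[offs]
    gc_frac = gc_count / length
    lo = offs + cfg.max_homopolymer
    hi = np.minimum(offs + length, n)
    runs_ok = (sc.cum_bad5[hi] - sc.cum_bad5[np.minimum(lo, n)]) == 0
    dh = sc.cum_dh[offs + length - 1] - sc.cum_dh[offs] + _INIT[0]
    ds = sc.cum_ds[offs + length - 1] - sc.cum_ds[offs] + _INIT[1]
    first = sc.codes[offs]
    last = sc.codes[offs + length - 1]
    n_at = ((first == 0) | (first == 3)).astype(int) + (
        (last == 0) | (last == 3)
    ).astype(int)
    n_gc = ((first == 1) | (first == 2)).astype(int) + (
        (last == 1) | (last == 2)
    ).astype(int)
    dh = dh + _INIT_AT[0] * n_at + _INIT_GC[0] * n_gc
    ds = ds + _INIT_AT[1] * n_at + _INIT_GC[1] * n_gc
    all_at = gc_count == 0
    dh = dh + np.where(all_at, _INIT_ALL_AT[0], _INIT_ONE_GC[0])
    ds = ds + np.where(all_at, _INIT_ALL_AT[1], _INIT_ONE_GC[1])
    starts_t = (first == 3).astype(int)
    ends_a = (last == 0).astype(int)
    dh = dh + _INIT_5T[0] * (starts_t + ends_a)
    ds = ds + _INIT_5T[1] * (starts_t + ends_a)
    salt = 0.368 * (length - 1) * math.log(sc.mon)
    with np.errstate(divide="ignore", invalid="ignore"):
        tm = (1000.0 * dh) / (ds + salt + _R_GAS * sc.log_k) - 273.15
    mask = (
        all_acgt
        & runs_ok
        & (gc_frac >= cfg.gc_min)
        & (gc_frac <= cfg.gc_max)
        & (tm >= cfg.tm_min)
        & (tm <= cfg.tm_max)
    )
    if cfg.gc_clamp:
        mask &= (last == 1) | (last == 2)
    return offs, tm, gc_frac, mask


def primer_tm(seq: str, cfg: Optional[PrimerScreenConfig] = None) -> float:
    """Melting temperature of one primer under the pinned model."""
    cfg = cfg or PrimerScreenConfig()
    sc = _FlankScanner(seq, cfg)
    offs, tm, _, _ = _window_arrays(sc, len(seq))
    return float(tm[0])


def _flank_candidates(seq: str, cfg: PrimerScreenConfig):
    """Valid primer windows of a flank: list of (score, offset, length, tm, gc)."""
    sc = _FlankScanner(seq, cfg)
    out = []
    for length in range(cfg.min_len, cfg.max_len + 1):
        offs, tm, gc, mask = _window_arrays(sc, length)
        for idx in np.flatnonzero(mask):
            out.append(
                (abs(tm[idx] - cfg.tm_opt), int(offs[idx]), length,
                 float(tm[idx]), float(gc[idx]))
            )
    out.sort(key=lambda c: (c[0], c[2], c[1]))
    return out[: cfg.max_candidates_per_flank]


def three_prime_complementarity(forward: str, reverse: str) -> int:
    """Consecutive complementary base pairs at the two primers' 3' termini."""
    k = 0
    while (
        k < min(len(forward), len(reverse))
        and forward[-1 - k] == COMPLEMENT[reverse[-1 - k]]
    ):
        k += 1
    return k


def screen_primers(
    hit: RepeatHit, read: Read, params: Optional[PrimerScreenConfig] = None
) -> Optional[PrimerPair]:
    """Pick the best primer pair spanning the repeat, or None.

    Scans every window of length [min_len, max_len] in each flank, keeps
    windows satisfying the Tm/GC/homopolymer constraints, and returns the
    pair minimizing |Tm_f - opt| + |Tm_r - opt| among pairs whose 3' ends
    are complementary for at most ``max_3prime_complementarity`` consecutive
    bases; ties prefer the shorter amplicon.
    """
    cfg = params or PrimerScreenConfig()
    left = read.sequence[: hit.start]
    right = read.sequence[hit.end :]
    fwd_cands = _flank_candidates(left, cfg)
    if not fwd_cands:
        return None
    rcf = revcomp(right)  # windows of rcf are reverse primers, 5'->3'
    rev_cands = _flank_candidates(rcf, cfg)
    if not rev_cands:
        return None
    best = None
    n_right = len(right)
    for fs, fa, fl, ftm, fgc in fwd_cands:
        fseq = left[fa : fa + fl]
        for rs, rb, rl, rtm, rgc in rev_cands:
            rseq = rcf[rb : rb + rl]
            if three_prime_complementarity(fseq, rseq) > cfg.max_3prime_complementarity:
                continue
            rev_end = hit.end + n_right - rb
            amplicon = rev_end - fa
            key = (fs + rs, amplicon, fa, rev_end)
            if best is None or key < best[0]:
                best = (
                    key,
                    PrimerPair(fseq, rseq, fa, rev_end, ftm, rtm, fgc, rgc),
                )
    return best[1] if best else None


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def run_cascade(
    reads_by_species: dict[str, list[Read]],
    config: Optional[CascadeConfig] = None,
) -> tuple[list[CandidateLocus], dict[str, StageCounts]]:
    """Apply mine -> primary hit -> flank -> homopolymer -> quality -> primers.

    Returns every mined locus annotated with the stage it reached, plus
    per-species survivor counts at each stage.  Each read is processed
    independently, so tallies are invariant to input order.
    """
    config = config or CascadeConfig()
    loci: list[CandidateLocus] = []
    counts: dict[str, StageCounts] = {}
    for species, reads in reads_by_species.items():
        tally = counts.setdefault(species, StageCounts())
        for read in reads:
            tally.n_reads += 1
            hits = find_perfect_repeats(
                read.sequence,
                unit_len=config.unit_len,
                min_units=config.min_units,
                read_id=read.read_id,
            )
            hit = select_primary_hit(hits)
            if hit is None:
                continue
            tally.mined += 1
            locus = CandidateLocus(hit=hit, read=read)
            loci.append(locus)
            if not check_flanks(hit, config.min_flank):
                logger.debug("read %s dropped at flank stage", read.read_id)
                continue
            locus.flank_ok = True
            locus.stage_reached = "flank_pass"
            tally.flank_pass += 1
            if not check_homopolymer(hit, read, config.max_homopolymer):
                logger.debug("read %s dropped at homopolymer stage", read.read_id)
                continue
            locus.homopolymer_ok = True
            locus.stage_reached = "clean_flanks"
            tally.clean_flanks += 1
            if not check_quality(
                read, config.min_quality, hit=hit, mode=config.quality_mode
            ):
                logger.debug("read %s dropped at quality stage", read.read_id)
                continue
            locus.quality_ok = True
            locus.stage_reached = "quality_pass"
            tally.quality_pass += 1
            if config.screen_primers:
                pair = screen_primers(hit, read, config.primer)
                if pair is not None:
                    locus.primer_pair = pair
                    locus.stage_reached = "primer_designed"
                    tally.primer_designed += 1
    return loci, counts
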