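"""SIPL/NTPP extrapolation of potentially amplifiable loci (PALs).

The estimator takes, per species, the wet-lab outcome of a marker-development
run — the number of tested primer pairs (NTPP) and the subset confirmed
polymorphic (SIPL) — and extrapolates the SIPL/NTPP ratio to every sequence
that survived the candidate filters, giving an expected PAL count and an
overall success rate (PALs / total reads of the species).

All ratios are exact ``fractions.Fraction`` values so that rounding ties are
well-defined: PAL counts round half *down* (the convention consistent with
every published value this pipeline reproduces, including an exact .5 tie),
while printed percentages round half *up* at the requested precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP, localcontext
from fractions import Fraction
from typing import Optional, Sequence, Union

import pandas as pd

Ratio = Union[Fraction, float, int]


class TallyValidationError(ValueError):
    """A SpeciesTally violates the stage-count ordering invariants."""


@dataclass(frozen=True)
class SpeciesTally:
    """Per-species stage counts feeding the PAL estimate.

    ``n_reads`` >= ``n_repeat_reads`` >= ``n_candidates`` >= ``ntpp`` >=
    ``sipl`` >= 0.  NTPP and SIPL are wet-lab outcomes supplied by the user,
    not computed by the pipeline; they may be absent.
    """

    species: str
    n_reads: int
    n_repeat_reads: int
    n_candidates: int
    ntpp: Optional[int] = None
    sipl: Optional[int] = None

    def __post_init__(self):
        chain = [
            ("n_reads", self.n_reads),
            ("n_repeat_reads", self.n_repeat_reads),
            ("n_candidates", self.n_candidates),
        ]
        if self.ntpp is not None:
            chain.append(("ntpp", self.ntpp))
        if self.sipl is not None:
            if self.ntpp is None:
                raise TallyValidationError(
                    f"{self.species}: sipl given without ntpp"
                )
            chain.append(("sipl", self.sipl))
        for (name_hi, hi), (name_lo, lo) in zip(chain, chain[1:]):
            if lo > hi:
                raise TallyValidationError(
                    f"{self.species}: {name_lo}={lo} exceeds {name_hi}={hi}"
                )
        if chain[-1][1] < 0:
            raise TallyValidationError(f"{self.species}: negative count")


@dataclass(frozen=True)
class PalEstimate:
    """SIPL/NTPP ratio, extrapolated PAL count, and success rate for one species."""

    ratio: Fraction
    pals: int
    success_rate: Fraction


def sipl_ntpp_ratio(sipl: int, ntpp: int) -> Fraction:
    """Exact SIPL/NTPP quotient."""
    if ntpp <= 0:
        raise ZeroDivisionError("SIPL/NTPP ratio undefined for ntpp <= 0")
    if not 0 <= sipl <= ntpp:
        raise ValueError(f"need 0 <= sipl <= ntpp, got sipl={sipl}, ntpp={ntpp}")
    return Fraction(sipl, ntpp)


def extrapolate_pals(ratio: Ratio, n_candidates: int) -> int:
    """Expected PAL count: ratio x candidates, rounded half-down to an integer.

    Exact halves round down; pass a Fraction ratio for ties to be exact
    (floats cannot represent most quotients exactly).
    """
    if n_candidates < 0:
        raise ValueError("n_candidates must be >= 0")
    q = Fraction(ratio) * n_candidates
    if not 0 <= q <= n_candidates:
        raise ValueError(f"ratio {ratio!r} outside [0, 1]")
    # round half down == ceil(q - 1/2)
    return math.ceil(q - Fraction(1, 2))


def success_rate(pals: int, n_reads: int) -> Fraction:
    """Overall success rate: extrapolated PALs over the species' read count."""
    if n_reads <= 0:
        raise ZeroDivisionError("success rate undefined for n_reads <= 0")
    return Fraction(pals, n_reads)


def format_percent(x: Ratio, decimals: int = 2) -> str:
    """Render a fraction as a percentage, rounded half-up at ``decimals``."""
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    with localcontext() as ctx:
        ctx.prec = 60
        if isinstance(x, Fraction):
            value = Decimal(x.numerator) / Decimal(x.denominator) * 100
        else:
            value = Decimal(repr(float(x))) * 100
        quantum = Decimal(1).scaleb(-decimals)
        return f"{value.quantize(quantum, rounding=ROUND_HALF_UP)}%"


def estimate_pals(tally: SpeciesTally) -> PalEstimate:
    """Full step-I estimate for one species (requires ntpp and sipl)."""
    if tally.ntpp is None or tally.sipl is None:
        raise TallyValidationError(
            f"{tally.species}: PAL estimation requires ntpp and sipl"
        )
    ratio = sipl_ntpp_ratio(tally.sipl, tally.ntpp)
    pals = extrapolate_pals(ratio, tally.n_candidates)
    return PalEstimate(ratio, pals, success_rate(pals, tally.n_reads))


def build_report(tallies: Sequence[SpeciesTally], decimals: int = 2) -> pd.DataFrame:
    """Per-species marker-development report plus a pooled total row.

    Columns: read counts and demultiplex shares, repeat-bearing counts and
    per-species percentages, candidate counts, NTPP, SIPL, SIPL/NTPP ratio,
    extrapolated PALs, and the success-rate percentage.  The total row pools
    counts; its ratio uses pooled SIPL/NTPP and its PAL count is the sum of
    the per-species extrapolations.
    """
    tallies = list(tallies)
    if not tallies:
        raise TallyValidationError("no tallies supplied")
    total_reads = sum(t.n_reads for t in tallies)
    rows = []
    total = {
        "pals": 0,
        "sipl": 0,
        "ntpp": 0,
        "have_lab": all(t.ntpp is not None and t.sipl is not None for t in tallies),
    }
    for t in tallies:
        row = {
            "species": t.species,
            "n_reads": t.n_reads,
            "read_share": format_percent(Fraction(t.n_reads, total_reads), decimals),
            "n_repeat_reads": t.n_repeat_reads,
            "repeat_share": format_percent(
                Fraction(t.n_repeat_reads, t.n_reads), decimals
            ),
            "n_candidates": t.n_candidates,
            "ntpp": t.ntpp,
            "sipl": t.sipl,
        }
        if t.ntpp is not None and t.sipl is not None:
            est = estimate_pals(t)
            row.update(
                {
                    "sipl_ntpp": format_percent(est.ratio, decimals),
                    "pals": est.pals,
                    "success_rate": format_percent(est.success_rate, decimals),
                }
            )
            total["pals"] += est.pals
            total["sipl"] += t.sipl
            total["ntpp"] += t.ntpp
        else:
            row.update({"sipl_ntpp": None, "pals": None, "success_rate": None})
        rows.append(row)
    total_row = {
        "species": "Total",
        "n_reads": total_reads,
        "read_share": format_percent(Fraction(1), decimals),
        "n_repeat_reads": sum(t.n_repeat_reads for t in tallies),
        "repeat_share": format_percent(
            Fraction(sum(t.n_repeat_reads for t in tallies), total_reads), decimals
        ),
        "n_candidates": sum(t.n_candidates for t in tallies),
        "ntpp": total["ntpp"] if total["have_lab"] else None,
        "sipl": total["sipl"] if total["have_lab"] else None,
        "sipl_ntpp": (
            format_percent(Fraction(total["sipl"], total["ntpp"]), decimals)
            if total["have_lab"] and total["ntpp"]
            else None
        ),
        "pals": total["pals"] if total["have_lab"] else None,
        "success_rate": (
            format_percent(Fraction(total["pals"], total_reads), decimals)
            if total["have_lab"]
            else None
        ),
    }
    rows.append(total_row)
    return pd.DataFrame(rows)


def report_to_markdown(report: pd.DataFrame) -> str:
    """Render the report as a GitHub-style markdown table."""
    cols = list(report.columns)
    header = "| " + " | ".join(cols) + " |"
    sep = "| " + " | ".join("---" for _ in cols) + " |"
    lines = [header, sep]
    for _, row in report.iterrows():
        cells = ["" if pd.isna(row[c]) else str(row[c]) for c in cols]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def report_to_json(report: pd.DataFrame) -> str:
    """Serialize the report as JSON records."""
    records = report.where(pd.notna(report), None).to_dict(orient="records")
    return json.dumps(records, indent=2)
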