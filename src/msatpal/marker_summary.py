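"""Marker characterization from genotype tables.

Summarizes diploid allele-size calls (individual x locus) into the standard
SSR marker descriptors: number of alleles, fragment size range, observed and
unbiased expected heterozygosity, and an exact (or Monte Carlo) test of
Hardy-Weinberg equilibrium conditioned on the observed allele counts.  A
cross-amplification summary reports, per locus, whether another species'
primers amplified at all and whether the locus is polymorphic there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np
import pandas as pd


class NoDataError(ValueError):
    """A locus has no (or too few) non-missing calls for the statistic."""


Call = Optional[tuple[int, int]]


@dataclass
class GenotypeTable:
    """Diploid allele-size calls for individuals (with population labels) x loci.

    ``calls[(individual, locus)]`` is a sorted pair of positive allele sizes
    (bp) or None/absent for missing data.
    """

    individuals: list[tuple[str, str]]  # (individual id, population)
    loci: list[str]
    calls: dict[tuple[str, str], Call]

    def __post_init__(self):
        for key, call in self.calls.items():
            if call is None:
                continue
            a, b = call
            if a <= 0 or b <= 0:
                raise ValueError(f"{key}: allele sizes must be positive")
            if a > b:
                self.calls[key] = (b, a)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "GenotypeTable":
        """Build from a long-format frame: individual, population, locus, allele1, allele2."""
        individuals: list[tuple[str, str]] = []
        seen = set()
        loci: list[str] = []
        calls: dict[tuple[str, str], Call] = {}
        for rec in df.itertuples(index=False):
            ind = str(rec.individual)
            pop = str(getattr(rec, "population", ""))
            locus = str(rec.locus)
            if ind not in seen:
                seen.add(ind)
                individuals.append((ind, pop))
            if locus not in loci:
                loci.append(locus)
            a1, a2 = rec.allele1, rec.allele2
            if pd.isna(a1) or pd.isna(a2):
                calls[(ind, locus)] = None
            else:
                calls[(ind, locus)] = (int(a1), int(a2))
        return cls(individuals, loci, calls)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeTable":
        """Read a long-format TSV (blank allele cells = missing)."""
        df = pd.read_csv(path, sep="\t", dtype={"individual": str, "locus": str})
        return cls.from_long(df)

    def locus_calls(self, locus: str) -> list[tuple[int, int]]:
        """Non-missing calls for one locus, in individual order."""
        if locus not in self.loci:
            raise KeyError(f"unknown locus {locus!r}")
        out = []
        for ind, _pop in self.individuals:
            call = self.calls.get((ind, locus))
            if call is not None:
                out.append(call)
        return out


@dataclass(frozen=True)
class LocusSummary:
    locus: str
    n_alleles: int
    size_min: int
    size_max: int
    ho: float
    he: float
    hwe_p: float

    @property
    def polymorphic(self) -> bool:
        return self.n_alleles >= 2


def allele_stats(table: GenotypeTable, locus: str) -> tuple[int, int, int]:
    """(number of distinct alleles, min size, max size) over non-missing calls."""
    calls = table.locus_calls(locus)
    if not calls:
        raise NoDataError(f"locus {locus!r} has no non-missing calls")
    alleles = {a for call in calls for a in call}
    return len(alleles), min(alleles), max(alleles)


def heterozygosities(table: GenotypeTable, locus: str) -> tuple[float, float]:
    """Observed and unbiased expected heterozygosity for one locus.

    Ho is the fraction of heterozygous individuals.  He is Nei's unbiased
    expected heterozygosity, (2n / (2n - 1)) * (1 - sum p_i^2) with allele
    frequencies p_i taken over the 2n non-missing gene copies.
    """
    calls = table.locus_calls(locus)
    n = len(calls)
    if n < 2:
        raise NoDataError(f"locus {locus!r}: need >= 2 non-missing calls, got {n}")
    ho = sum(1 for a, b in calls if a != b) / n
    counts: dict[int, int] = {}
    for a, b in calls:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    two_n = 2 * n
    sum_p2 = sum((c / two_n) ** 2 for c in counts.values())
    he = (two_n / (two_n - 1)) * (1 - sum_p2)
    return ho, he


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def _genotype_counts(calls: list[tuple[int, int]]):
    """(allele list, genotype-count dict {(i<=j): count}, allele-count dict)."""
    alleles = sorted({a for call in calls for a in call})
    index = {a: i for i, a in enumerate(alleles)}
    geno: dict[tuple[int, int], int] = {}
    acount = [0] * len(alleles)
    for a, b in calls:
        i, j = sorted((index[a], index[b]))
        geno[(i, j)] = geno.get((i, j), 0) + 1
        acount[i] += 1
        acount[j] += 1
    return alleles, geno, acount


def _table_prob(geno: dict[tuple[int, int], int], acount: list[int]) -> Fraction:
    """Exact conditional probability (Levene) of a genotype table given allele counts.

    P = n! * prod_i(a_i!) * 2^H / ((2n)! * prod_{i<=j}(g_ij!)), H = number of
    heterozygous individuals.  Returned as an exact Fraction.
    """
    n = sum(geno.values())
    two_n = sum(acount)
    het = sum(c for (i, j), c in geno.items() if i != j)
    num = math.factorial(n) * (2 ** het)
    for a in acount:
        num *= math.factorial(a)
    den = math.factorial(two_n)
    for c in geno.values():
        den *= math.factorial(c)
    return Fraction(num, den)


def _enumerate_tables(acount: list[int]):
    """Yield all genotype-count dicts consistent with the given allele counts.

    Enumerates off-diagonal counts recursively; diagonals are then forced.
    Intended for <= 3 alleles where the space is small.
    """
    k = len(acount)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]

    def rec(idx: int, geno: dict[tuple[int, int], int]):
        if idx == len(pairs):
            diag = []
            ok = True
            for i in range(k):
                used = sum(
                    c for (a, b), c in geno.items() if a == i or b == i
                )
                rem = acount[i] - used
                if rem < 0 or rem % 2:
                    ok = False
                    break
                diag.append(rem // 2)
            if ok:
                full = dict(geno)
                for i, d in enumerate(diag):
                    if d:
                        full[(i, i)] = d
                yield full
            return
        i, j = pairs[idx]
        used_i = sum(c for (a, b), c in geno.items() if a == i or b == i)
        used_j = sum(c for (a, b), c in geno.items() if a == j or b == j)
        limit = min(acount[i] - used_i, acount[j] - used_j)
        for c in range(limit + 1):
            g = dict(geno)
            if c:
                g[(i, j)] = c
            yield from rec(idx + 1, g)

    yield from rec(0, {})


def hwe_exact(
    table: GenotypeTable,
    locus: str,
    n_permutations: int = 10000,
    seed: int = 0,
    force_monte_carlo: bool = False,
) -> float:
    """Exact / Monte Carlo Hardy-Weinberg test conditioned on allele counts.

    For loci with <= 3 alleles every genotype table with the observed allele
    counts is enumerated and the p-value is the exact probability of tables
    no more probable than the observed one.  For more alleles, gene copies
    are shuffled ``n_permutations`` times with the given seed and paired into
    genotypes; the p-value uses the (1 + hits) / (1 + permutations) estimator.
    """
    calls = table.locus_calls(locus)
    alleles, geno_obs, acount = _genotype_counts(calls)
    if len(alleles) < 2:
        raise NoDataError(f"locus {locus!r} is monomorphic; HWE test undefined")
    p_obs = _table_prob(geno_obs, acount)
    if len(alleles) <= 3 and not force_monte_carlo:
        total = Fraction(0)
        for geno in _enumerate_tables(acount):
            p = _table_prob(geno, acount)
            if p <= p_obs:
                total += p
        return float(total)
    # Monte Carlo: shuffle the vector of gene copies
    rng = np.random.default_rng(seed)
    copies = np.array(
        [i for i, c in enumerate(acount) for _ in range(c)], dtype=np.int64
    )
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(copies)
        geno: dict[tuple[int, int], int] = {}
        for a, b in copies.reshape(-1, 2):
            key = (int(min(a, b)), int(max(a, b)))
            geno[key] = geno.get(key, 0) + 1
        if _table_prob(geno, acount) <= p_obs:
            hits += 1
    return (1 + hits) / (1 + n_permutations)


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted per-test significance level: alpha / n_tests."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_loci(
    table: GenotypeTable, n_permutations: int = 10000, seed: int = 0
) -> list[LocusSummary]:
    """LocusSummary for every locus with >= 2 non-missing calls."""
    out = []
    for locus in table.loci:
        calls = table.locus_calls(locus)
        if len(calls) < 2:
            continue
        n_alleles, lo, hi = allele_stats(table, locus)
        ho, he = heterozygosities(table, locus)
        if n_alleles >= 2:
            p = hwe_exact(table, locus, n_permutations=n_permutations, seed=seed)
        else:
            p = float("nan")
        out.append(LocusSummary(locus, n_alleles, lo, hi, ho, he, p))
    return out


def cross_amp_summary(table: GenotypeTable) -> pd.DataFrame:
    """Cross-amplification outcome per locus.

    A locus with no non-missing calls did not amplify; otherwise it is
    polymorphic iff it shows >= 2 alleles.  The frame carries the columns
    ``locus, amplified, n_alleles, polymorphic`` plus summary attributes
    ``n_polymorphic``, ``n_monomorphic`` and ``n_failed`` in ``df.attrs``.
    """
    rows = []
    for locus in table.loci:
        calls = table.locus_calls(locus)
        if not calls:
            rows.append(
                {"locus": locus, "amplified": False, "n_alleles": 0,
                 "polymorphic": False}
            )
        else:
            n_alleles = len({a for call in calls for a in call})
            rows.append(
                {"locus": locus, "amplified": True, "n_alleles": n_alleles,
                 "polymorphic": n_alleles >= 2}
            )
    df = pd.DataFrame(
        rows, columns=["locus", "amplified", "n_alleles", "polymorphic"]
    )
    df.attrs["n_polymorphic"] = int(df["polymorphic"].sum())
    df.attrs["n_monomorphic"] = int((df["amplified"] & ~df["polymorphic"]).sum())
    df.attrs["n_failed"] = int((~df["amplified"]).sum())
    return df
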