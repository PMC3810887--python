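"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written by direct definition (periodic
extension, direct counting, closed-form probabilities) without reusing any
pipeline internals beyond trivially shared constants.
"""

import math
from collections import Counter
from fractions import Fraction
from itertools import groupby


def brute_force_repeats(seq: str, unit_len: int = 4, min_units: int = 2):
    """All maximal perfect repeats by direct periodic extension.

    For every start position, take the motif there, reject motifs that are a
    repetition of a shorter block, require left-maximality (the base before
    the start must not continue the period), extend right base by base while
    the period continues, and keep runs with enough complete units.
    Returns a set of (start, end, motif, unit_count) tuples.
    """
    s = seq.upper()
    n = len(s)
    hits = set()
    for start in range(n - unit_len + 1):
        motif = s[start : start + unit_len]
        if set(motif) - set("ACGT"):
            continue
        if any(
            unit_len % d == 0 and motif == motif[:d] * (unit_len // d)
            for d in range(1, unit_len)
        ):
            continue
        prev = start - 1
        if prev >= 0 and s[prev] in "ACGT" and s[prev] == s[prev + unit_len]:
            continue  # not the leftmost phase of this run
        end = start + unit_len
        while end < n and s[end] in "ACGT" and s[end] == s[end - unit_len]:
            end += 1
        units = (end - start) // unit_len
        if units >= min_units:
            hits.add((start, end, motif, units))
    return hits


def longest_identical_run(seq: str) -> int:
    """Longest run of identical characters, via itertools.groupby."""
    return max((len(list(g)) for _, g in groupby(seq)), default=0)


def direct_heterozygosities(calls):
    """(Ho, He) by direct counting over a list of (allele, allele) pairs."""
    n = len(calls)
    ho = sum(a != b for a, b in calls) / n
    copies = Counter()
    for a, b in calls:
        copies[a] += 1
        copies[b] += 1
    two_n = 2 * n
    he = (two_n / (two_n - 1)) * (1 - sum((c / two_n) ** 2 for c in copies.values()))
    return ho, he


def two_allele_conditional_prob(n11: int, n12: int, n22: int) -> Fraction:
    """Closed-form conditional probability of 2-allele genotype counts.

    P(n12 | a1, a2) = n! / (n11! n12! n22!) * 2^n12 * a1! a2! / (2n)!
    """
    n = n11 + n12 + n22
    a1 = 2 * n11 + n12
    a2 = 2 * n22 + n12
    return Fraction(
        math.factorial(n)
        * 2**n12
        * math.factorial(a1)
        * math.factorial(a2),
        math.factorial(n11)
        * math.factorial(n12)
        * math.factorial(n22)
        * math.factorial(2 * n),
    )


def two_allele_exact_p(n11: int, n12: int, n22: int) -> Fraction:
    """Exact HWE p-value for a 2-allele table, summing over heterozygote counts."""
    a1 = 2 * n11 + n12
    a2 = 2 * n22 + n12
    p_obs = two_allele_conditional_prob(n11, n12, n22)
    total = Fraction(0)
    for h in range(min(a1, a2) + 1):
        if (a1 - h) % 2 or (a2 - h) % 2:
            continue
        g11 = (a1 - h) // 2
        g22 = (a2 - h) // 2
        p = two_allele_conditional_prob(g11, h, g22)
        if p <= p_obs:
            total += p
    return total
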