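# Methods

This note documents the models, conventions, and numerical choices behind
`msatpal`, and what its synthetic-data validation does and does not
demonstrate.

## Demultiplexing

MID barcodes are matched as exact prefixes with 0 mismatches by default.
The tag set must be prefix-free (no tag a prefix of another), which makes
the assignment unambiguous; a configurable mismatch allowance (≤ 1 is the
intended use) exists for robustness experiments, under which an `N` base
never matches and a best-match tie between species leaves the read
unassigned. The MID is trimmed before mining, so flank-length accounting
never includes tag bases; this is the conservative choice, since tag bases
are not genomic sequence and could not serve as primer sites.

## Repeat model

A hit is a maximal run in which every position equals the position four
bases earlier (both unambiguous). "Tetra-nucleotide" is interpreted as
*minimal period exactly 4*: motifs that are a repetition of a 1- or 2-base
block (AAAA, ACAC, ATAT…) are rejected however long the run, because such
runs are homopolymers or dinucleotide repeats in disguise. All 13
enrichment-probe motifs used to build the libraries this pipeline models
have minimal period 4, so the interpretation costs nothing on-target. For
a run of at least two units the minimal period of the array necessarily
divides the unit length, so checking the divisor-blocks of the starting
motif is exact.

Runs are reported once each, at their leftmost phase; `end` includes
trailing bases that continue the period without completing a unit
(affecting flank lengths), while `unit_count` counts complete units only —
"at least ten repeat motifs" counts whole motifs. Interrupted repeats are
never merged. Whole-unit counting is a documented convention of this
implementation; repeat finders that score imperfect alignments or count
fractional units can differ at run boundaries.

The miner is validated against a brute-force periodic-extension oracle:
exhaustively on all 2-letter strings up to length 14, on seeded random
2-letter strings of lengths 15–50, and on ≥ 1,000 random 300-bp ACGT
strings, requiring exact hit-set equality. The exhaustive band is capped at
length 14 because the 2-letter space doubles per base; beyond it random
sampling covers the remaining lengths.

## Filter cascade

Order: mine → select primary hit (most units, ties to the leftmost) →
flank length → flank homopolymers → read quality → primer screen. Survivor
sets are nested by construction, and each filter is pure and idempotent.

* **Flank length** ≥ 25 bp each side, boundary inclusive ("at least").
* **Homopolymers**: a run of more than five identical bases in either
  flank disqualifies the read. The repeat region itself is not scanned — a
  perfect minimal-period-4 array cannot contain a run longer than 5, and
  the screen targets primer regions.
* **Quality**: the statistic is the mean per-base Phred-like score of the
  MID-trimmed read, threshold 20 of a maximum 40, boundary kept (scores
  *below* 20 are discarded). The source protocol does not pin the
  statistic; mean read quality is the documented default and a
  minimum-flank-quality mode is available behind `quality_mode`. Reads
  without quality values pass with a logged warning. FASTQ input above 40
  is clipped to 40 on read (the 454 quality ceiling).

## Primer screen

The screen is an explicit simplified stand-in for a primer-design package,
not a Primer3 clone — no secondary-structure ΔG, no mispriming libraries.
All thresholds live in `PrimerScreenConfig`: window length 18–27 bp, Tm in
[57, 63] °C with a 60 °C optimum, GC fraction in [0.20, 0.80], no
single-base run longer than 4 inside a primer, 3′-end cross-
complementarity of at most 3 consecutive bases, optional GC clamp
(disabled by default).

Melting temperatures use nearest-neighbor thermodynamics with the Allawi &
SantaLucia (1997) parameter table, 50 mM monovalent salt, 250 nM for each
strand, and the entropy salt correction 0.368·(L−1)·ln[Na⁺]. The
computation is vectorized with cumulative stack sums so every window of
every length costs O(1); the test suite verifies it is numerically
identical (1e−9 °C) to the reference implementation in Biopython's
`MeltingTemp.Tm_NN` under the same parameters. Pinning the table and ionic
conditions makes results bit-reproducible across machines.

Pair choice: per flank the best `max_candidates_per_flank` windows by
|Tm − 60| are retained (a pragmatic cap that keeps pairing quadratic in a
small constant); pairs failing the 3′-complementarity constraint are
discarded; the winner minimizes |Tm_f − 60| + |Tm_r − 60|, ties going to
the shorter amplicon, then to the leftmost coordinates for determinism.

## PAL extrapolation

All quotients are exact rationals (`fractions.Fraction`). The PAL count is
`ratio × candidates` rounded to the nearest integer with exact halves
rounded **down** — the unique simple rule consistent with all three
published values this package reproduces (28.71 → 29, 154.15 → 154, and
the exact tie 217.5 → 217). Printed percentages round half **up** at the
requested number of decimals (default 2; one published figure uses 3).
Floats are accepted but a float ratio cannot represent most quotients
exactly, so exact ties are only guaranteed with rational inputs. NTPP and
SIPL are wet-lab outcomes; they enter via the tally file and are validated
against the nesting invariant 0 ≤ SIPL ≤ NTPP ≤ candidates ≤ repeat-bearing
≤ reads. The report's pooled row sums counts and per-species PAL estimates;
its ratio is pooled SIPL over pooled NTPP (it is not a re-extrapolation).

The extrapolation itself assumes the tested primer pairs are a
representative sample of all filter-passing candidates; the package
reproduces that arithmetic and attaches no confidence interval, since the
sampling design supports none.

## Marker summaries

Ho is the heterozygous fraction of non-missing individuals. He is Nei's
unbiased expected heterozygosity, (2n/(2n−1))(1 − Σp_i²), over the 2n
non-missing gene copies. The Hardy–Weinberg test conditions on the observed
allele counts (Levene): with ≤ 3 alleles every genotype table is
enumerated and the p-value is the exact total probability of tables no
more probable than the observed one, computed in exact rational arithmetic
so ties are unambiguous; with more alleles a seeded Monte Carlo shuffle of
gene copies is used with the (1 + hits)/(1 + permutations) estimator.
"Polymorphic" means ≥ 2 observed alleles everywhere in the package; a
cross-amplification table that shows two alleles for a locus therefore
counts it as polymorphic, whatever flag the original genotyping carried.
Null-allele frequency estimation and linkage-disequilibrium testing are
out of scope. A Bonferroni-adjusted α (α/number of tests) is provided as a
report-layer utility.

## Synthetic data

The generator emulates the enriched 454 run the pipeline targets: per
species (three by default, each with its two published MID tags), reads of
uniform length 200–600 bp, per-read mean quality drawn uniformly from
[28, 36] with per-base Gaussian jitter (σ = 2) clipped to [0, 40], and a
planted-repeat incidence of 3 % by default, echoing the 2–5 %
repeat-bearing rates such enriched libraries produce. Planted repeats draw
a motif from the 13 enrichment-probe motifs and a unit count uniform in
[10, 30]; the low-unit decoy class draws 5–9 units so the two ranges never
overlap the 10-unit threshold from the same side.

Decoy classes are margin-separated so that every read's fate is provable,
not probable: failing flanks are exactly 24 bp versus ≥ 26 for passers;
homopolymer decoys carry a planted run of exactly 6 versus ≤ 5 everywhere
else; low-quality reads draw mean quality from [12, 17] versus [28, 36].
Background sequence is i.i.d. uniform ACGT rejection-sampled to contain no
qualifying repeat and no run longer than 5, and the bases adjacent to a
planted repeat are constrained not to continue its period, so planted
coordinates are exactly the maximal-run coordinates the miner must report.
Interrupted-repeat decoys place one base between two same-phase 5–9-unit
halves, chosen to break the period on both sides.

The manifest stores the planted attributes (class, motif, units,
coordinates, flank lengths, realized mean quality) and the expected
cascade fate derived from them; `expected_tally` turns a manifest into the
stage counts the cascade must produce. The primer-design stage is excluded
from this prediction because random background flanks carry no engineered
primer sites; end-to-end tests therefore compare the mining, flank,
homopolymer, and quality stages exactly (recall = precision = 1 by
construction of the margins) and smoke-test the primer stage separately.

What passing these tests does **not** show: robustness to real 454
artifacts. The generator models no homopolymer-length miscalls, flowgram
noise, chimeras, or length-dependent quality decay, and real genomic flanks
are not i.i.d. uniform. The end-to-end guarantees concern the pipeline's
logic, not sequencing-error tolerance.

## Problem sizes and determinism

Default simulated runs use 1,000 reads per species (~3,000 per run); the
end-to-end suite covers three configurations × five seeds at that scale,
and the miner-oracle suite the string collections listed above. All
randomness flows through `numpy.random.default_rng(seed)`; identical
configurations produce byte-identical FASTA/QUAL/FASTQ and manifest files.
`scripts/acceptance.py` seeds only its simulation self-check — the
reported ratios, PAL counts, and success rates are exact arithmetic on the
published input counts and are seed-independent.
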