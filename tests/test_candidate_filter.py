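import random

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt

from msatpal.candidate_filter import (
    CascadeConfig,
    PrimerScreenConfig,
    check_flanks,
    check_homopolymer,
    check_quality,
    primer_tm,
    run_cascade,
    screen_primers,
    three_prime_complementarity,
)
from msatpal.repeat_miner import RepeatHit, find_perfect_repeats
from msatpal.seqio_demux import DEFAULT_MID_TAGS, Read, demultiplex
from msatpal.synthetic_reads import simulate

from conftest import small_sim_config
from oracles import longest_identical_run


def make_hit(left, right, units=12, read_id="r"):
    start = left
    end = left + 4 * units
    return RepeatHit(read_id, "AGAT", "AGAT", units, start, end, left, right)


def make_read(left_seq, right_seq, units=12, quality=None, read_id="r"):
    seq = left_seq + "AGAT" * units + right_seq
    return Read(read_id, seq, quality)


class TestCheckFlanks:
    def test_boundary_is_inclusive(self):
        assert check_flanks(make_hit(25, 25)) is True

    def test_one_short_flank_fails(self):
        assert check_flanks(make_hit(24, 100)) is False

    def test_simulated_hits_agree_with_planted_flanks(self):
        reads, manifest = simulate(small_sim_config(seed=21, n_reads=300))
        by_sp, _ = demultiplex(reads, DEFAULT_MID_TAGS)
        planted = manifest[manifest.has_repeat].set_index("read_id")
        checked = 0
        for rds in by_sp.values():
            for r in rds:
                if r.read_id not in planted.index:
                    continue
                row = planted.loc[r.read_id]
                (hit,) = find_perfect_repeats(r.sequence, read_id=r.read_id)
                assert check_flanks(hit) == (
                    min(row.left_flank, row.right_flank) >= 25
                )
                checked += 1
        assert checked > 50


class TestCheckHomopolymer:
    def test_six_base_run_in_flank_fails(self):
        left = "TGC" * 8 + "AAAAAA"
        read = make_read(left, "CTG" * 10)
        hit = make_hit(len(left), 30)
        assert check_homopolymer(hit, read) is False

    def test_five_base_run_passes(self):
        left = "TGC" * 8 + "AAAAA" + "C"
        read = make_read(left, "CTG" * 10)
        hit = make_hit(len(left), 30)
        assert check_homopolymer(hit, read) is True

    def test_repeat_region_is_not_scanned(self):
        # an AAAT repeat contains runs of 3 A's (and 4 across units: TAAA|T)
        read = Read("r", "TGC" * 10 + "AAAT" * 12 + "CTG" * 10)
        (hit,) = find_perfect_repeats(read.sequence, read_id="r")
        assert check_homopolymer(hit, read) is True

    def test_random_flanks_match_bruteforce_scanner(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            left = "".join(rng.choice(list("ACGT"), size=30))
            right = "".join(rng.choice(list("ACGT"), size=30))
            read = make_read(left, right)
            hit = make_hit(30, 30)
            expected = (
                longest_identical_run(left) <= 5
                and longest_identical_run(right) <= 5
            )
            assert check_homopolymer(hit, read) is expected


class TestCheckQuality:
    def test_high_quality_passes(self):
        assert check_quality(Read("r", "ACGT", (40, 40, 40, 40))) is True

    def test_low_quality_fails(self):
        assert check_quality(Read("r", "ACGT", (19, 19, 19, 19))) is False

    def test_mean_exactly_at_threshold_is_kept(self):
        # scores *below* 20 are discarded; a mean of exactly 20.0 is kept
        assert check_quality(Read("r", "ACGT", (10, 30, 15, 25))) is True

    def test_missing_quality_passes_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert check_quality(Read("r", "ACGT")) is True
        assert "no quality" in caplog.text

    def test_min_flank_mode(self):
        read = make_read("G" * 30, "C" * 30,
                         quality=tuple([5] + [35] * 107))
        (hit,) = find_perfect_repeats(read.sequence, read_id="r")
        assert check_quality(read, mode="mean_read") is True
        assert check_quality(read, hit=hit, mode="min_flank") is False


class TestPrimerTm:
    def test_matches_biopython_nearest_neighbor_model(self):
        rng = random.Random(42)
        cfg = PrimerScreenConfig()
        for _ in range(200):
            n = rng.randint(18, 27)
            seq = "".join(rng.choice("ACGT") for _ in range(n))
            expected = mt.Tm_NN(seq, Na=cfg.na_mM, dnac1=cfg.dnac_nM,
                                dnac2=cfg.dnac_nM)
            assert primer_tm(seq, cfg) == pytest.approx(expected, abs=1e-9)


class TestThreePrimeComplementarity:
    def test_complementary_ends_counted(self):
        # primers end in AAAA / TTTT (4 consecutive 3' pairs); the 5th
        # position (C vs complement-of-C = G) breaks the run
        assert three_prime_complementarity("TTGCAAAA", "AACCTTTT") == 4

    def test_non_complementary_ends(self):
        assert three_prime_complementarity("GCGCAAAA", "CGCGAAAA") == 0


def _engineered_flank(rng, cfg, length=40):
    """A random flank guaranteed to contain >= 1 valid primer window."""
    while True:
        flank = "".join(rng.choice("ACGT") for _ in range(length))
        if longest_identical_run(flank) > 5:
            continue
        for wl in range(cfg.min_len, cfg.max_len + 1):
            for a in range(length - wl + 1):
                w = flank[a : a + wl]
                if longest_identical_run(w) > cfg.max_homopolymer:
                    continue
                gc = sum(b in "GC" for b in w) / wl
                if not cfg.gc_min <= gc <= cfg.gc_max:
                    continue
                tm = mt.Tm_NN(w, Na=cfg.na_mM, dnac1=cfg.dnac_nM,
                              dnac2=cfg.dnac_nM)
                if cfg.tm_min <= tm <= cfg.tm_max:
                    return flank
        # no valid window; resample


class TestScreenPrimers:
    def test_poly_a_flanks_unsatisfiable(self):
        read = make_read("A" * 30, "A" * 30)
        hit = make_hit(30, 30)
        assert screen_primers(hit, read) is None

    def test_flanks_too_short_for_any_window(self):
        read = make_read("TGC" * 5, "CTG" * 5)  # 15 bp < min primer length
        hit = make_hit(15, 15)
        assert screen_primers(hit, read) is None

    def test_engineered_flanks_yield_verified_pair(self):
        rng = random.Random(7)
        cfg = PrimerScreenConfig()
        left = _engineered_flank(rng, cfg)
        right = _engineered_flank(rng, cfg)
        read = make_read(left, right)
        hit = make_hit(len(left), len(right))
        pair = screen_primers(hit, read, cfg)
        assert pair is not None
        # primers sit in the correct flanks and span the repeat
        assert read.sequence[pair.fwd_start:].startswith(pair.forward)
        assert pair.fwd_start + len(pair.forward) <= hit.start
        assert pair.rev_end >= hit.end
        from msatpal.dna import revcomp
        rstart = pair.rev_end - len(pair.reverse)
        assert revcomp(read.sequence[rstart : pair.rev_end]) == pair.reverse
        # reported Tm matches an independent recomputation and the constraints
        for primer, tm in [(pair.forward, pair.tm_forward),
                           (pair.reverse, pair.tm_reverse)]:
            ref = mt.Tm_NN(primer, Na=cfg.na_mM, dnac1=cfg.dnac_nM,
                           dnac2=cfg.dnac_nM)
            assert tm == pytest.approx(ref, abs=1e-9)
            assert cfg.tm_min <= tm <= cfg.tm_max
            assert longest_identical_run(primer) <= cfg.max_homopolymer
        assert three_prime_complementarity(
            pair.forward, pair.reverse
        ) <= cfg.max_3prime_complementarity


class TestRunCascade:
    def test_zero_reads_zero_tallies(self):
        loci, counts = run_cascade({"sp": []})
        assert loci == []
        assert counts["sp"].as_dict() == {
            "n_reads": 0, "mined": 0, "flank_pass": 0, "clean_flanks": 0,
            "quality_pass": 0, "primer_designed": 0,
        }

    def test_monotone_stage_counts_and_order_invariance(self):
        reads, _ = simulate(small_sim_config(seed=31, n_reads=150))
        by_sp, _ = demultiplex(reads, DEFAULT_MID_TAGS)
        cfg = CascadeConfig(screen_primers=False)
        loci, counts = run_cascade(by_sp, cfg)
        for tally in counts.values():
            d = tally.as_dict()
            assert (
                d["n_reads"] >= d["mined"] >= d["flank_pass"]
                >= d["clean_flanks"] >= d["quality_pass"] >= d["primer_designed"]
            )
        shuffled = {
            sp: list(reversed(rds)) for sp, rds in by_sp.items()
        }
        loci2, counts2 = run_cascade(shuffled, cfg)
        assert {sp: t.as_dict() for sp, t in counts.items()} == {
            sp: t.as_dict() for sp, t in counts2.items()
        }
        key = lambda c: c.hit.read_id
        assert sorted([c.hit for c in loci], key=lambda h: h.read_id) == sorted(
            [c.hit for c in loci2], key=lambda h: h.read_id
        )

    def test_rerunning_on_survivors_reproduces_survivors(self):
        reads, _ = simulate(small_sim_config(seed=32, n_reads=150))
        by_sp, _ = demultiplex(reads, DEFAULT_MID_TAGS)
        cfg = CascadeConfig(screen_primers=False)
        loci, _ = run_cascade(by_sp, cfg)
        survivors = [c.read for c in loci if c.stage_reached == "quality_pass"]
        assert survivors
        _, counts2 = run_cascade({"pool": survivors}, cfg)
        d = counts2["pool"].as_dict()
        assert d["n_reads"] == d["quality_pass"] == len(survivors)
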