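import numpy as np
import pytest

from msatpal.seqio_demux import (
    DEFAULT_MID_TAGS,
    InputConsistencyError,
    MidTag,
    Read,
    TagConfigError,
    UNASSIGNED,
    assign_species,
    demultiplex,
    read_fastq,
    read_sequences,
    trim_mid,
    validate_tags,
    write_fastq,
    write_sequences,
)
from msatpal.synthetic_reads import simulate

from conftest import small_sim_config


class TestRead:
    def test_rejects_empty_and_invalid_sequences(self):
        with pytest.raises(ValueError):
            Read("r", "")
        with pytest.raises(ValueError):
            Read("r", "ACGX")

    def test_rejects_quality_length_mismatch(self):
        with pytest.raises(ValueError):
            Read("r", "ACGT", (30, 30))

    def test_uppercases_sequence(self):
        assert Read("r", "acgt").sequence == "ACGT"


class TestFileIO:
    def test_empty_fasta_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        assert read_sequences(p) == []
        q = tmp_path / "empty.fastq"
        q.write_text("")
        assert read_fastq(q) == []

    def test_single_record_with_qual(self, tmp_path):
        (tmp_path / "r.fasta").write_text(">r1\nACGT\n")
        (tmp_path / "r.qual").write_text(">r1\n30 30 30 30\n")
        reads = read_sequences(tmp_path / "r.fasta", tmp_path / "r.qual")
        assert reads == [Read("r1", "ACGT", (30, 30, 30, 30))]

    def test_fasta_qual_id_mismatch(self, tmp_path):
        (tmp_path / "r.fasta").write_text(">r1\nACGT\n")
        (tmp_path / "r.qual").write_text(">other\n30 30 30 30\n")
        with pytest.raises(InputConsistencyError):
            read_sequences(tmp_path / "r.fasta", tmp_path / "r.qual")

    def test_fasta_qual_length_mismatch(self, tmp_path):
        (tmp_path / "r.fasta").write_text(">r1\nACGT\n")
        (tmp_path / "r.qual").write_text(">r1\n30 30 30\n")
        with pytest.raises(InputConsistencyError):
            read_sequences(tmp_path / "r.fasta", tmp_path / "r.qual")

    def test_fastq_phred_offset(self, tmp_path):
        # 'I' is Phred 40 at Sanger offset 33
        (tmp_path / "r.fastq").write_text("@r1\nAC\n+\nII\n")
        assert read_fastq(tmp_path / "r.fastq")[0].quality == (40, 40)

    def test_fastq_clips_quality_above_40(self, tmp_path):
        # 'K' is Phred 42; the 454 convention caps scores at 40
        (tmp_path / "r.fastq").write_text("@r1\nAC\n+\nKI\n")
        assert read_fastq(tmp_path / "r.fastq")[0].quality == (40, 40)

    def test_round_trip_fasta_qual_and_fastq(self, tmp_path):
        reads, _ = simulate(small_sim_config(seed=3, n_reads=17))
        reads = reads[:50]
        write_sequences(reads, tmp_path / "x.fasta", tmp_path / "x.qual")
        assert read_sequences(tmp_path / "x.fasta", tmp_path / "x.qual") == reads
        write_fastq(reads, tmp_path / "x.fastq")
        assert read_fastq(tmp_path / "x.fastq") == reads


class TestAssignSpecies:
    def test_published_tag_prefix_assigns_c_asper(self):
        read = Read("r", "ACGAGTAGACT" + "AAGTC" * 10)
        assert assign_species(read, DEFAULT_MID_TAGS) == "C. asper"

    def test_unmatched_prefix_is_unassigned(self):
        read = Read("r", "T" * 60)
        assert assign_species(read, DEFAULT_MID_TAGS) == UNASSIGNED

    def test_n_never_matches_even_with_mismatch_allowance(self):
        tag = MidTag("sp", "ACGT")
        read = Read("r", "NCGT" + "A" * 20)
        assert assign_species(read, [tag], max_mismatches=0) == UNASSIGNED
        # the N costs the single allowed mismatch; a second difference fails
        read2 = Read("r", "NCGA" + "A" * 20)
        assert assign_species(read2, [tag], max_mismatches=1) == UNASSIGNED

    def test_duplicate_tag_across_species_is_config_error(self):
        tags = [MidTag("a", "ACGT"), MidTag("b", "ACGT")]
        with pytest.raises(TagConfigError):
            validate_tags(tags)

    def test_prefix_tag_is_config_error(self):
        tags = [MidTag("a", "ACGT"), MidTag("b", "ACGTAA")]
        with pytest.raises(TagConfigError):
            assign_species(Read("r", "ACGTAAAA"), tags)


class TestTrimMid:
    def test_trim_removes_tag_and_quality(self):
        tag = MidTag("C. asper", "ACGAGTAGACT")
        read = Read("r", "ACGAGTAGACT" + "AAAA", tuple(range(15)))
        trimmed = trim_mid(read, tag)
        assert trimmed.sequence == "AAAA"
        assert trimmed.quality == (11, 12, 13, 14)
        assert trimmed.read_id == "r"
        assert trimmed.species == "C. asper"
        assert len(trimmed) == len(read) - 11

    def test_trim_requires_prefix(self):
        with pytest.raises(ValueError):
            trim_mid(Read("r", "TTTTTTTTTTTTTT"), MidTag("sp", "ACGT"))

    def test_prepending_tag_recovers_original(self):
        tag = MidTag("sp", "ACGT")
        original = Read("r", "ACGTGGGG")
        trimmed = trim_mid(original, tag)
        assert tag.tag + trimmed.sequence == original.sequence


class TestDemultiplex:
    def test_empty_input_gives_empty_buckets(self):
        buckets, unassigned = demultiplex([], DEFAULT_MID_TAGS)
        assert all(len(v) == 0 for v in buckets.values())
        assert unassigned == []

    def test_simulated_pool_counts_match_manifest(self):
        reads, manifest = simulate(small_sim_config(seed=7, n_reads=100))
        buckets, unassigned = demultiplex(reads, DEFAULT_MID_TAGS)
        assert not unassigned
        expected = manifest.groupby("species").size().to_dict()
        assert {sp: len(v) for sp, v in buckets.items()} == expected
        # per-read assignment agrees with the manifest
        by_id = dict(zip(manifest["read_id"], manifest["species"]))
        for sp, rds in buckets.items():
            assert all(by_id[r.read_id] == sp for r in rds)

    def test_partition_invariant(self):
        rng = np.random.default_rng(11)
        reads, _ = simulate(small_sim_config(seed=5, n_reads=40))
        # corrupt the first base of a random subset so some reads unassign
        corrupted = []
        for r in reads:
            seq = r.sequence
            if rng.random() < 0.5:
                seq = ("T" if seq[0] != "T" else "A") + seq[1:]
            corrupted.append(Read(r.read_id, seq, r.quality))
        buckets, unassigned = demultiplex(corrupted, DEFAULT_MID_TAGS)
        assert sum(len(v) for v in buckets.values()) + len(unassigned) == len(
            corrupted
        )

    def test_corrupted_first_base_lands_unassigned(self):
        reads, _ = simulate(small_sim_config(seed=6, n_reads=10))
        corrupted = [
            Read(r.read_id,
                 ("T" if r.sequence[0] != "T" else "A") + r.sequence[1:],
                 r.quality)
            for r in reads
        ]
        buckets, unassigned = demultiplex(corrupted, DEFAULT_MID_TAGS)
        assert len(unassigned) == len(corrupted)
        assert all(len(v) == 0 for v in buckets.values())

    def test_order_preserved_within_buckets(self):
        reads, _ = simulate(small_sim_config(seed=8, n_reads=50))
        buckets, _ = demultiplex(reads, DEFAULT_MID_TAGS)
        order = {r.read_id: i for i, r in enumerate(reads)}
        for rds in buckets.values():
            ids = [order[r.read_id] for r in rds]
            assert ids == sorted(ids)
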