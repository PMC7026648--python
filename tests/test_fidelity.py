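"""The mismatch statistic against brute-force oracles and truth tables."""
import logging

import numpy as np
import pytest

import transfidelity as tf
from transfidelity import fidelity
from transfidelity._alphabet import SUBSTITUTIONS, encode
from transfidelity.synthdata import write_fasta, write_sam

from conftest import naive_error_counts, resolved_mismatches_from_truth


def make_read(seq, quals, ref_window, start=0, name="r1", unique=True):
    """Hand-build an AlignedRead for targeted cases."""
    s, w = encode(seq), encode(ref_window)
    return fidelity.AlignedRead(
        name=name,
        reference_name="ref1",
        ref_start=start,
        is_reverse=False,
        seq_codes=s,
        quals=np.asarray(quals, dtype=np.int16),
        ref_codes=w,
        ref_positions=np.arange(start, start + len(seq), dtype=np.int64),
        is_unique=unique,
        n_mismatches=int(np.count_nonzero(s != w)),
    )


@pytest.fixture(scope="module")
def written_dataset(tmp_path_factory, rich_dataset):
    cfg, genome, sim, _ = rich_dataset
    d = tmp_path_factory.mktemp("sam")
    write_fasta(d / "ref.fa", genome.name, genome.reference)
    write_sam(sim, genome, d / "reads.sam")
    return d / "reads.sam", d / "ref.fa"


class TestReadAlignments:
    def test_empty_sam_gives_empty_list(self, tmp_path):
        sam = tmp_path / "empty.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:ref1\tLN:100\n")
        write_fasta(tmp_path / "ref.fa", "ref1", "A" * 100)
        assert fidelity.read_alignments(sam, tmp_path / "ref.fa") == []

    def test_perfect_read_has_zero_mismatches(self, tmp_path):
        ref = "ACGTACGTACGTACGTACGT"
        write_fasta(tmp_path / "ref.fa", "ref1", ref)
        sam = tmp_path / "one.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ref1\tLN:20\n"
            f"r1\t0\tref1\t3\t42\t10M\t*\t0\t0\t{ref[2:12]}\t{'I' * 10}\n"
        )
        (read,) = fidelity.read_alignments(sam, tmp_path / "ref.fa")
        assert read.n_mismatches == 0
        assert read.ref_start == 2

    def test_non_single_match_cigar_skipped_with_warning(self, tmp_path, caplog):
        write_fasta(tmp_path / "ref.fa", "ref1", "ACGTACGTACGT")
        sam = tmp_path / "mix.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ref1\tLN:12\n"
            "ok\t0\tref1\t1\t42\t8M\t*\t0\t0\tACGTACGT\tIIIIIIII\n"
            "indel\t0\tref1\t1\t42\t4M1I4M\t*\t0\t0\tACGTTACGT\tIIIIIIIII\n"
        )
        with caplog.at_level(logging.WARNING, logger="transfidelity.fidelity"):
            reads = fidelity.read_alignments(sam, tmp_path / "ref.fa")
        assert [r.name for r in reads] == ["ok"]
        assert "non-single-M" in caplog.text

    def test_mismatch_counts_match_truth_table(self, written_dataset, rich_dataset):
        # truth-table oracle through a full SAM/FASTA round trip
        _, genome, sim, in_memory = rich_dataset
        reads = fidelity.read_alignments(*written_dataset)
        expected = resolved_mismatches_from_truth(sim, genome)
        assert len(reads) == len(in_memory)
        for r in reads:
            assert r.n_mismatches == expected[r.name]

    def test_file_roundtrip_equals_in_memory_adapter(self, written_dataset, rich_dataset):
        *_, in_memory = rich_dataset
        by_name = {r.name: r for r in fidelity.read_alignments(*written_dataset)}
        for mem in in_memory:
            r = by_name[mem.name]
            assert np.array_equal(r.seq_codes, mem.seq_codes)
            assert np.array_equal(r.quals, mem.quals)
            assert np.array_equal(r.ref_positions, mem.ref_positions)

    def test_reverse_strand_flipped_into_read_orientation(self, tmp_path):
        ref = "AACCGGTTAACCGGTT"
        write_fasta(tmp_path / "ref.fa", "ref1", ref)
        # read orientation CCGGTT.. reverse-complemented into the record
        sam = tmp_path / "rev.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ref1\tLN:16\n"
            f"rv\t16\tref1\t1\t42\t8M\t*\t0\t0\t{ref[:8]}\tABCDEFGH\n"
        )
        (read,) = fidelity.read_alignments(sam, tmp_path / "ref.fa")
        assert read.is_reverse
        from transfidelity._alphabet import decode

        assert read.sequence == "AACCGGTT"  # revcomp of AACCGGTT window
        assert decode(read.ref_codes) == read.sequence
        assert read.quals.tolist() == [ord(c) - 33 for c in "HGFEDCBA"]
        assert read.ref_positions.tolist() == list(range(7, -1, -1))


class TestTrim:
    def test_identity_trim(self, rich_dataset):
        *_, reads = rich_dataset
        out = fidelity.trim_reads(reads[:50], keep_first=50, drop_first=0)
        for a, b in zip(out, reads):
            assert np.array_equal(a.seq_codes, b.seq_codes)
            assert a.n_mismatches == b.n_mismatches

    def test_trim_index_arithmetic(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTAC"
        read = make_read(seq, [30] * 50, seq)
        (t,) = fidelity.trim_reads([read], keep_first=40, drop_first=2)
        assert len(t) == 40
        assert t.sequence[0] == seq[2]
        assert t.ref_positions[0] == 2

    def test_window_exceeding_read_rejected(self):
        read = make_read("ACGT", [30] * 4, "ACGT")
        with pytest.raises(ValueError, match="exceeds read length"):
            fidelity.trim_reads([read], keep_first=4, drop_first=1)

    def test_trim_shifts_error_profile_exactly(self, rich_dataset):
        # E(p) of trimmed reads equals E(p + drop_first) of untrimmed reads
        *_, reads = rich_dataset
        drop, keep = 5, 40
        full = tf.compute_error_table(reads, qmin=30)
        trimmed = tf.compute_error_table(fidelity.trim_reads(reads, keep, drop), qmin=30)
        assert np.array_equal(trimmed.N, full.N[drop : drop + keep])
        assert np.array_equal(trimmed.M, full.M[drop : drop + keep])
        assert np.array_equal(trimmed.M_sub, full.M_sub[drop : drop + keep])


class TestFilter:
    def test_exceeding_mismatch_budget_removed(self):
        read = make_read("AAAA" + "C" * 6, [40] * 10, "A" * 10)  # 6 mismatches
        ok = make_read("AAAACCC" + "AAA", [40] * 10, "AAAACCCAAA", name="ok")
        assert fidelity.filter_alignments([read, ok], max_mismatches=3) == [ok]

    def test_infinite_budget_is_identity(self, rich_dataset):
        *_, reads = rich_dataset
        assert fidelity.filter_alignments(reads, max_mismatches=np.inf, unique_only=False) == list(reads)

    def test_matches_predicate_scan_oracle(self, rich_dataset):
        *_, reads = rich_dataset
        reads = list(reads)
        # plant some non-unique reads
        doctored = []
        for i, r in enumerate(reads[:2000]):
            if i % 7 == 0:
                from dataclasses import replace

                r = replace(r, is_unique=False)
            doctored.append(r)
        expected = [r for r in doctored if r.n_mismatches <= 3 and r.is_unique]
        assert fidelity.filter_alignments(doctored, 3, unique_only=True) == expected


class TestVariantMask:
    def test_concordant_reads_give_empty_mask(self):
        reads = [make_read("ACGTACGT", [40] * 8, "ACGTACGT", name=f"r{i}") for i in range(20)]
        mask = fidelity.call_variant_mask(reads, "ACGTACGT", min_coverage=5, alt_fraction=0.8)
        assert len(mask) == 0

    def test_unanimous_alt_is_masked(self):
        ref = "ACGTACGTAC"
        alt = "ACGTTCGTAC"  # position 4 A->T in every read
        reads = [make_read(alt, [40] * 10, ref, name=f"r{i}") for i in range(10)]
        mask = fidelity.call_variant_mask(reads, ref, min_coverage=5, alt_fraction=0.8)
        assert mask.positions == {4}
        row = mask.evidence.iloc[0]
        assert row["coverage"] == 10 and row["alt_base"] == "T" and row["alt_fraction"] == 1.0

    def test_low_quality_bases_do_not_support_calls(self):
        ref = "ACGTACGTAC"
        alt = "ACGTTCGTAC"
        reads = [make_read(alt, [10] * 10, ref, name=f"r{i}") for i in range(10)]
        mask = fidelity.call_variant_mask(reads, ref, min_coverage=5, alt_fraction=0.8, qmin=30)
        assert len(mask) == 0

    def test_tied_alts_masked_conservatively(self):
        ref = "AAAAAAAAAA"
        reads = [make_read("AAAAC" + "A" * 5, [40] * 10, ref, name=f"c{i}") for i in range(5)]
        reads += [make_read("AAAAG" + "A" * 5, [40] * 10, ref, name=f"g{i}") for i in range(5)]
        mask = fidelity.call_variant_mask(reads, ref, min_coverage=5, alt_fraction=0.8)
        assert mask.positions == {4}

    @pytest.mark.parametrize("kwargs", [dict(min_coverage=0), dict(alt_fraction=0.5), dict(alt_fraction=1.2)])
    def test_invalid_thresholds_rejected(self, kwargs):
        with pytest.raises(ValueError):
            fidelity.call_variant_mask([], "ACGT", **kwargs)

    def test_recovers_true_snvs_without_false_calls(self, rich_dataset):
        cfg, genome, sim, reads = rich_dataset
        reads = fidelity.filter_alignments(reads)
        mask = fidelity.call_variant_mask(reads, genome.reference, min_coverage=10, alt_fraction=0.8)
        true_pos = set(genome.variant_positions.tolist())
        # recall among well-covered true variants
        counts = np.zeros(cfg.genome_length, dtype=int)
        for r in reads:
            ok = r.quals >= 30
            np.add.at(counts, r.ref_positions[ok], 1)
        covered = {p for p in true_pos if counts[p] >= 20}
        assert covered, "fixture should produce well-covered variants"
        recall = len(covered & mask.positions) / len(covered)
        assert recall >= 0.95
        false = {p for p in mask.positions - true_pos if counts[p] >= 20}
        assert not false


class TestExtractMismatches:
    def test_phred_below_threshold_excluded(self):
        read = make_read("ACGT", [40, 40, 29, 40], "ACTT")  # mismatch at pos 3, Q29
        assert fidelity.extract_mismatches(read, qmin=30) == []
        events = fidelity.extract_mismatches(read, qmin=29)
        assert len(events) == 1 and events[0].read_pos == 3

    def test_masked_position_excluded(self):
        read = make_read("ACGT", [40] * 4, "ACTT", start=10)
        mask = fidelity.VariantMask.from_positions([12])
        assert fidelity.extract_mismatches(read, mask=mask, qmin=30) == []

    def test_n_bases_excluded(self):
        read = make_read("ANGT", [40] * 4, "CCNT")
        events = fidelity.extract_mismatches(read, qmin=30)
        assert len(events) == 1 and events[0].read_pos == 1  # A vs C only

    def test_matches_bruteforce_scan(self, rich_dataset):
        _, genome, _, reads = rich_dataset
        mask = fidelity.VariantMask.from_positions(genome.variant_positions)
        for r in reads[:500]:
            got = fidelity.extract_mismatches(r, mask=mask, qmin=30)
            want = []
            for j in range(len(r)):
                b, w, q = int(r.seq_codes[j]), int(r.ref_codes[j]), int(r.quals[j])
                if b != w and b != 4 and w != 4 and q >= 30 and int(r.ref_positions[j]) not in mask.positions:
                    want.append((j + 1, int(r.ref_positions[j]), "ACGT"[w], "ACGT"[b], q))
            assert [(e.read_pos, e.ref_pos, e.ref_base, e.read_base, e.quality) for e in got] == want


class TestErrorTable:
    def test_single_read_arithmetic(self):
        seq = "ACGTACGTAC"
        ref = "ACTTACGTAC"  # mismatch at read position 3 (G vs T)
        read = make_read(seq, [40] * 10, ref)
        table = tf.compute_error_table([read], qmin=30)
        assert table.total_rate(3) == 100.0
        assert table.substitution_rate(3, "T>G") == 100.0
        for p in range(1, 11):
            if p != 3:
                assert table.total_rate(p) == 0.0

    def test_error_free_dataset_rates_are_zero(self):
        cfg = tf.SimConfig(genome_length=2000, n_reads=500, read_length=40,
                           sequencing_errors=False, seed=8)
        g = tf.simulate_genome(cfg)
        reads = tf.simulate_reads(cfg, g).to_aligned_reads(g)
        table = tf.compute_error_table(reads)
        assert (table.M == 0).all()
        assert np.nanmax(table.rate_profile()) == 0.0

    def test_undefined_rate_is_nan_not_zero(self):
        read = make_read("ACGT", [10, 40, 40, 40], "ACGT")
        table = tf.compute_error_table([read], qmin=30)
        assert np.isnan(table.total_rate(1))  # base excluded, N=0
        assert table.total_rate(2) == 0.0

    def test_matches_naive_double_loop(self, rich_dataset):
        _, genome, _, reads = rich_dataset
        subset = reads[:2000]
        mask = fidelity.call_variant_mask(subset, genome.reference, min_coverage=5, alt_fraction=0.8)
        table = tf.compute_error_table(subset, genome.reference, mask, qmin=30)
        N, M, M_sub = naive_error_counts(subset, mask.positions, qmin=30)
        assert table.N.tolist() == N
        assert table.M.tolist() == M
        assert table.M_sub.tolist() == M_sub

    def test_substitution_counts_decompose_total(self, rich_dataset):
        *_, reads = rich_dataset
        table = tf.compute_error_table(reads, qmin=30)
        assert np.array_equal(table.M_sub.sum(axis=1), table.M)

    def test_threshold_monotonicity_event_subset(self, rich_dataset):
        *_, reads = rich_dataset
        lo = {(e.read_id, e.read_pos) for r in reads[:1000] for e in fidelity.extract_mismatches(r, qmin=30)}
        hi = {(e.read_id, e.read_pos) for r in reads[:1000] for e in fidelity.extract_mismatches(r, qmin=35)}
        assert hi <= lo
        t30 = tf.compute_error_table(reads, qmin=30)
        t35 = tf.compute_error_table(reads, qmin=35)
        assert (t35.M <= t30.M).all()

    def test_masking_monotonicity(self, rich_dataset):
        _, genome, _, reads = rich_dataset
        small = fidelity.VariantMask.from_positions(genome.variant_positions[:20])
        big = fidelity.VariantMask.from_positions(genome.variant_positions)
        t_small = tf.compute_error_table(reads, genome.reference, small)
        t_big = tf.compute_error_table(reads, genome.reference, big)
        assert (t_big.M_sub <= t_small.M_sub).all()

    def test_numerator_only_threshold_flag(self, rich_dataset):
        *_, reads = rich_dataset
        sym = tf.compute_error_table(reads, qmin=30)
        num_only = tf.compute_error_table(reads, qmin=30, threshold_numerator_only=True)
        assert (num_only.N >= sym.N).all()
        assert np.array_equal(num_only.M, sym.M)


@pytest.fixture()
def table():
    read = make_read("ACGTACGTAC", [40] * 10, "ACTTACGTAC")
    return tf.compute_error_table([read], qmin=30)


class TestRatesAndComparison:

    def test_specific_rate_recount(self, rich_dataset):
        *_, reads = rich_dataset
        table = tf.compute_error_table(reads, qmin=30)
        events = [e for r in reads for e in fidelity.extract_mismatches(r, qmin=30)]
        m = sum(1 for e in events if e.read_pos == 7 and e.ref_base == "C" and e.read_base == "T")
        assert tf.specific_error_rate(table, 7, "C>T") == pytest.approx(100.0 * m / table.N[6])

    def test_absent_substitution_is_zero(self, table):
        assert tf.specific_error_rate(table, 3, "A>C") == 0.0

    def test_undefined_denominator_raises(self):
        read = make_read("ACGT", [10] * 4, "ACGT")
        table = tf.compute_error_table([read], qmin=30)
        with pytest.raises(ValueError, match="undefined"):
            tf.specific_error_rate(table, 2, "C>T")

    def test_identical_tables_compare_to_100(self, table):
        cmp = tf.compare_samples(table, table, read_pos=3, substitution="T>G")
        assert cmp.ratio_percent == pytest.approx(100.0)

    def test_ratio_arithmetic(self):
        # rates 0.002% vs 0.001% -> 200%
        a = fidelity.ErrorRateTable(N=np.array([100_000]), M=np.array([2]),
                                    M_sub=np.eye(1, 12, k=5, dtype=np.int64) * 2)
        b = fidelity.ErrorRateTable(N=np.array([100_000]), M=np.array([1]),
                                    M_sub=np.eye(1, 12, k=5, dtype=np.int64))
        cmp = tf.compare_samples(a, b, read_pos=1, substitution="C>T")
        assert cmp.ratio_percent == pytest.approx(200.0)

    def test_zero_reference_rate_raises(self, table):
        zero = tf.compute_error_table([make_read("ACGT", [40] * 4, "ACGT")], qmin=30)
        with pytest.raises(ValueError):
            tf.compare_samples(table, zero, read_pos=3, substitution="T>G")
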