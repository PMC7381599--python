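"""UMI/barcode extraction, mismatch-tolerant matching and demultiplexing."""

import csv
import itertools

import pysam
import pytest

from relacs_kit import simulator
from relacs_kit.barcode_design import Barcode, BarcodeSet, design_barcode_set
from relacs_kit.demux import (
    DemuxFormatError,
    DemuxReport,
    MateTooShortError,
    ReadPair,
    demultiplex,
    extract_tags,
    match_barcode,
)
from relacs_kit.layout import ReadLayout


def _pair(seq1, seq2, name="r1"):
    return ReadPair(name, seq1, "I" * len(seq1), seq2, "I" * len(seq2))


class TestExtractTags:
    def test_default_layout_splits_umi_barcode_insert(self):
        insert = "TTTTTTTTTTGGGGG"
        pair = _pair("AAAA" + "ACGTACGT" + insert, "CCCC" + "ACGTACGT" + "GG")
        tags = extract_tags(pair)
        assert tags.umi1 == "AAAA"
        assert tags.barcode1 == "ACGTACGT"
        assert tags.trimmed.mate1_seq == insert
        assert tags.combined_umi == "AAAACCCC"
        assert len(tags.combined_umi) == 8

    def test_trim_removes_prefix_from_both_mates_in_lockstep(self):
        pair = ReadPair("r", "A" * 20, "ABCDEFGHIJKLMNOPQRST", "C" * 15, "I" * 15)
        tags = extract_tags(pair)
        assert len(pair.mate1_seq) - len(tags.trimmed.mate1_seq) == 12
        assert len(pair.mate2_seq) - len(tags.trimmed.mate2_seq) == 12
        assert tags.trimmed.mate1_qual == "MNOPQRST"  # qualities follow the sequence

    def test_zero_umi_layout(self):
        pair = _pair("ACGTACGT" + "TT", "ACGTACGT" + "GG")
        tags = extract_tags(pair, ReadLayout(umi_len=0, barcode_len=8))
        assert tags.combined_umi == ""
        assert tags.barcode1 == "ACGTACGT"

    def test_short_mate_raises(self):
        with pytest.raises(MateTooShortError):
            extract_tags(_pair("A" * 11, "C" * 50))


class TestMatchBarcode:
    def test_exact_match(self, small_bset):
        seq = small_bset.sequences[2]
        m = match_barcode(seq, small_bset, max_mismatch=0)
        assert (m.index, m.mismatches, m.status) == (2, 0, "ok")

    def test_every_one_substitution_neighbour_resolves_uniquely(self, small_bset):
        # min Hamming 3 guarantees unambiguous 1-mismatch correction
        for idx, seq in enumerate(small_bset.sequences):
            for pos, sub in itertools.product(range(8), "ACGTN"):
                if sub == seq[pos]:
                    continue
                probe = seq[:pos] + sub + seq[pos + 1 :]
                m = match_barcode(probe, small_bset, max_mismatch=1)
                assert m.status == "ok" and m.index == idx, probe

    def test_equidistant_probe_is_ambiguous(self):
        bset = BarcodeSet([Barcode("AAAACCCC"), Barcode("AAAACCCG")], min_hamming=1)
        m = match_barcode("AAAACCCT", bset, max_mismatch=1)
        assert m.status == "ambiguous"

    def test_no_match_beyond_tolerance(self, small_bset):
        # all-N is 8 mismatches from every barcode
        assert match_barcode("N" * 8, small_bset, max_mismatch=1).status == "no_match"
        assert match_barcode("N" * 8, small_bset, max_mismatch=0).status == "no_match"

    def test_length_mismatch_raises(self, small_bset):
        with pytest.raises(ValueError):
            match_barcode("ACGT", small_bset)


def _simulate(tmp_path, bset, n_pairs, error_rate=0.0, pcr=0.0, seed=9, genome=None):
    cfg = simulator.SimConfig(
        samples=[
            simulator.SampleSpec(bset.label_of(i), b.sequence) for i, b in enumerate(bset)
        ],
        n_pairs=n_pairs,
        error_rate=error_rate,
        pcr_duplicate_rate=pcr,
        seed=seed,
    )
    return simulator.simulate_run(genome, cfg, tmp_path / "run", compress=False)


def _truth_by_name(truth_path):
    with open(truth_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return {row["read_name"]: row for row in reader}


class TestDemultiplex:
    def test_zero_error_round_trip_recovers_truth_exactly(self, tmp_path, toy_genome, small_bset):
        run = _simulate(tmp_path, small_bset, 2_000, genome=toy_genome)
        report = demultiplex(
            run.r1_path, run.r2_path, small_bset, tmp_path / "demux",
            max_mismatch=0, compress=False,
        )
        truth = _truth_by_name(run.truth_path)
        expected = {}
        for row in truth.values():
            expected[row["sample"]] = expected.get(row["sample"], 0) + 1
        observed = dict(zip(report.samples, report.pair_counts))
        assert {k: v for k, v in observed.items() if v} == expected
        assert report.unassigned_pairs == 0
        assert report.total_pairs == 2_000

        # read names carry the true combined UMI; trim removed exactly 12 nt
        out1 = tmp_path / "demux" / f"{report.samples[0]}_R1.fastq"
        with pysam.FastxFile(str(out1)) as fq:
            for entry in fq:
                base, umi = entry.name.rsplit("_", 1)
                assert umi == truth[base]["umi"]
                assert len(umi) == 8

    def test_conservation_and_no_cross_assignment_with_errors(
        self, tmp_path, toy_genome, small_bset
    ):
        run = _simulate(tmp_path, small_bset, 5_000, error_rate=0.005, genome=toy_genome)
        report = demultiplex(
            run.r1_path, run.r2_path, small_bset, tmp_path / "demux",
            max_mismatch=1, compress=False,
        )
        assert report.assigned_pairs + report.unassigned_pairs == 5_000
        truth = _truth_by_name(run.truth_path)
        for sample in report.samples:
            path = tmp_path / "demux" / f"{sample}_R1.fastq"
            with pysam.FastxFile(str(path)) as fq:
                for entry in fq:
                    base = entry.name.rsplit("_", 1)[0]
                    assert truth[base]["sample"] == sample  # never cross-assigned

    def test_mate_conflict_policies(self, tmp_path, fastq_writer, small_bset):
        bc_a, bc_b = small_bset.sequences[0], small_bset.sequences[1]
        insert = "T" * 38
        r1 = fastq_writer(tmp_path / "r1.fastq", [("p", "AAAA" + bc_a + insert, "I" * 50)])
        r2 = fastq_writer(tmp_path / "r2.fastq", [("p", "CCCC" + bc_b + insert, "I" * 50)])
        strict = demultiplex(r1, r2, small_bset, tmp_path / "strict", compress=False)
        assert strict.unassigned["mate_conflict"] == 1
        assert strict.assigned_pairs == 0
        loose = demultiplex(
            r1, r2, small_bset, tmp_path / "loose", mate_policy="either", compress=False
        )
        assert loose.unassigned["mate_conflict"] == 1  # both resolve, to different samples

        r2_bad = fastq_writer(
            tmp_path / "r2b.fastq", [("p", "CCCC" + "N" * 8 + insert, "I" * 50)]
        )
        loose2 = demultiplex(
            r1, r2_bad, small_bset, tmp_path / "loose2", mate_policy="either", compress=False
        )
        assert loose2.pair_counts[0] == 1  # single resolving mate is accepted

    def test_too_short_pairs_go_undetermined_untrimmed(self, tmp_path, fastq_writer, small_bset):
        r1 = fastq_writer(tmp_path / "r1.fastq", [("p", "ACGTACG", "IIIIIII")])
        r2 = fastq_writer(tmp_path / "r2.fastq", [("p", "ACGTACG", "IIIIIII")])
        report = demultiplex(r1, r2, small_bset, tmp_path / "out", compress=False)
        assert report.unassigned["too_short"] == 1
        with pysam.FastxFile(str(tmp_path / "out" / "undetermined_R1.fastq")) as fq:
            entry = next(iter(fq))
            assert entry.sequence == "ACGTACG"  # untouched for diagnosis

    def test_desynchronised_inputs_raise(self, tmp_path, fastq_writer, small_bset):
        good = ("p1", "A" * 50, "I" * 50)
        r1 = fastq_writer(tmp_path / "r1.fastq", [good, ("p2", "A" * 50, "I" * 50)])
        r2 = fastq_writer(tmp_path / "r2.fastq", [good])
        with pytest.raises(DemuxFormatError, match="record counts differ"):
            demultiplex(r1, r2, small_bset, tmp_path / "o1", compress=False)

        r2_names = fastq_writer(tmp_path / "r2n.fastq", [("other", "A" * 50, "I" * 50)])
        r1_single = fastq_writer(tmp_path / "r1s.fastq", [good])
        with pytest.raises(DemuxFormatError, match="desynchronised"):
            demultiplex(r1_single, r2_names, small_bset, tmp_path / "o2", compress=False)

    def test_gzip_autodetection_and_report_round_trip(self, tmp_path, toy_genome, small_bset):
        run = _simulate(tmp_path, small_bset, 500, genome=toy_genome)
        gz_dir = tmp_path / "gz"
        report = demultiplex(run.r1_path, run.r2_path, small_bset, gz_dir)  # gzip out
        # gzipped outputs are themselves demultiplexable input (magic-byte detection)
        report2 = DemuxReport.from_tsv(gz_dir / "demux_report.tsv")
        assert report2.pair_counts == report.pair_counts
        assert report2.total_pairs == report.total_pairs
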