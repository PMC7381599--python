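"""In-silico digestion and synthetic run generation."""

import csv
import math

import pyfaidx
import pysam
import pytest

from relacs_kit import simulator
from relacs_kit.barcode_design import design_barcode_set
from relacs_kit.simulator import (
    Fragment,
    SampleSpec,
    SimConfig,
    digest_genome,
    iupac_pattern,
    reverse_complement,
    simulate_run,
    write_toy_genome,
)


def _write_fasta(path, contigs):
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n{seq}\n")
    return path


def _config(bset, **kw):
    samples = [SampleSpec(bset.label_of(i), b.sequence) for i, b in enumerate(bset)]
    return SimConfig(samples=samples, **kw)


class TestDigest:
    def test_single_cut_site(self, tmp_path):
        fa = _write_fasta(tmp_path / "a.fa", {"c": "AAAGATCAAA"})
        frags = digest_genome(fa, "GATC", 0)
        assert [(f.start, f.end) for f in frags] == [(0, 3), (3, 10)]
        assert [f.sequence for f in frags] == ["AAA", "GATCAAA"]

    def test_no_match_yields_whole_contig(self, tmp_path):
        fa = _write_fasta(tmp_path / "a.fa", {"c": "AAAATTTT"})
        frags = digest_genome(fa, "GATC")
        assert len(frags) == 1
        assert (frags[0].start, frags[0].end) == (0, 8)

    def test_degenerate_motif_with_offset(self, tmp_path):
        # RGCY matches AGCC (R={A,G}, Y={C,T}); offset 2 cuts between AG and CC
        fa = _write_fasta(tmp_path / "a.fa", {"c": "AGCC"})
        frags = digest_genome(fa, "RGCY", 2)
        assert [f.sequence for f in frags] == ["AG", "CC"]

    def test_overlapping_matches_all_cut(self, tmp_path):
        fa = _write_fasta(tmp_path / "a.fa", {"c": "AAAA"})
        frags = digest_genome(fa, "AA", 0)
        # matches at 0,1,2; interior cuts at 1 and 2
        assert [(f.start, f.end) for f in frags] == [(0, 1), (1, 2), (2, 4)]

    def test_digest_is_a_partition(self, toy_genome):
        frags = digest_genome(toy_genome, "GATC")
        with pyfaidx.Fasta(str(toy_genome), as_raw=True, sequence_always_upper=True) as fa:
            for name in fa.keys():
                contig = str(fa[name][:])
                parts = [f for f in frags if f.reference == name]
                assert sum(len(f) for f in parts) == len(contig)
                assert "".join(f.sequence for f in parts) == contig
                starts = [f.start for f in parts]
                assert starts == sorted(starts)

    def test_invalid_iupac_symbol(self, tmp_path):
        with pytest.raises(ValueError, match="IUPAC"):
            iupac_pattern("GAXC")
        fa = _write_fasta(tmp_path / "a.fa", {"c": "ACGT"})
        with pytest.raises(ValueError):
            digest_genome(fa, "GATC", cut_offset=9)

    def test_fragment_invariant(self):
        with pytest.raises(ValueError):
            Fragment(reference="c", start=0, end=5, sequence="AC")


class TestSimulateRun:
    def test_empty_run(self, tmp_path, toy_genome, small_bset):
        run = simulate_run(toy_genome, _config(small_bset, n_pairs=0), tmp_path / "r", compress=False)
        assert run.n_pairs == 0
        assert open(run.r1_path).read() == ""
        with open(run.truth_path) as fh:
            assert len(fh.readlines()) == 1  # header only

    def test_read_len_must_exceed_prefix(self, tmp_path, toy_genome, small_bset):
        with pytest.raises(ValueError, match="prefix"):
            simulate_run(toy_genome, _config(small_bset, n_pairs=10, read_len=10), tmp_path / "r")

    def test_error_free_reads_reconstruct_exactly(self, tmp_path, toy_genome, small_bset):
        run = simulate_run(
            toy_genome, _config(small_bset, n_pairs=200, seed=2), tmp_path / "r", compress=False
        )
        frags = {
            (f.reference, f.start, f.end): f for f in digest_genome(toy_genome, "GATC")
        }
        barcode_of = {small_bset.label_of(i): b.sequence for i, b in enumerate(small_bset)}
        with open(run.truth_path) as fh:
            truth = {r["read_name"]: r for r in csv.DictReader(fh, delimiter="\t")}
        with pysam.FastxFile(str(run.r1_path)) as fq1, pysam.FastxFile(str(run.r2_path)) as fq2:
            for e1, e2 in zip(fq1, fq2):
                row = truth[e1.name]
                frag = frags[(row["reference"], int(row["fragment_start"]), int(row["fragment_end"]))]
                umi = row["umi"]
                expect1 = (umi[:4] + barcode_of[row["sample"]] + frag.sequence[:38])[:50]
                expect2 = (umi[4:] + barcode_of[row["sample"]] + reverse_complement(frag.sequence)[:38])[:50]
                assert e1.sequence == expect1
                assert e2.sequence == expect2

    def test_sidecar_completeness(self, tmp_path, toy_genome, small_bset):
        run = simulate_run(
            toy_genome,
            _config(small_bset, n_pairs=2_000, pcr_duplicate_rate=0.3, seed=4),
            tmp_path / "r",
            compress=False,
        )
        with open(run.truth_path) as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
        truth_names = [r["read_name"] for r in rows]
        with pysam.FastxFile(str(run.r1_path)) as fq:
            fq_names = [e.name for e in fq]
        assert fq_names == truth_names
        assert len(set(truth_names)) == len(truth_names)
        # duplicate lineage points at an earlier original row
        index = {name: i for i, name in enumerate(truth_names)}
        for i, row in enumerate(rows):
            if row["duplicate_of"] != "-":
                j = index[row["duplicate_of"]]
                assert j < i
                assert rows[j]["duplicate_of"] == "-"
                assert rows[j]["umi"] == row["umi"]

    def test_sample_proportions_follow_weights(self, tmp_path, toy_genome):
        bset = design_barcode_set(3, seed=6)
        samples = [
            SampleSpec(bset.label_of(i), b.sequence, weight=w)
            for (i, b), w in zip(enumerate(bset), (1.0, 2.0, 7.0))
        ]
        n = 100_000
        cfg = SimConfig(samples=samples, n_pairs=n, seed=3)
        run = simulate_run(toy_genome, cfg, tmp_path / "r", compress=False)
        with open(run.truth_path) as fh:
            counts = {}
            for row in csv.DictReader(fh, delimiter="\t"):
                counts[row["sample"]] = counts.get(row["sample"], 0) + 1
        for spec in samples:
            p = spec.weight / 10.0
            sd = math.sqrt(n * p * (1 - p))
            assert abs(counts[spec.label] - n * p) < 3 * sd

    def test_enrichment_regions_bias_fragment_draws(self, tmp_path, toy_genome, small_bset):
        frags = digest_genome(toy_genome, "GATC")
        region = ("contig1", 0, 10_000, 50.0)
        cfg = _config(small_bset, n_pairs=20_000, seed=9, enrichment_regions=[region])
        run = simulate_run(toy_genome, cfg, tmp_path / "r", compress=False)
        inside = 0
        total = 0
        with open(run.truth_path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                total += 1
                mid = (int(row["fragment_start"]) + int(row["fragment_end"])) / 2
                if row["reference"] == "contig1" and mid < 10_000:
                    inside += 1
        # weighted mass inside the region far exceeds its unweighted share
        base_share = sum(1 for f in frags if f.reference == "contig1" and f.midpoint < 10_000) / len(frags)
        assert inside / total > 2 * base_share

    def test_determinism(self, tmp_path, toy_genome, small_bset):
        cfg = _config(small_bset, n_pairs=300, error_rate=0.01, pcr_duplicate_rate=0.2, seed=21)
        a = simulate_run(toy_genome, cfg, tmp_path / "a", compress=False)
        b = simulate_run(toy_genome, cfg, tmp_path / "b", compress=False)
        assert open(a.r1_path).read() == open(b.r1_path).read()
        assert open(a.truth_path).read() == open(b.truth_path).read()


def test_toy_genome_is_reproducible(tmp_path):
    a = write_toy_genome(tmp_path / "a.fa", seed=1)
    b = write_toy_genome(tmp_path / "b.fa", seed=1)
    assert open(a).read().splitlines()[1:] == open(b).read().splitlines()[1:]
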