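"""Synthetic RELACS runs with per-read ground truth.

The generative model mirrors the wet protocol: a reference genome is digested
in silico at every occurrence of a (possibly degenerate) restriction motif;
each emitted read pair draws a sample (by pool weight), a restriction
fragment (uniformly, or up-weighted inside enrichment regions), and a fresh
UMI per mate; mate 1 reads the fragment 5' end, mate 2 the reverse complement
of its 3' end, each prefixed by that mate's UMI and the sample's barcode and
truncated to the read length. PCR duplicates re-emit an earlier pair — same
fragment, same UMIs — and substitution errors are applied independently per
emission, so duplicates differ only by sequencing noise. A truth sidecar
records, per read pair, the sample, combined UMI, fragment coordinates and
duplicate lineage.

What is deliberately not modelled: fragment-length bias, adapter
read-through on short fragments (reads are simply truncated at the fragment
end), indel errors, and any chromatin or antibody realism.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pyfaidx
import pysam

from relacs_kit.demux import _open_fastq_out

DNA = "ACGT"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Degenerate 4-cutter preset (CviKI-1-like RGCY, blunt cut in the middle).
RGCY_PRESET = ("RGCY", 2)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_pattern(motif: str) -> str:
    """Translate an IUPAC motif into a regex character-class pattern."""
    try:
        return "".join(f"[{IUPAC[c]}]" for c in motif.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol {exc.args[0]!r} in motif {motif!r}") from None


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment: a half-open interval on one contig."""

    reference: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"{self.reference}:{self.start}-{self.end}: interval length "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def digest_genome(
    fasta: str | Path, motif: str = "GATC", cut_offset: int = 0
) -> list[Fragment]:
    """Cut every contig at each motif occurrence, returning a partition.

    Overlapping motif matches are honoured (lookahead scan); each match
    contributes a cut at ``match_start + cut_offset``. Palindromic motifs
    (their own reverse complement under IUPAC expansion, as for most
    restriction sites) need no separate reverse-strand scan. Fragment
    sequences concatenate back to the contig exactly.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if not 0 <= cut_offset <= len(motif):
        raise ValueError(f"cut_offset must be within [0, {len(motif)}], got {cut_offset}")
    pattern = re.compile(f"(?={iupac_pattern(motif)})")
    fragments: list[Fragment] = []
    with pyfaidx.Fasta(str(fasta), as_raw=True, sequence_always_upper=True) as fa:
        for name in fa.keys():
            seq = str(fa[name][:])
            cuts = sorted({m.start() + cut_offset for m in pattern.finditer(seq)})
            bounds = [0] + [c for c in cuts if 0 < c < len(seq)] + [len(seq)]
            for a, b in zip(bounds, bounds[1:]):
                fragments.append(Fragment(reference=name, start=a, end=b, sequence=seq[a:b]))
    return fragments


@dataclass(frozen=True)
class SampleSpec:
    """One pooled sample: label, its inline barcode, and its pool weight."""

    label: str
    barcode: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"{self.label}: weight must be > 0, got {self.weight}")


@dataclass
class SimConfig:
    """Parameters of one simulated run.

    ``enrichment_regions`` is a list of ``(reference, start, end, fold)``
    tuples; a fragment whose midpoint falls inside a region has its sampling
    weight multiplied by that region's fold.
    """

    samples: list[SampleSpec]
    n_pairs: int
    motif: str = "GATC"
    cut_offset: int = 0
    read_len: int = 50
    umi_len: int = 4
    error_rate: float = 0.0
    pcr_duplicate_rate: float = 0.0
    enrichment_regions: list[tuple[str, int, int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("at least one sample is required")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be within [0, 1]")
        if not 0.0 <= self.pcr_duplicate_rate <= 1.0:
            raise ValueError("pcr_duplicate_rate must be within [0, 1]")
        lens = {len(s.barcode) for s in self.samples}
        if len(lens) != 1:
            raise ValueError(f"sample barcodes have mixed lengths: {sorted(lens)}")
        if self.umi_len < 0:
            raise ValueError("umi_len must be >= 0")

    @property
    def barcode_len(self) -> int:
        return len(self.samples[0].barcode)

    @property
    def prefix_len(self) -> int:
        return self.umi_len + self.barcode_len


@dataclass
class SimRun:
    """Paths and tallies of one simulated run."""

    r1_path: Path
    r2_path: Path
    truth_path: Path
    sam_path: Path | None
    n_pairs: int
    n_originals: int


def load_enrichment_bed(path: str | Path, default_fold: float = 2.0) -> list[tuple[str, int, int, float]]:
    """Read enrichment intervals from a BED file (fold in column 4, optional)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            fold = float(parts[3]) if len(parts) > 3 else default_fold
            regions.append((parts[0], int(parts[1]), int(parts[2]), fold))
    return regions


def write_toy_genome(
    path: str | Path,
    n_contigs: int = 2,
    contig_length: int = 20_000,
    gc_fraction: float = 0.5,
    seed: int = 0,
) -> Path:
    """Write a random synthetic FASTA reference for simulations and tests."""
    rng = np.random.default_rng(seed)
    p_gc = gc_fraction / 2
    p_at = (1 - gc_fraction) / 2
    path = Path(path)
    with open(path, "w") as fh:
        for i in range(n_contigs):
            bases = rng.choice(list(DNA), size=contig_length, p=[p_at, p_gc, p_gc, p_at])
            fh.write(f">contig{i + 1}\n")
            seq = "".join(bases)
            for j in range(0, len(seq), 80):
                fh.write(seq[j : j + 80] + "\n")
    return path


def _fragment_weights(
    fragments: Sequence[Fragment], regions: Sequence[tuple[str, int, int, float]]
) -> np.ndarray:
    w = np.ones(len(fragments))
    for ref, start, end, fold in regions:
        for i, frag in enumerate(fragments):
            if frag.reference == ref and start <= frag.midpoint < end:
                w[i] *= fold
    return w


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0.0 or not seq:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in DNA if b != out[pos]]
        out[pos] = alternatives[rng.integers(3)]
    return "".join(out)


def simulate_run(
    fasta: str | Path,
    config: SimConfig,
    out_prefix: str | Path,
    compress: bool = True,
    truth_sam: bool = False,
    sam_mapq: int = 60,
) -> SimRun:
    """Emit a synthetic paired-end RELACS run plus its ground-truth sidecar.

    Outputs ``<prefix>_R1.fastq[.gz]``, ``<prefix>_R2.fastq[.gz]`` and
    ``<prefix>_truth.tsv`` (columns: read_name, sample, umi, reference,
    fragment_start, fragment_end, duplicate_of; ``-`` marks originals).

    With ``truth_sam``, also writes ``<prefix>_truth.sam``: perfect
    alignments reconstructed from the fragment coordinates, named as the
    demultiplexer would name them (``<read_name>_<combined_umi>``), read 1
    forward at the fragment 5' end, read 2 reverse at its 3' end. This is a
    deduplication test harness, not an aligner.

    Raises
    ------
    ValueError
        If ``read_len <= umi_len + barcode_len`` — no insert bases would
        remain after the technical prefix.
    """
    if config.read_len <= config.prefix_len:
        raise ValueError(
            f"read_len ({config.read_len}) must exceed the technical prefix "
            f"({config.prefix_len} nt): no insert bases would remain"
        )
    fragments = digest_genome(fasta, config.motif, config.cut_offset)
    if not fragments:
        raise ValueError(f"{fasta}: reference contains no sequence")
    rng = np.random.default_rng(config.seed)

    sample_w = np.array([s.weight for s in config.samples])
    sample_p = sample_w / sample_w.sum()
    frag_w = _fragment_weights(fragments, config.enrichment_regions)
    frag_p = frag_w / frag_w.sum()

    n = config.n_pairs
    sample_draws = rng.choice(len(config.samples), size=n, p=sample_p) if n else np.array([], int)
    frag_draws = rng.choice(len(fragments), size=n, p=frag_p) if n else np.array([], int)
    dup_flags = rng.random(n) < config.pcr_duplicate_rate if n else np.array([], bool)
    umi_codes = rng.integers(0, 4, size=(n, 2 * config.umi_len)) if n else np.empty((0, 0), int)

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if compress else ".fastq"
    r1_path = out_prefix.parent / (out_prefix.name + f"_R1{suffix}")
    r2_path = out_prefix.parent / (out_prefix.name + f"_R2{suffix}")
    truth_path = out_prefix.parent / (out_prefix.name + "_truth.tsv")
    sam_path = out_prefix.parent / (out_prefix.name + "_truth.sam") if truth_sam else None

    insert_len = config.read_len - config.prefix_len
    ulen = config.umi_len
    digits = max(7, len(str(max(n, 1))))

    # (sample_idx, frag_idx, umi1, umi2, name) per emission, for duplicate reuse
    emitted: list[tuple[int, int, str, str, str]] = []
    originals: list[int] = []
    truth_rows: list[str] = []
    sam_records: list[tuple[str, int, int, int, int]] = []  # qname, frag_idx fields

    fq1 = _open_fastq_out(r1_path, compress)
    fq2 = _open_fastq_out(r2_path, compress)
    try:
        for i in range(n):
            if dup_flags[i] and originals:
                src = emitted[originals[rng.integers(len(originals))]]
                si, fi, umi1, umi2 = src[0], src[1], src[2], src[3]
                duplicate_of = src[4]
            else:
                si, fi = int(sample_draws[i]), int(frag_draws[i])
                codes = umi_codes[i]
                umi1 = "".join(DNA[c] for c in codes[:ulen])
                umi2 = "".join(DNA[c] for c in codes[ulen:])
                duplicate_of = "-"
                originals.append(i)
            name = f"sim-{i:0{digits}d}"
            emitted.append((si, fi, umi1, umi2, name))

            sample = config.samples[si]
            frag = fragments[fi]
            fwd = frag.sequence[:insert_len]
            rev = reverse_complement(frag.sequence)[:insert_len]
            read1 = _mutate(umi1 + sample.barcode + fwd, rng, config.error_rate)
            read2 = _mutate(umi2 + sample.barcode + rev, rng, config.error_rate)
            fq1.write(f"@{name}\n{read1}\n+\n{'I' * len(read1)}\n")
            fq2.write(f"@{name}\n{read2}\n+\n{'I' * len(read2)}\n")
            truth_rows.append(
                f"{name}\t{sample.label}\t{umi1}{umi2}\t{frag.reference}"
                f"\t{frag.start}\t{frag.end}\t{duplicate_of}"
            )
            if truth_sam:
                sam_records.append((f"{name}_{umi1}{umi2}", fi, len(fwd), len(rev), i))
    finally:
        fq1.close()
        fq2.close()

    with open(truth_path, "w") as fh:
        fh.write("read_name\tsample\tumi\treference\tfragment_start\tfragment_end\tduplicate_of\n")
        for row in truth_rows:
            fh.write(row + "\n")

    if truth_sam:
        _write_truth_sam(sam_path, fragments, fasta, sam_records, sam_mapq)

    return SimRun(
        r1_path=r1_path,
        r2_path=r2_path,
        truth_path=truth_path,
        sam_path=sam_path,
        n_pairs=n,
        n_originals=len(originals),
    )


def _write_truth_sam(
    path: Path,
    fragments: Sequence[Fragment],
    fasta: str | Path,
    records: Sequence[tuple[str, int, int, int, int]],
    mapq: int,
) -> None:
    with pyfaidx.Fasta(str(fasta)) as fa:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": len(fa[name])} for name in fa.keys()],
        }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        refs = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
        for qname, fi, len1, len2, _ in records:
            frag = fragments[fi]
            tid = refs[frag.reference]
            pos1 = frag.start
            pos2 = frag.end - len2
            for is_read2, pos, length in ((False, pos1, len1), (True, pos2, len2)):
                a = pysam.AlignedSegment()
                a.query_name = qname
                a.reference_id = tid
                a.reference_start = pos
                a.mapping_quality = mapq
                a.cigarstring = f"{length}M"
                seq = frag.sequence[:length] if not is_read2 else reverse_complement(
                    frag.sequence
                )[:length]
                if is_read2:
                    seq = reverse_complement(seq)  # SAM stores the forward-strand sequence
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array("I" * length)
                a.flag = 147 if is_read2 else 99
                a.next_reference_id = tid
                a.next_reference_start = pos1 if is_read2 else pos2
                a.template_length = (frag.end - frag.start) * (-1 if is_read2 else 1)
                out.write(a)
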