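"""Demultiplexing of pooled paired-end reads on inline sample barcodes.

Each mate of a RELACS pair begins with ``umi_len`` random bases and
``barcode_len`` sample-barcode bases. Demultiplexing extracts both mate UMIs
(concatenated mate1-then-mate2 into the fragment tag), matches both observed
barcodes against the sample sheet with a bounded number of mismatches, trims
the technical prefix from both mates, and appends the combined UMI to the
read name as ``<name>_<umi>`` — the convention UMI-aware deduplicators read
back from the alignment QNAME.
"""

from __future__ import annotations

import gzip
import itertools
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, NamedTuple

import pysam

from relacs_kit.barcode_design import BarcodeSet
from relacs_kit.layout import ReadLayout

UNASSIGNED_REASONS = ("no_match", "ambiguous", "mate_conflict", "too_short")

_MATCH_ALPHABET = "ACGTN"  # N in the observed barcode counts as a mismatch
_AMBIGUOUS = -2


class DemuxFormatError(ValueError):
    """Malformed or desynchronised input FASTQ."""


class MateTooShortError(ValueError):
    """A mate is shorter than the technical prefix; the pair is unassignable."""


@dataclass(frozen=True)
class ReadPair:
    name: str
    mate1_seq: str
    mate1_qual: str
    mate2_seq: str
    mate2_qual: str

    def __post_init__(self) -> None:
        if len(self.mate1_seq) != len(self.mate1_qual):
            raise ValueError(f"{self.name}: mate1 sequence/quality length mismatch")
        if len(self.mate2_seq) != len(self.mate2_qual):
            raise ValueError(f"{self.name}: mate2 sequence/quality length mismatch")


class ExtractedTags(NamedTuple):
    umi1: str
    barcode1: str
    umi2: str
    barcode2: str
    trimmed: ReadPair

    @property
    def combined_umi(self) -> str:
        """Fragment tag: mate1 UMI followed by mate2 UMI."""
        return self.umi1 + self.umi2


def extract_tags(pair: ReadPair, layout: ReadLayout | None = None) -> ExtractedTags:
    """Split both mates into UMI, barcode and trimmed insert.

    The first ``umi_len`` bases of each mate are its UMI, the next
    ``barcode_len`` the observed barcode; the returned pair has the full
    ``prefix_len`` bases (and qualities) removed from *both* mates.

    Raises
    ------
    MateTooShortError
        If either mate is shorter than ``prefix_len``; callers route such
        pairs to the undetermined output rather than truncating silently.
    """
    layout = layout or ReadLayout()
    p, u = layout.prefix_len, layout.umi_len
    if len(pair.mate1_seq) < p or len(pair.mate2_seq) < p:
        raise MateTooShortError(
            f"{pair.name}: mate shorter than technical prefix ({p} nt)"
        )
    trimmed = ReadPair(
        name=pair.name,
        mate1_seq=pair.mate1_seq[p:],
        mate1_qual=pair.mate1_qual[p:],
        mate2_seq=pair.mate2_seq[p:],
        mate2_qual=pair.mate2_qual[p:],
    )
    return ExtractedTags(
        umi1=pair.mate1_seq[:u],
        barcode1=pair.mate1_seq[u:p],
        umi2=pair.mate2_seq[:u],
        barcode2=pair.mate2_seq[u:p],
        trimmed=trimmed,
    )


class MatchResult(NamedTuple):
    index: int | None
    mismatches: int | None
    status: str  # ok | no_match | ambiguous


def match_barcode(observed: str, bset: BarcodeSet, max_mismatch: int = 0) -> MatchResult:
    """Resolve an observed barcode to the unique set member within tolerance.

    Returns ``no_match`` when no barcode lies within ``max_mismatch``
    substitutions, and ``ambiguous`` when two or more tie at the minimal
    distance. ``N`` bases never match and therefore count as mismatches.
    """
    if len(observed) != bset.barcode_length:
        raise ValueError(
            f"observed barcode length {len(observed)} != set length {bset.barcode_length}"
        )
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    best, best_idx, ties = None, None, 0
    for i, seq in enumerate(bset.sequences):
        d = sum(a != b for a, b in zip(observed, seq))
        if best is None or d < best:
            best, best_idx, ties = d, i, 1
        elif d == best:
            ties += 1
    assert best is not None
    if best > max_mismatch:
        return MatchResult(None, None, "no_match")
    if ties > 1:
        return MatchResult(None, best, "ambiguous")
    return MatchResult(best_idx, best, "ok")


def _build_match_table(bset: BarcodeSet, max_mismatch: int) -> dict[str, tuple[int, int]]:
    """Precompute observed-sequence -> (index, distance) for distance <= 1.

    Ambiguous neighbours map to the ``_AMBIGUOUS`` sentinel; absent keys mean
    no match. Only built for ``max_mismatch <= 1`` — larger radii fall back to
    the linear scan.
    """
    table: dict[str, tuple[int, int]] = {}

    def claim(seq: str, idx: int, dist: int) -> None:
        prev = table.get(seq)
        if prev is None or dist < prev[1]:
            table[seq] = (idx, dist)
        elif dist == prev[1] and prev[0] != idx:
            table[seq] = (_AMBIGUOUS, dist)

    for idx, seq in enumerate(bset.sequences):
        claim(seq, idx, 0)
        if max_mismatch >= 1:
            for pos, orig in enumerate(seq):
                for sub in _MATCH_ALPHABET:
                    if sub != orig:
                        claim(seq[:pos] + sub + seq[pos + 1 :], idx, 1)
    return table


@dataclass
class DemuxReport:
    """Per-sample assignment counts for one demultiplexing run.

    Percentages are of *all* input pairs (assigned + unassigned), matching a
    "percent of input reads per barcode" readout.
    """

    samples: list[str]
    barcodes: list[str]
    pair_counts: list[int]
    unassigned: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in UNASSIGNED_REASONS}
    )

    @property
    def total_pairs(self) -> int:
        return self.assigned_pairs + self.unassigned_pairs

    @property
    def assigned_pairs(self) -> int:
        return sum(self.pair_counts)

    @property
    def unassigned_pairs(self) -> int:
        return sum(self.unassigned.values())

    @property
    def percentages(self) -> list[float]:
        total = self.total_pairs
        if total == 0:
            return [0.0] * len(self.pair_counts)
        return [100.0 * c / total for c in self.pair_counts]

    def barcode_counts(self) -> dict[str, int]:
        """Per-barcode assigned pair counts, keyed by barcode sequence."""
        return dict(zip(self.barcodes, self.pair_counts))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("barcode\tsample\tpairs\tpercent\n")
            for bc, sample, count, pct in zip(
                self.barcodes, self.samples, self.pair_counts, self.percentages
            ):
                fh.write(f"{bc}\t{sample}\t{count}\t{pct:.4f}\n")
            total = self.total_pairs
            for reason in UNASSIGNED_REASONS:
                count = self.unassigned[reason]
                pct = 100.0 * count / total if total else 0.0
                fh.write(f"-\tunassigned:{reason}\t{count}\t{pct:.4f}\n")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "total_pairs": self.total_pairs,
            "assigned_pairs": self.assigned_pairs,
            "unassigned": dict(self.unassigned),
            "samples": [
                {"sample": s, "barcode": b, "pairs": c, "percent": p}
                for s, b, c, p in zip(
                    self.samples, self.barcodes, self.pair_counts, self.percentages
                )
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DemuxReport":
        samples, barcodes, counts = [], [], []
        unassigned = {r: 0 for r in UNASSIGNED_REASONS}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["barcode", "sample", "pairs"]:
                raise ValueError(f"{path}: not a demux report TSV (header {header})")
            for line in fh:
                bc, sample, count = line.rstrip("\n").split("\t")[:3]
                if bc == "-" and sample.startswith("unassigned:"):
                    unassigned[sample.split(":", 1)[1]] = int(count)
                else:
                    barcodes.append(bc)
                    samples.append(sample)
                    counts.append(int(count))
        return cls(samples=samples, barcodes=barcodes, pair_counts=counts, unassigned=unassigned)


_SAFE_NAME = re.compile(r"[^A-Za-z0-9._-]+")


def _sanitize(name: str) -> str:
    return _SAFE_NAME.sub("_", name)


def _open_fastq_out(path: Path, compress: bool) -> IO[str]:
    if compress:
        # mtime=0 keeps output bytes identical across reruns
        import io

        raw = open(path, "wb")
        gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0, compresslevel=1)
        return io.TextIOWrapper(gz, encoding="ascii", write_through=False)
    return open(path, "w")


def _pair_key(name: str) -> str:
    # strip a trailing /1 or /2 mate marker if present
    return name[:-2] if name.endswith(("/1", "/2")) else name


def demultiplex(
    fastq_r1: str | Path,
    fastq_r2: str | Path,
    bset: BarcodeSet,
    out_dir: str | Path,
    layout: ReadLayout | None = None,
    max_mismatch: int | None = None,
    mate_policy: str = "both-agree",
    compress: bool = True,
) -> DemuxReport:
    """Split a pooled paired-end run into per-sample FASTQ files.

    Every input pair lands in exactly one output: a per-sample pair when both
    observed barcodes resolve consistently (policy ``both-agree``, the
    default, requires both mates to agree on the sample; ``either`` accepts a
    pair on a single resolving mate), or the undetermined pair otherwise.
    Assigned reads are trimmed by ``prefix_len`` and renamed
    ``<name>_<combined_umi>``; undetermined reads are written untouched for
    diagnosis. Gzip input is autodetected from the file content, not the
    extension.

    ``max_mismatch`` defaults to 1 when the set guarantees ``min_hamming >= 3``
    (the soundness condition for single-substitution correction) and 0
    otherwise.

    Returns the :class:`DemuxReport`, also written to ``demux_report.tsv`` and
    ``demux_report.json`` in ``out_dir``.
    """
    layout = layout or bset.layout
    if mate_policy not in ("both-agree", "either"):
        raise ValueError(f"unknown mate_policy: {mate_policy!r}")
    if max_mismatch is None:
        max_mismatch = 1 if bset.min_hamming >= 3 else 0

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if compress else ".fastq"

    labels = [bset.label_of(i) for i in range(len(bset))]
    handles: list[tuple[IO[str], IO[str]]] = []
    try:
        for label in labels:
            safe = _sanitize(label)
            handles.append(
                (
                    _open_fastq_out(out_dir / f"{safe}_R1{suffix}", compress),
                    _open_fastq_out(out_dir / f"{safe}_R2{suffix}", compress),
                )
            )
        und = (
            _open_fastq_out(out_dir / f"undetermined_R1{suffix}", compress),
            _open_fastq_out(out_dir / f"undetermined_R2{suffix}", compress),
        )
        handles.append(und)

        counts = [0] * len(bset)
        unassigned = {r: 0 for r in UNASSIGNED_REASONS}

        use_table = max_mismatch <= 1
        table = _build_match_table(bset, max_mismatch) if use_table else {}
        scan_cache: dict[str, tuple[int, int] | None] = {}

        def resolve(obs: str) -> tuple[int, int] | None:
            """(index, dist), (_AMBIGUOUS, dist), or None for no match."""
            if use_table:
                return table.get(obs)
            hit = scan_cache.get(obs, False)
            if hit is False:
                m = match_barcode(obs, bset, max_mismatch)
                if m.status == "ok":
                    hit = (m.index, m.mismatches)
                elif m.status == "ambiguous":
                    hit = (_AMBIGUOUS, m.mismatches)
                else:
                    hit = None
                scan_cache[obs] = hit
            return hit

        prefix = layout.prefix_len
        umi_len = layout.umi_len
        both_agree = mate_policy == "both-agree"
        record_no = 0

        with pysam.FastxFile(str(fastq_r1)) as fq1, pysam.FastxFile(str(fastq_r2)) as fq2:
            for r1, r2 in itertools.zip_longest(fq1, fq2):
                record_no += 1
                if r1 is None or r2 is None:
                    short = fastq_r1 if r1 is None else fastq_r2
                    raise DemuxFormatError(
                        f"R1/R2 record counts differ: {short} ended before record {record_no}"
                    )
                if _pair_key(r1.name) != _pair_key(r2.name):
                    raise DemuxFormatError(
                        f"R1/R2 desynchronised at record {record_no}: "
                        f"{r1.name!r} vs {r2.name!r}"
                    )
                s1, s2 = r1.sequence, r2.sequence
                if len(s1) < prefix or len(s2) < prefix:
                    unassigned["too_short"] += 1
                    _write_record(und[0], r1.name, s1, r1.quality)
                    _write_record(und[1], r2.name, s2, r2.quality)
                    continue
                m1 = resolve(s1[umi_len:prefix])
                m2 = resolve(s2[umi_len:prefix])

                idx: int | None = None
                reason: str | None = None
                if both_agree:
                    if m1 is not None and m2 is not None and m1[0] == m2[0] and m1[0] >= 0:
                        idx = m1[0]
                    elif (m1 is not None and m1[0] == _AMBIGUOUS) or (
                        m2 is not None and m2[0] == _AMBIGUOUS
                    ):
                        reason = "ambiguous"
                    elif m1 is not None and m2 is not None and m1[0] >= 0 and m2[0] >= 0:
                        reason = "mate_conflict"
                    else:
                        reason = "no_match"
                else:  # either
                    ok1 = m1 is not None and m1[0] >= 0
                    ok2 = m2 is not None and m2[0] >= 0
                    if ok1 and ok2 and m1[0] != m2[0]:
                        reason = "mate_conflict"
                    elif ok1:
                        idx = m1[0]
                    elif ok2:
                        idx = m2[0]
                    elif (m1 is not None and m1[0] == _AMBIGUOUS) or (
                        m2 is not None and m2[0] == _AMBIGUOUS
                    ):
                        reason = "ambiguous"
                    else:
                        reason = "no_match"

                if idx is None:
                    assert reason is not None
                    unassigned[reason] += 1
                    _write_record(und[0], r1.name, s1, r1.quality)
                    _write_record(und[1], r2.name, s2, r2.quality)
                    continue

                counts[idx] += 1
                umi = s1[:umi_len] + s2[:umi_len]
                name = f"{r1.name}_{umi}" if umi else r1.name
                out1, out2 = handles[idx]
                _write_record(out1, name, s1[prefix:], r1.quality[prefix:])
                _write_record(out2, name, s2[prefix:], r2.quality[prefix:])
    finally:
        for h1, h2 in handles:
            h1.close()
            h2.close()

    report = DemuxReport(
        samples=list(labels),
        barcodes=bset.sequences,
        pair_counts=counts,
        unassigned=unassigned,
    )
    report.to_tsv(out_dir / "demux_report.tsv")
    report.to_json(out_dir / "demux_report.json")
    return report


def _write_record(fh: IO[str], name: str, seq: str, qual: str) -> None:
    fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
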