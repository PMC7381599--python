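"""Design of inline sample barcodes for chromatin multiplexing.

The published adaptor design fixes two things about the sample barcode: it is
8 nt long and has exactly 50% GC content. For demultiplexing with mismatch
tolerance to be *sound* — every read within the tolerated error radius of a
barcode resolves to that barcode and no other — the set additionally needs a
minimum pairwise Hamming distance of ``2 * max_mismatch + 1``. This module
enumerates the candidate space under composition constraints and greedily
selects distance-separated sets, reproducibly for a fixed seed.
"""

from __future__ import annotations

import csv
import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from relacs_kit.layout import ReadLayout

DNA_ALPHABET = "ACGT"

#: Motifs excluded from barcodes by default: the simulator's default
#: restriction recognition site, so a barcode can never recreate a cut site
#: at the ligation junction.
DEFAULT_FORBIDDEN_MOTIFS: tuple[str, ...] = ("GATC",)

_WELL_ROWS = "ABCDEFGH"


class BarcodeDesignError(ValueError):
    """Raised when a requested barcode set cannot be constructed.

    Attributes
    ----------
    max_reached : int
        Largest set size achievable under the given constraints.
    """

    def __init__(self, message: str, max_reached: int = 0) -> None:
        super().__init__(message)
        self.max_reached = max_reached


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def max_homopolymer_run(sequence: str) -> int:
    """Length of the longest single-base run in ``sequence``."""
    return max((len(m.group(0)) for m in re.finditer(r"(.)\1*", sequence)), default=0)


def gc_count(sequence: str) -> int:
    """Number of G or C bases in ``sequence``."""
    return sum(1 for b in sequence if b in "GC")


@dataclass(frozen=True)
class Barcode:
    """One sample barcode: a DNA sequence plus optional bookkeeping."""

    sequence: str
    sample_label: str | None = None
    well: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence or any(b not in DNA_ALPHABET for b in self.sequence):
            raise ValueError(f"barcode sequence must be non-empty over ACGT: {self.sequence!r}")


@dataclass
class BarcodeSet:
    """An ordered collection of same-length barcodes with a declared separation.

    ``min_hamming`` is the separation the set is *supposed* to guarantee;
    :func:`validate_barcode_set` checks it against the actual sequences, and
    :func:`min_pairwise_distance` computes the exact minimum.
    """

    barcodes: list[Barcode]
    min_hamming: int = 1
    layout: ReadLayout = field(default_factory=ReadLayout)

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("a BarcodeSet needs at least one barcode")
        lengths = {len(b.sequence) for b in self.barcodes}
        if len(lengths) != 1:
            raise ValueError(f"barcodes have mixed lengths: {sorted(lengths)}")
        seqs = [b.sequence for b in self.barcodes]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate barcode sequences in set")
        if self.min_hamming < 1:
            raise ValueError("min_hamming must be >= 1")

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self) -> Iterator[Barcode]:
        return iter(self.barcodes)

    @property
    def sequences(self) -> list[str]:
        return [b.sequence for b in self.barcodes]

    @property
    def barcode_length(self) -> int:
        return len(self.barcodes[0].sequence)

    def label_of(self, index: int) -> str:
        bc = self.barcodes[index]
        return bc.sample_label if bc.sample_label is not None else bc.sequence

    def to_sample_sheet(self, path: str | Path) -> None:
        """Write the TSV sample sheet (sample_name, barcode_sequence, well)."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["sample_name", "barcode_sequence", "well"])
            for i, bc in enumerate(self.barcodes):
                writer.writerow([self.label_of(i), bc.sequence, bc.well or ""])

    @classmethod
    def from_sample_sheet(cls, path: str | Path, layout: ReadLayout | None = None) -> "BarcodeSet":
        """Read a TSV sample sheet; ``min_hamming`` is set to the observed minimum."""
        barcodes: list[Barcode] = []
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header is None or [h.strip().lower() for h in header[:2]] != [
                "sample_name",
                "barcode_sequence",
            ]:
                raise ValueError(
                    f"{path}: expected header 'sample_name<TAB>barcode_sequence[<TAB>well]', got {header}"
                )
            for row in reader:
                if not row or not "".join(row).strip():
                    continue
                label, seq = row[0].strip(), row[1].strip().upper()
                well = row[2].strip() or None if len(row) > 2 else None
                barcodes.append(Barcode(sequence=seq, sample_label=label, well=well))
        if not barcodes:
            raise ValueError(f"{path}: sample sheet contains no barcodes")
        bset = cls(barcodes=barcodes, min_hamming=1, layout=layout or ReadLayout(barcode_len=len(barcodes[0].sequence)))
        if len(bset) >= 2:
            bset.min_hamming = min_pairwise_distance(bset)
        return bset


def enumerate_candidates(
    length: int,
    gc_target: int,
    max_homopolymer: int | None = None,
    forbidden_motifs: Sequence[str] = (),
) -> list[str]:
    """Enumerate every sequence of ``length`` with exactly ``gc_target`` G/C bases.

    Candidates containing a homopolymer run longer than ``max_homopolymer`` or
    any of ``forbidden_motifs`` as a substring are excluded. The result is in
    lexicographic order (A < C < G < T) and, without filters, has size
    ``C(length, gc_target) * 2**length`` (each chosen position is G or C, each
    remaining position A or T).

    Raises
    ------
    ValueError
        If ``gc_target`` is outside ``[0, length]`` or ``length < 1``.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if not 0 <= gc_target <= length:
        raise ValueError(f"gc_count must be within [0, {length}], got {gc_target}")
    max_run = max_homopolymer if max_homopolymer is not None else length
    motifs = tuple(m.upper() for m in forbidden_motifs)
    out: list[str] = []
    for tup in itertools.product(DNA_ALPHABET, repeat=length):
        seq = "".join(tup)
        if gc_count(seq) != gc_target:
            continue
        if max_homopolymer_run(seq) > max_run:
            continue
        if any(m in seq for m in motifs):
            continue
        out.append(seq)
    return out


def _encode(seqs: Sequence[str]) -> np.ndarray:
    """Pack sequences into a (n, L) uint8 matrix for vectorised Hamming."""
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(len(seqs), -1)


def _assign_wells(n: int) -> list[str | None]:
    # column-wise 96-well coordinates (A1, B1, ... H1, A2, ...), plate-prefixed
    # beyond the first plate
    wells: list[str | None] = []
    for i in range(n):
        plate, pos = divmod(i, 96)
        col, row = divmod(pos, 8)
        coord = f"{_WELL_ROWS[row]}{col + 1}"
        wells.append(coord if plate == 0 else f"P{plate + 1}:{coord}")
    return wells


def design_barcode_set(
    n: int | None,
    length: int = 8,
    gc_target: int = 4,
    min_hamming: int = 3,
    max_homopolymer: int = 2,
    forbidden_motifs: Sequence[str] = DEFAULT_FORBIDDEN_MOTIFS,
    seed: int = 0,
    label_prefix: str = "sample",
) -> BarcodeSet:
    """Select a barcode set satisfying composition and separation constraints.

    Candidates are enumerated under the composition constraints, shuffled with
    ``seed``, and accepted greedily when at Hamming distance >= ``min_hamming``
    from every already-accepted barcode. The procedure is deterministic for a
    fixed seed.

    Parameters
    ----------
    n : int or None
        Number of barcodes requested. ``None`` returns the largest set the
        greedy pass reaches (a maximal, not necessarily maximum, code).

    Raises
    ------
    BarcodeDesignError
        If fewer than ``n`` barcodes are achievable; the error reports the
        maximum size reached.
    """
    if n is not None and n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    pool = enumerate_candidates(length, gc_target, max_homopolymer, forbidden_motifs)
    if not pool:
        raise BarcodeDesignError(
            "no candidate sequences satisfy the composition constraints", max_reached=0
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    mat = _encode(pool)[order]

    selected = np.empty_like(mat)
    k = 0
    for row in mat:
        if k == 0 or int((selected[:k] != row).sum(axis=1).min()) >= min_hamming:
            selected[k] = row
            k += 1
            if n is not None and k == n:
                break
    if n is not None and k < n:
        raise BarcodeDesignError(
            f"cannot satisfy constraints: requested {n} barcodes but only {k} "
            f"achievable (length={length}, gc={gc_target}/{length}, "
            f"min_hamming={min_hamming}, max_homopolymer={max_homopolymer})",
            max_reached=k,
        )
    seqs = ["".join(chr(c) for c in row) for row in selected[:k]]
    width = max(2, len(str(len(seqs))))
    wells = _assign_wells(len(seqs))
    barcodes = [
        Barcode(sequence=s, sample_label=f"{label_prefix}_{i + 1:0{width}d}", well=wells[i])
        for i, s in enumerate(seqs)
    ]
    return BarcodeSet(
        barcodes=barcodes,
        min_hamming=min_hamming,
        layout=ReadLayout(barcode_len=length),
    )


def min_pairwise_distance(bset: BarcodeSet) -> int:
    """Exact minimum Hamming distance over all unordered barcode pairs."""
    if len(bset) < 2:
        raise ValueError("min_pairwise_distance needs a set of size >= 2")
    mat = _encode(bset.sequences)
    best = bset.barcode_length
    for i in range(len(mat) - 1):
        d = int((mat[i + 1 :] != mat[i]).sum(axis=1).min())
        if d < best:
            best = d
    return best


@dataclass
class ValidationReport:
    """Per-constraint pass/fail summary for a barcode set."""

    length_ok: bool
    gc_ok: bool
    homopolymer_ok: bool
    motif_ok: bool
    distance_ok: bool
    min_distance: int | None
    failures: dict[str, list] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(
            (self.length_ok, self.gc_ok, self.homopolymer_ok, self.motif_ok, self.distance_ok)
        )


def validate_barcode_set(
    bset: BarcodeSet,
    gc_target: int | None = None,
    max_homopolymer: int | None = None,
    forbidden_motifs: Sequence[str] = (),
) -> ValidationReport:
    """Check a barcode set against its constraints, reporting every violation.

    Length is checked against the set's layout, pairwise distance against the
    set's declared ``min_hamming`` (vacuously true for a single barcode).
    Composition checks are skipped when their target is ``None``. The report
    carries offending sequences/pairs rather than raising.
    """
    failures: dict[str, list] = {}
    expect_len = bset.layout.barcode_len
    bad_len = [b.sequence for b in bset if len(b.sequence) != expect_len]
    if bad_len:
        failures["length"] = bad_len

    bad_gc: list[str] = []
    if gc_target is not None:
        bad_gc = [b.sequence for b in bset if gc_count(b.sequence) != gc_target]
        if bad_gc:
            failures["gc"] = bad_gc

    bad_homo: list[str] = []
    if max_homopolymer is not None:
        bad_homo = [b.sequence for b in bset if max_homopolymer_run(b.sequence) > max_homopolymer]
        if bad_homo:
            failures["homopolymer"] = bad_homo

    motifs = tuple(m.upper() for m in forbidden_motifs)
    bad_motif = [b.sequence for b in bset if any(m in b.sequence for m in motifs)]
    if bad_motif:
        failures["motif"] = bad_motif

    min_dist: int | None = None
    bad_pairs: list[tuple[str, str, int]] = []
    if len(bset) >= 2:
        seqs = bset.sequences
        min_dist = min_pairwise_distance(bset)
        if min_dist < bset.min_hamming:
            for a, b in itertools.combinations(seqs, 2):
                d = hamming(a, b)
                if d < bset.min_hamming:
                    bad_pairs.append((a, b, d))
            failures["distance"] = bad_pairs

    return ValidationReport(
        length_ok=not bad_len,
        gc_ok=not bad_gc,
        homopolymer_ok=not bad_homo,
        motif_ok=not bad_motif,
        distance_ok=not bad_pairs,
        min_distance=min_dist,
        failures=failures,
    )


def plate_capacity(n_barcodes: int = 96, n_ip_reactions: int = 96) -> int:
    """Number of independent chromatin profiles one full run can yield.

    A pool of ``n_barcodes`` barcoded samples split across ``n_ip_reactions``
    immunoprecipitation reactions gives one profile per (sample, antibody)
    combination: 96 x 96 = 9,216 at full plate capacity.
    """
    if n_barcodes < 1 or n_ip_reactions < 1:
        raise ValueError("n_barcodes and n_ip_reactions must be >= 1")
    return n_barcodes * n_ip_reactions
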