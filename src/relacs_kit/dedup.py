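"""Mapping-quality filtering and UMI-based duplicate removal of read pairs.

Aligned RELACS pairs carry their combined 8-nt UMI as the last
underscore-delimited token of the query name (written there at demux time).
Pairs are first filtered to near-unique alignments (``mapq > 3``), then
grouped by fragment interval — reference, leftmost and rightmost coordinate,
and orientation, i.e. paired-mode grouping; restriction-defined fragments
make both ends informative — and deduplicated within each group by UMI,
either exactly (one representative per distinct UMI) or with the directional
adjacency rule that collapses sequencing-error-derived UMIs into their
abundant parent: an edge runs from UMI ``u`` to ``v`` when they differ by at
most ``umi_mismatch`` bases and ``count(u) >= 2 * count(v) - 1``.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pysam

_UMI_ALPHABET = frozenset("ACGTN")

Orientation = Literal["F1R2", "F2R1"]


class MalformedNameError(ValueError):
    """Query name does not carry an underscore-delimited UMI suffix."""


@dataclass(frozen=True)
class AlignedPairRecord:
    """Minimal view of an aligned read pair for duplicate grouping.

    ``fragment_start``/``fragment_end`` are the 0-based half-open span of the
    whole pair on the reference; ``umi`` is the combined tag parsed from the
    query name.
    """

    query_name: str
    reference: str
    fragment_start: int
    fragment_end: int
    orientation: Orientation
    mapq: int
    umi: str

    def __post_init__(self) -> None:
        if self.fragment_start >= self.fragment_end:
            raise ValueError(
                f"{self.query_name}: fragment_start {self.fragment_start} "
                f">= fragment_end {self.fragment_end}"
            )

    @property
    def group_key(self) -> tuple[str, int, int, str]:
        return (self.reference, self.fragment_start, self.fragment_end, self.orientation)


def parse_umi_from_name(query_name: str) -> str:
    """Extract the UMI from a ``<name>_<umi>`` query name.

    The UMI is the substring after the *last* underscore, up to the first
    whitespace; it must be non-empty and over {A, C, G, T, N}.
    """
    head = query_name.split(None, 1)[0] if query_name.strip() else ""
    if "_" not in head:
        raise MalformedNameError(f"no underscore-delimited UMI suffix in {query_name!r}")
    umi = head.rsplit("_", 1)[1]
    if not umi or not set(umi) <= _UMI_ALPHABET:
        raise MalformedNameError(f"invalid UMI {umi!r} in query name {query_name!r}")
    return umi


def filter_mapq(
    records: Iterable[AlignedPairRecord], threshold: int = 3
) -> list[AlignedPairRecord]:
    """Keep records with mapping quality *strictly greater* than ``threshold``."""
    return [r for r in records if r.mapq > threshold]


@dataclass
class DedupStats:
    input_pairs: int
    retained_pairs: int
    duplicates_removed: int
    group_cluster_counts: dict[tuple[str, int, int, str], int] = field(default_factory=dict)
    pairs_below_mapq: int = 0

    @property
    def duplication_rate(self) -> float:
        return self.duplicates_removed / self.input_pairs if self.input_pairs else 0.0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "input_pairs": self.input_pairs,
                    "retained_pairs": self.retained_pairs,
                    "duplicates_removed": self.duplicates_removed,
                    "duplication_rate": self.duplication_rate,
                    "pairs_below_mapq": self.pairs_below_mapq,
                    "n_position_groups": len(self.group_cluster_counts),
                    "groups": [
                        {
                            "reference": ref,
                            "start": start,
                            "end": end,
                            "orientation": orient,
                            "umi_clusters": n,
                        }
                        for (ref, start, end, orient), n in self.group_cluster_counts.items()
                    ],
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def _umi_hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def directional_clusters(counts: Counter[str], umi_mismatch: int = 1) -> list[set[str]]:
    """Cluster UMIs with the directional adjacency rule.

    Nodes are visited in decreasing count order (ties broken
    lexicographically); from each unvisited seed, a breadth-first walk
    follows edges ``u -> v`` that exist when ``Hamming(u, v) <=
    umi_mismatch`` and ``count(u) >= 2 * count(v) - 1``. Each walk yields one
    cluster, so an abundant parent absorbs its one-off error neighbours but
    two similarly-abundant UMIs stay separate.
    """
    order = sorted(counts, key=lambda u: (-counts[u], u))
    visited: set[str] = set()
    clusters: list[set[str]] = []
    for seed in order:
        if seed in visited:
            continue
        component = {seed}
        visited.add(seed)
        queue = [seed]
        while queue:
            u = queue.pop()
            cu = counts[u]
            for v in order:
                if v in visited:
                    continue
                if _umi_hamming(u, v) <= umi_mismatch and cu >= 2 * counts[v] - 1:
                    visited.add(v)
                    component.add(v)
                    queue.append(v)
        clusters.append(component)
    return clusters


def dedup_pairs(
    records: Sequence[AlignedPairRecord],
    method: Literal["exact", "directional"] = "directional",
    umi_mismatch: int = 1,
) -> tuple[list[AlignedPairRecord], DedupStats]:
    """Remove UMI duplicates within fragment-interval groups.

    ``exact`` keeps one representative per distinct UMI per group;
    ``directional`` additionally merges error-derived UMIs (see
    :func:`directional_clusters`). The representative of a cluster is the
    first record of that cluster in input order, so the operation is
    deterministic and idempotent for a fixed input order.
    """
    if method not in ("exact", "directional"):
        raise ValueError(f"unknown dedup method: {method!r}")
    umi_lens = {len(r.umi) for r in records}
    if len(umi_lens) > 1:
        raise ValueError(f"inconsistent UMI lengths in input: {sorted(umi_lens)}")

    groups: dict[tuple, list[int]] = defaultdict(list)
    for i, rec in enumerate(records):
        groups[rec.group_key].append(i)

    keep: set[int] = set()  # positions in `records`, to preserve global input order
    cluster_counts: dict[tuple, int] = {}
    for key, member_idx in groups.items():
        if method == "exact":
            seen: set[str] = set()
            n_clusters = 0
            for i in member_idx:
                umi = records[i].umi
                if umi not in seen:
                    seen.add(umi)
                    keep.add(i)
                    n_clusters += 1
        else:
            counts = Counter(records[i].umi for i in member_idx)
            clusters = directional_clusters(counts, umi_mismatch)
            umi_to_cluster = {u: ci for ci, cl in enumerate(clusters) for u in cl}
            first_of: dict[int, int] = {}
            for i in member_idx:
                ci = umi_to_cluster[records[i].umi]
                if ci not in first_of:
                    first_of[ci] = i
            keep.update(first_of.values())
            n_clusters = len(clusters)
        cluster_counts[key] = n_clusters

    retained = [records[i] for i in sorted(keep)]
    stats = DedupStats(
        input_pairs=len(records),
        retained_pairs=len(retained),
        duplicates_removed=len(records) - len(retained),
        group_cluster_counts=cluster_counts,
    )
    return retained, stats


def _orientation(read1_reverse: bool) -> Orientation:
    return "F2R1" if read1_reverse else "F1R2"


def read_aligned_pairs(path: str | Path) -> tuple[list[AlignedPairRecord], "pysam.AlignmentHeader"]:
    """Load primary, mapped, properly-paired records from a SAM/BAM file.

    Mates are joined on query name; unmapped, secondary and supplementary
    records are skipped, as are query names for which only one mate is
    present. The pair's mapq is the minimum of the two mates' values, its
    fragment interval the union span of both alignments (soft-clipped bases
    are not un-clipped), and its orientation follows read1's strand.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    pairs: list[AlignedPairRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        header = fh.header
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            r1, r2 = (read, mate) if read.is_read1 else (mate, read)
            if r1.reference_name != r2.reference_name:
                continue  # discordant pairs carry no single fragment interval
            pairs.append(
                AlignedPairRecord(
                    query_name=r1.query_name,
                    reference=r1.reference_name,
                    fragment_start=min(r1.reference_start, r2.reference_start),
                    fragment_end=max(r1.reference_end, r2.reference_end),
                    orientation=_orientation(r1.is_reverse),
                    mapq=min(r1.mapping_quality, r2.mapping_quality),
                    umi=parse_umi_from_name(r1.query_name),
                )
            )
    return pairs, header


def dedup_sam(
    in_path: str | Path,
    out_path: str | Path,
    mapq_threshold: int = 3,
    method: Literal["exact", "directional"] = "directional",
    umi_mismatch: int = 1,
    stats_path: str | Path | None = None,
) -> DedupStats:
    """Filter a SAM/BAM file by pair mapq and UMI-deduplicate it.

    Writes retained pairs (both mates, original records) to ``out_path`` as
    SAM with the input header preserved, and the statistics to
    ``stats_path`` (default: ``dedup_stats.json`` next to the output).
    ``DedupStats.input_pairs`` counts pairs entering deduplication, i.e.
    after the mapq filter; pairs removed by the filter are reported in
    ``pairs_below_mapq``.
    """
    pairs, header = read_aligned_pairs(in_path)
    passing = filter_mapq(pairs, mapq_threshold)
    retained, stats = dedup_pairs(passing, method=method, umi_mismatch=umi_mismatch)
    stats.pairs_below_mapq = len(pairs) - len(passing)

    keep_names = {r.query_name for r in retained}
    with pysam.AlignmentFile(str(in_path), check_sq=False) as src, pysam.AlignmentFile(
        str(out_path), "w", header=header
    ) as dst:
        for read in src:
            if read.query_name in keep_names and not (
                read.is_secondary or read.is_supplementary
            ):
                dst.write(read)

    stats_file = Path(stats_path) if stats_path else Path(out_path).parent / "dedup_stats.json"
    stats.to_json(stats_file)
    return stats
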