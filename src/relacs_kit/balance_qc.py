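"""Barcode-balance statistics and sequencing-depth estimation.

After barcoded chromatin from many samples is pooled, an input-control lane
reveals how evenly the barcodes are represented. Under perfect balance each
of ``n`` barcodes captures ``100 / n`` percent of the pool (1.667% for a
60-plex). The summary here mirrors that readout: per-barcode percentages,
their mean and standard deviation, and the fold-deviation of the extremes
from uniform. A shallow input run also calibrates how deep the full run must
be sequenced so that even the rarest sample reaches a target read count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from relacs_kit.demux import DemuxReport


@dataclass
class BarcodeCounts:
    """Assigned read-pair counts per barcode (or per sample)."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("BarcodeCounts needs at least one barcode")
        neg = {k: v for k, v in self.counts.items() if v < 0}
        if neg:
            raise ValueError(f"negative counts: {neg}")

    @property
    def n_barcodes(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_demux_report(
        cls, report: DemuxReport | str | Path, include_undetermined: bool = False
    ) -> "BarcodeCounts":
        """Build counts from a demux report object or its TSV on disk.

        By default only barcode-assigned pairs enter the balance statistics;
        ``include_undetermined`` adds one pseudo-category holding all
        unassigned pairs.
        """
        if not isinstance(report, DemuxReport):
            report = DemuxReport.from_tsv(report)
        counts = dict(zip(report.barcodes, report.pair_counts))
        if include_undetermined:
            counts["undetermined"] = report.unassigned_pairs
        return cls(counts=counts)


@dataclass
class BalanceSummary:
    percent: dict[str, float]
    mean_percent: float
    sd_percent: float  # population sd, ddof=0
    sd_percent_sample: float  # ddof=1 (nan for a single barcode)
    uniform_percent: float
    max_fold_deviation: float
    min_fold_deviation: float
    missing_barcodes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mean_percent": self.mean_percent,
                    "sd_percent": self.sd_percent,
                    "sd_percent_sample": self.sd_percent_sample,
                    "uniform_percent": self.uniform_percent,
                    "max_fold_deviation": self.max_fold_deviation,
                    "min_fold_deviation": self.min_fold_deviation,
                    "missing_barcodes": self.missing_barcodes,
                    "percent": self.percent,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("barcode\tpercent\tfold_deviation\n")
            for bc, pct in self.percent.items():
                fold = pct / self.uniform_percent if self.uniform_percent else math.nan
                fh.write(f"{bc}\t{pct:.4f}\t{fold:.4f}\n")


def barcode_balance(counts: BarcodeCounts) -> BalanceSummary:
    """Per-barcode percentage summary against the uniform expectation.

    ``percent_i = 100 * count_i / total``; the mean of category percentages
    is identically ``100 / n`` whenever the total is positive, so deviations
    show up in the standard deviation and the fold-deviation extremes, not in
    the mean. Barcodes with zero reads are flagged as missing.
    """
    total = counts.total
    if total == 0:
        raise ValueError("all barcode counts are zero; balance is undefined")
    pct = {k: 100.0 * v / total for k, v in counts.counts.items()}
    values = np.fromiter(pct.values(), dtype=float)
    uniform = 100.0 / counts.n_barcodes
    return BalanceSummary(
        percent=pct,
        mean_percent=float(values.mean()),
        sd_percent=float(values.std(ddof=0)),
        sd_percent_sample=float(values.std(ddof=1)) if len(values) > 1 else math.nan,
        uniform_percent=uniform,
        max_fold_deviation=float(values.max() / uniform),
        min_fold_deviation=float(values.min() / uniform),
        missing_barcodes=[k for k, v in counts.counts.items() if v == 0],
    )


@dataclass
class DepthEstimate:
    total_pairs: int
    per_barcode_projection: dict[str, float]
    limiting_barcode: str
    min_fraction: float
    min_reads_per_sample: int
    safety_factor: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "total_pairs": self.total_pairs,
                    "limiting_barcode": self.limiting_barcode,
                    "min_fraction": self.min_fraction,
                    "min_reads_per_sample": self.min_reads_per_sample,
                    "safety_factor": self.safety_factor,
                    "per_barcode_projection": self.per_barcode_projection,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def estimate_required_depth(
    counts: BarcodeCounts | Mapping[str, int],
    min_reads_per_sample: int,
    safety_factor: float = 1.0,
) -> DepthEstimate:
    """Total sequencing depth guaranteeing a minimum per-sample read count.

    Uses the plug-in fractions from a shallow run: with ``fraction_i =
    count_i / total_observed``, the rarest barcode dictates
    ``total = ceil(safety_factor * min_reads_per_sample / min_i fraction_i)``,
    and each barcode's projected yield is ``fraction_i * total``. The
    estimate is monotone non-decreasing in ``min_reads_per_sample``.

    Raises
    ------
    ValueError
        If any barcode has zero observed reads — no finite depth can
        guarantee its coverage; the error names the offending barcodes.
    """
    if not isinstance(counts, BarcodeCounts):
        counts = BarcodeCounts(counts=dict(counts))
    if min_reads_per_sample < 0:
        raise ValueError("min_reads_per_sample must be >= 0")
    if safety_factor <= 0:
        raise ValueError("safety_factor must be > 0")
    zero = [k for k, v in counts.counts.items() if v == 0]
    if zero:
        raise ValueError(
            "depth estimate undefined: zero observed reads for barcode(s) "
            + ", ".join(zero)
        )
    total_obs = counts.total
    fractions = {k: v / total_obs for k, v in counts.counts.items()}
    limiting = min(fractions, key=lambda k: (fractions[k], k))
    min_frac = fractions[limiting]
    total = math.ceil(safety_factor * min_reads_per_sample / min_frac)
    return DepthEstimate(
        total_pairs=total,
        per_barcode_projection={k: f * total for k, f in fractions.items()},
        limiting_barcode=limiting,
        min_fraction=min_frac,
        min_reads_per_sample=min_reads_per_sample,
        safety_factor=safety_factor,
    )


def plot_balance(summary: BalanceSummary, path: str | Path) -> None:
    """Bar plot of per-barcode percentages with the uniform line and ±1 sd band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(summary.percent)
    values = list(summary.percent.values())
    fig, ax = plt.subplots(figsize=(max(6.0, 0.16 * len(names)), 4.0))
    ax.bar(range(len(names)), values, color="#4878a8")
    ax.axhline(summary.uniform_percent, linestyle="--", color="black", linewidth=1,
               label=f"uniform 100/{len(names)}")
    ax.axhspan(
        summary.mean_percent - summary.sd_percent,
        summary.mean_percent + summary.sd_percent,
        color="grey",
        alpha=0.3,
        label="mean ± 1 sd",
    )
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=90, fontsize=5)
    ax.set_ylabel("% of input read pairs")
    ax.set_xlabel("barcode")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
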