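"""End-to-end smoke pipeline: design -> simulate -> demux -> QC -> dedup.

Runs the whole computational workflow on a synthetic reference, standing in
for a real sequencing run: a toy genome is generated, a barcode set designed
and written as a sample sheet, a multiplexed run simulated (with a
truth-derived SAM as the alignment stage stand-in), demultiplexed, balance-
and depth-checked, and UMI-deduplicated. All randomness flows from the
single configured seed, so identical configurations give identical reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from relacs_kit import balance_qc, barcode_design, demux, dedup, simulator


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


DEFAULT_CONFIG: dict = {
    "seed": 7,
    "n_samples": 4,
    "n_pairs": 10_000,
    "read_len": 50,
    "umi_len": 4,
    "barcode_len": 8,
    "gc_count": 4,
    "min_hamming": 3,
    "max_homopolymer": 2,
    "motif": "GATC",
    "cut_offset": 0,
    "error_rate": 0.001,
    "pcr_duplicate_rate": 0.1,
    "mate_policy": "both-agree",
    "max_mismatch": None,
    "dedup_method": "directional",
    "umi_mismatch": 1,
    "mapq_threshold": 3,
    "min_reads_per_sample": 100,
    "genome_contigs": 2,
    "genome_contig_length": 20_000,
    "compress": True,
}


@dataclass
class EndToEndResult:
    out_dir: Path
    genome: Path
    sample_sheet: Path
    sim: simulator.SimRun
    demux_report: demux.DemuxReport
    balance: balance_qc.BalanceSummary
    depth: balance_qc.DepthEstimate
    dedup_stats: dedup.DedupStats


def load_config(path: str | Path) -> dict:
    """Read a JSON or YAML pipeline configuration, filling in defaults."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        user = yaml.safe_load(text)
    else:
        user = json.loads(text)
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return {**DEFAULT_CONFIG, **user}


def run_end_to_end(out_dir: str | Path, config: dict | str | Path | None = None) -> EndToEndResult:
    """Run every stage under ``out_dir``; raises :class:`PipelineError` on failure."""
    if config is None:
        cfg = dict(DEFAULT_CONFIG)
    elif isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = {**DEFAULT_CONFIG, **config}

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(f"stage '{name}' failed: {exc}") from exc
                return False

        return _Ctx()

    with stage("genome"):
        genome = simulator.write_toy_genome(
            out_dir / "genome.fa",
            n_contigs=int(cfg["genome_contigs"]),
            contig_length=int(cfg["genome_contig_length"]),
            seed=seed,
        )

    with stage("design"):
        bset = barcode_design.design_barcode_set(
            n=int(cfg["n_samples"]),
            length=int(cfg["barcode_len"]),
            gc_target=int(cfg["gc_count"]),
            min_hamming=int(cfg["min_hamming"]),
            max_homopolymer=int(cfg["max_homopolymer"]),
            forbidden_motifs=(cfg["motif"],),
            seed=seed,
        )
        sheet = out_dir / "sample_sheet.tsv"
        bset.to_sample_sheet(sheet)

    with stage("simulate"):
        sim_cfg = simulator.SimConfig(
            samples=[
                simulator.SampleSpec(label=bset.label_of(i), barcode=bc.sequence)
                for i, bc in enumerate(bset)
            ],
            n_pairs=int(cfg["n_pairs"]),
            motif=str(cfg["motif"]),
            cut_offset=int(cfg["cut_offset"]),
            read_len=int(cfg["read_len"]),
            umi_len=int(cfg["umi_len"]),
            error_rate=float(cfg["error_rate"]),
            pcr_duplicate_rate=float(cfg["pcr_duplicate_rate"]),
            seed=seed,
        )
        sim = simulator.simulate_run(
            genome,
            sim_cfg,
            out_dir / "sim" / "run",
            compress=bool(cfg["compress"]),
            truth_sam=True,
        )

    with stage("demux"):
        report = demux.demultiplex(
            sim.r1_path,
            sim.r2_path,
            bset,
            out_dir / "demux",
            max_mismatch=cfg["max_mismatch"],
            mate_policy=str(cfg["mate_policy"]),
            compress=bool(cfg["compress"]),
        )

    with stage("qc"):
        qc_dir = out_dir / "qc"
        qc_dir.mkdir(exist_ok=True)
        counts = balance_qc.BarcodeCounts.from_demux_report(report)
        balance = balance_qc.barcode_balance(counts)
        balance.to_tsv(qc_dir / "balance_summary.tsv")
        balance.to_json(qc_dir / "balance_summary.json")
        depth = balance_qc.estimate_required_depth(counts, int(cfg["min_reads_per_sample"]))
        depth.to_json(qc_dir / "depth_estimate.json")

    with stage("dedup"):
        dd_dir = out_dir / "dedup"
        dd_dir.mkdir(exist_ok=True)
        stats = dedup.dedup_sam(
            sim.sam_path,
            dd_dir / "dedup.sam",
            mapq_threshold=int(cfg["mapq_threshold"]),
            method=cfg["dedup_method"],
            umi_mismatch=int(cfg["umi_mismatch"]),
            stats_path=dd_dir / "dedup_stats.json",
        )

    return EndToEndResult(
        out_dir=out_dir,
        genome=Path(genome),
        sample_sheet=sheet,
        sim=sim,
        demux_report=report,
        balance=balance,
        depth=depth,
        dedup_stats=stats,
    )
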