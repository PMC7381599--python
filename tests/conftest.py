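"""Shared fixtures: synthetic references and small designed barcode sets."""

from pathlib import Path

import pytest

from relacs_kit import barcode_design, simulator


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory) -> Path:
    """Small random two-contig reference with plenty of GATC sites."""
    path = tmp_path_factory.mktemp("genome") / "toy.fa"
    simulator.write_toy_genome(path, n_contigs=2, contig_length=20_000, seed=11)
    return path


@pytest.fixture(scope="session")
def small_bset() -> barcode_design.BarcodeSet:
    """Six default-constraint barcodes (8 nt, 4 GC, min Hamming 3)."""
    return barcode_design.design_barcode_set(6, seed=3)


def write_fastq(path: Path, records: list[tuple[str, str, str]]) -> Path:
    """Write (name, seq, qual) records as a plain 4-line FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    return path


@pytest.fixture()
def fastq_writer():
    return write_fastq
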