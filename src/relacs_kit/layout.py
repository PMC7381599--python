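"""Positional contract of a RELACS read: UMI then inline barcode then insert."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReadLayout:
    """Where the technical bases sit at the start of each mate.

    Both mates of a RELACS pair carry the same prefix structure: ``umi_len``
    random bases followed by ``barcode_len`` sample-barcode bases, then the
    genomic insert. The default layout (4 + 8) matches the published adaptor
    design; the two mate UMIs concatenate into a ``2 * umi_len`` fragment tag.

    Parameters
    ----------
    umi_len : int
        Number of random identifier bases at the start of each mate (>= 0).
    barcode_len : int
        Number of sample-barcode bases following the UMI (>= 1).
    """

    umi_len: int = 4
    barcode_len: int = 8

    def __post_init__(self) -> None:
        if self.umi_len < 0:
            raise ValueError(f"umi_len must be >= 0, got {self.umi_len}")
        if self.barcode_len < 1:
            raise ValueError(f"barcode_len must be >= 1, got {self.barcode_len}")

    @property
    def prefix_len(self) -> int:
        """Total technical bases trimmed from the 5' end of each mate."""
        return self.umi_len + self.barcode_len

    @property
    def combined_umi_len(self) -> int:
        """Length of the fragment tag formed by joining both mate UMIs."""
        return 2 * self.umi_len
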