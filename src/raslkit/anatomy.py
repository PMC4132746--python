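"""The fixed layout of a ligation-assay sequencing read.

A read is the concatenation

    well_barcode (8 nt) + AD1 (17 nt) + acceptor_gene (20 nt)
    + donor_gene (20 nt) + RCAD2 (17 nt) + RChSP3 (17 nt) [+ 1 nt pad]

totalling 99 nt of signal in a 100-nt read; the plate barcode (7 nt)
arrives in a separate 8-nt index read.  AD1 sits 5' of the acceptor
gene-specific half on the acceptor oligo; RCAD2 sits 3' of the donor
half on the donor oligo, so the ligated, amplified product reads
through both adaptors in this order.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReadAnatomy", "AD1", "RCAD2", "RCHSP3", "DEFAULT_ANATOMY"]

AD1 = "GGAAGCCTTGGCTTTTG"
RCAD2 = "AGATCGGAAGAGCACAC"
RCHSP3 = "GTCTGAACTCCAGTCAC"


@dataclass(frozen=True)
class ReadAnatomy:
    """Segment lengths and constant sequences of one read."""

    well_bc_len: int = 8
    ad1: str = AD1
    probe_region_len: int = 40
    rcad2: str = RCAD2
    rchsp3: str = RCHSP3
    read_len: int = 100
    index_read_len: int = 8
    plate_bc_len: int = 7
    pad_base: str = "A"

    def __post_init__(self) -> None:
        if self.min_payload > self.read_len:
            raise ValueError("read layout does not fit in read_len")
        if self.plate_bc_len > self.index_read_len:
            raise ValueError("plate barcode longer than index read")

    @property
    def tail(self) -> str:
        """Constant 3' adaptor block (RCAD2 + RChSP3)."""
        return self.rcad2 + self.rchsp3

    @property
    def probe_offset(self) -> int:
        return self.well_bc_len + len(self.ad1)

    @property
    def tail_offset(self) -> int:
        return self.probe_offset + self.probe_region_len

    @property
    def min_payload(self) -> int:
        return self.tail_offset + len(self.tail)


DEFAULT_ANATOMY = ReadAnatomy()
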