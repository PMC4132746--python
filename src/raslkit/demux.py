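"""Deconvolution of pooled reads into on/off-target count matrices.

Stage order matches the assay's published pipeline: plate demultiplex
by the index read, collapse to unique sequences (counts preserved),
isolate the well barcode and probe region by exact adaptor matching
(with a one-mismatch rescue for AD1), assign the well barcode, map the
probe region against all acceptor x donor combinations, and sum
collapsed multiplicities into probe-set x sample matrices.  Reads are
conserved: every input read lands in exactly one tally.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .align import Hit, MapperConfig, ProbeMapper
from .anatomy import DEFAULT_ANATOMY, ReadAnatomy
from .barcodes import UNASSIGNED, BarcodeSet, assign_barcode
from .design import ProbeSet

__all__ = [
    "CollapsedRead",
    "MappedRead",
    "DemuxStats",
    "DemuxResult",
    "demultiplex_plates",
    "collapse_unique",
    "parse_anatomy",
    "map_probe_region",
    "build_matrices",
    "run_demux",
]


@dataclass(frozen=True)
class CollapsedRead:
    sequence: str
    count: int


@dataclass(frozen=True)
class MappedRead:
    """One unique read sequence resolved to its sample and probe pair."""

    plate: int
    well: int
    acceptor_id: str
    donor_id: str
    on_target: bool
    score: int
    query_start: int
    length: int
    count: int


@dataclass
class DemuxStats:
    """Per-stage read-conservation tallies (in input-read units)."""

    total: int = 0
    plate_unassigned: int = 0
    unparsed: int = 0
    well_len_filtered: int = 0
    well_unassigned: int = 0
    no_hit: int = 0
    mapped_on: int = 0
    mapped_off: int = 0
    unique_sequences: int = 0

    @property
    def mapped(self) -> int:
        return self.mapped_on + self.mapped_off

    @property
    def accounted(self) -> int:
        return (
            self.plate_unassigned
            + self.unparsed
            + self.well_len_filtered
            + self.well_unassigned
            + self.no_hit
            + self.mapped
        )

    @property
    def compression(self) -> float:
        n = self.total - self.plate_unassigned
        return n / self.unique_sequences if self.unique_sequences else 1.0


@dataclass
class DemuxResult:
    on_target: pd.DataFrame  # probe sets x samples
    off_target: pd.DataFrame  # acceptor|donor pairs x samples
    sample_meta: pd.DataFrame | None
    stats: DemuxStats
    mapped: list[MappedRead] = field(default_factory=list)


def demultiplex_plates(
    reads: list[tuple[str, str]],
    index_reads: list[tuple[str, str]],
    plates: BarcodeSet,
    anatomy: ReadAnatomy = DEFAULT_ANATOMY,
    max_dist: int = 1,
) -> tuple[dict[int, list[str]], int]:
    """Route each read by its index read's plate barcode.

    Returns ({plate_index: [read sequences]}, n_unassigned); the sum of
    routed reads plus unassigned equals the input count.
    """
    if len(reads) != len(index_reads):
        raise ValueError(
            f"read/index pairing error: {len(reads)} reads vs "
            f"{len(index_reads)} index reads"
        )
    streams: dict[int, list[str]] = {}
    unassigned = 0
    for (_, read), (_, idx_read) in zip(reads, index_reads):
        observed = idx_read[: anatomy.plate_bc_len]
        plate = assign_barcode(observed, plates, max_dist)
        if plate == UNASSIGNED:
            unassigned += 1
        else:
            streams.setdefault(plate, []).append(read)
    return streams, unassigned


def collapse_unique(stream: list[str]) -> list[CollapsedRead]:
    """Exact-string deduplication preserving multiplicities."""
    counts = Counter(stream)
    return [CollapsedRead(seq, n) for seq, n in counts.items()]


def parse_anatomy(
    read: str, anatomy: ReadAnatomy = DEFAULT_ANATOMY
) -> tuple[str, str] | None:
    """Isolate (well_barcode, probe_region) from one read, or None.

    AD1 is located by exact string match, then by a single-substitution
    scan around the expected offset (+/- 2).  The probe region runs from
    the end of AD1 to the exact tail match (full tail first, then its
    RCAD2 prefix), or to the read end when the tail is not found.
    """
    ad1 = anatomy.ad1
    pos = read.find(ad1)
    if pos == -1:
        expected = anatomy.well_bc_len
        for off in sorted(
            range(max(0, expected - 2), expected + 3), key=lambda o: abs(o - expected)
        ):
            window = read[off : off + len(ad1)]
            if len(window) == len(ad1) and (
                sum(a != b for a, b in zip(window, ad1)) <= 1
            ):
                pos = off
                break
        if pos == -1:
            return None
    well_bc = read[:pos]
    start = pos + len(ad1)
    tail_pos = read.find(anatomy.tail, start)
    if tail_pos == -1:
        tail_pos = read.find(anatomy.rcad2, start)
    end = tail_pos if tail_pos != -1 else len(read)
    return well_bc, read[start:end]


def map_probe_region(seq: str, mapper: ProbeMapper) -> Hit | None:
    """Best filtered acceptor/donor hit for one probe region."""
    if not seq:
        return None
    return mapper.map(seq)


def build_matrices(
    mapped: list[MappedRead],
    probe_ids: list[str],
    metadata: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Sum mapped multiplicities into count matrices.

    on-target rows: every probe set in the table (zero-filled);
    off-target rows: observed acceptor|donor pairs with i != j.
    Columns are samples labelled "plate:well".  Metadata (columns
    'plate' and 'well' plus annotations) is joined per sample; duplicate
    (plate, well) keys raise.
    """
    samples = sorted({(m.plate, m.well) for m in mapped})
    labels = [f"{p}:{w}" for p, w in samples]
    on = pd.DataFrame(0, index=pd.Index(probe_ids, name="set_id"), columns=labels)
    off_rows: dict[str, dict[str, int]] = {}
    for m in mapped:
        col = f"{m.plate}:{m.well}"
        if m.on_target:
            on.loc[m.acceptor_id, col] += m.count
        else:
            key = f"{m.acceptor_id}|{m.donor_id}"
            off_rows.setdefault(key, {})[col] = (
                off_rows.setdefault(key, {}).get(col, 0) + m.count
            )
    off = (
        pd.DataFrame.from_dict(off_rows, orient="index")
        .reindex(columns=labels)
        .fillna(0)
        .astype(int)
        .sort_index()
    )
    off.index.name = "acceptor|donor"
    meta_joined = None
    if metadata is not None:
        if metadata.duplicated(subset=["plate", "well"]).any():
            raise ValueError("metadata join error: duplicate (plate, well) keys")
        meta = metadata.copy()
        meta["sample"] = (
            meta["plate"].astype(str) + ":" + meta["well"].astype(str)
        )
        meta_joined = meta.set_index("sample").reindex(labels)
    return on, off, meta_joined


def run_demux(
    reads: list[tuple[str, str]],
    index_reads: list[tuple[str, str]],
    probes: list[ProbeSet],
    wells: BarcodeSet,
    plates: BarcodeSet,
    metadata: pd.DataFrame | None = None,
    anatomy: ReadAnatomy = DEFAULT_ANATOMY,
    mapper_cfg: MapperConfig = MapperConfig(),
    rescue_dist: int = 1,
) -> DemuxResult:
    """Full deconvolution of one run into count matrices."""
    stats = DemuxStats(total=len(reads))
    streams, stats.plate_unassigned = demultiplex_plates(
        reads, index_reads, plates, anatomy, rescue_dist
    )
    mapper = ProbeMapper(
        [p.acceptor_gene_seq for p in probes],
        [p.donor_gene_seq for p in probes],
        mapper_cfg,
    )
    min_bc, max_bc = 6, 10  # observed well-barcode length bounds (strict)
    mapped: list[MappedRead] = []
    for plate_idx in sorted(streams):
        collapsed = collapse_unique(streams[plate_idx])
        stats.unique_sequences += len(collapsed)
        for cr in collapsed:
            parsed = parse_anatomy(cr.sequence, anatomy)
            if parsed is None:
                stats.unparsed += cr.count
                continue
            well_bc, region = parsed
            if not (min_bc < len(well_bc) < max_bc):
                stats.well_len_filtered += cr.count
                continue
            well_idx = assign_barcode(well_bc, wells, rescue_dist)
            if well_idx == UNASSIGNED:
                stats.well_unassigned += cr.count
                continue
            hit = map_probe_region(region, mapper)
            if hit is None:
                stats.no_hit += cr.count
                continue
            on = hit.acceptor_idx == hit.donor_idx
            if on:
                stats.mapped_on += cr.count
            else:
                stats.mapped_off += cr.count
            mapped.append(
                MappedRead(
                    plate=plate_idx,
                    well=well_idx,
                    acceptor_id=probes[hit.acceptor_idx].set_id,
                    donor_id=probes[hit.donor_idx].set_id,
                    on_target=on,
                    score=hit.score,
                    query_start=hit.query_start,
                    length=hit.length,
                    count=cr.count,
                )
            )
    on_df, off_df, meta = build_matrices(
        mapped, [p.set_id for p in probes], metadata
    )
    assert stats.accounted == stats.total, "read conservation violated"
    return DemuxResult(on_df, off_df, meta, stats, mapped)
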