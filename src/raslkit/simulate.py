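"""Synthetic sequencing-run generator with per-read ground truth.

Emits reads with the assay's fixed anatomy (well barcode, AD1,
acceptor+donor gene-specific halves, constant tail) plus matched index
reads carrying the plate barcode.  Read counts per (sample, probe)
cell are multinomial around an expected-abundance matrix, scaled down
per probe by any decoy plan; a configurable fraction of reads are
off-target chimeras joining the acceptor of one set to the donor of
another; sequencing noise is i.i.d. per-base substitution.

The generator also computes, by exhaustive enumeration of low-weight
error patterns through the actual demultiplex/parse/map policies, the
analytically expected fraction of reads surviving the full pipeline --
the yardstick the simulation round-trip tests compare against.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import MapperConfig, ProbeMapper
from .anatomy import DEFAULT_ANATOMY, ReadAnatomy
from .barcodes import UNASSIGNED, BarcodeSet, assign_barcode
from .design import ProbeSet
from .quantify import DecoyPlanEntry

__all__ = [
    "SimConfig",
    "SimResult",
    "assemble_read",
    "simulate_run",
    "uniform_abundance",
    "RetentionEstimate",
    "expected_retention",
]

_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}


class AnatomyError(ValueError):
    """A read component does not fit the declared layout."""


def assemble_read(
    well_bc: str,
    acceptor_gene: str,
    donor_gene: str,
    anatomy: ReadAnatomy = DEFAULT_ANATOMY,
) -> str:
    """Concatenate one read: well_bc + AD1 + probe halves + tail, padded
    with the filler base (or truncated) to the fixed read length."""
    if len(well_bc) != anatomy.well_bc_len:
        raise AnatomyError(
            f"well barcode length {len(well_bc)} != {anatomy.well_bc_len}"
        )
    if not acceptor_gene or not donor_gene:
        raise AnatomyError("zero-length probe region component")
    read = well_bc + anatomy.ad1 + acceptor_gene + donor_gene + anatomy.tail
    if len(read) < anatomy.read_len:
        read += anatomy.pad_base * (anatomy.read_len - len(read))
    return read[: anatomy.read_len]


@dataclass
class SimConfig:
    """One simulated pooled run.

    samples: (plate_index, well_index) pairs into the barcode sets.
    abundance: expected relative counts, shape (n_probes, n_samples).
    decoy_plan: per-probe decoy entries; expected counts are divided by
    each entry's predicted fold reduction.
    """

    probes: list[ProbeSet]
    wells: BarcodeSet
    plates: BarcodeSet
    samples: list[tuple[int, int]]
    abundance: np.ndarray
    total_reads: int = 10000
    off_target_rate: float = 0.0
    error_rate: float = 0.0
    decoy_plan: list[DecoyPlanEntry] = field(default_factory=list)
    anatomy: ReadAnatomy = DEFAULT_ANATOMY

    def __post_init__(self) -> None:
        if not self.probes:
            raise ValueError("empty probe table")
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.shape != (len(self.probes), len(self.samples)):
            raise ValueError("abundance must be (n_probes, n_samples)")
        if (self.abundance < 0).any():
            raise ValueError("expected counts must be >= 0")
        for r in (self.off_target_rate, self.error_rate):
            if not (0 <= r <= 1):
                raise ValueError("rates must lie in [0, 1]")

    def expected_matrix(self) -> np.ndarray:
        """Abundance after decoy fold reductions."""
        fold = np.ones(len(self.probes))
        by_id = {p.set_id: i for i, p in enumerate(self.probes)}
        for e in self.decoy_plan:
            if e.set_id in by_id:
                fold[by_id[e.set_id]] = e.predicted_fold_reduction
        return self.abundance / fold[:, None]


@dataclass
class SimResult:
    reads: list[tuple[str, str]]  # (read_id, sequence)
    index_reads: list[tuple[str, str]]
    truth: pd.DataFrame  # read_id, plate, well, acceptor, donor, on_target


def uniform_abundance(n_probes: int, n_samples: int, level: float = 1.0) -> np.ndarray:
    return np.full((n_probes, n_samples), level)


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate == 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits) == 0:
        return seq
    chars = list(seq)
    for i in hits:
        chars[i] = _OTHER[chars[i]][rng.integers(3)]
    return "".join(chars)


def simulate_run(cfg: SimConfig, seed: int = 0) -> SimResult:
    """Deterministic (given seed) synthetic run with ground truth."""
    rng = np.random.default_rng(seed)
    expected = cfg.expected_matrix()
    total = expected.sum()
    if total <= 0:
        raise ValueError("all expected counts are zero")
    counts = rng.multinomial(cfg.total_reads, (expected / total).ravel()).reshape(
        expected.shape
    )
    n_probes = len(cfg.probes)
    reads, index_reads, truth_rows = [], [], []
    serial = 0
    for s_idx, (plate_idx, well_idx) in enumerate(cfg.samples):
        well_bc = cfg.wells[well_idx]
        plate_bc = cfg.plates[plate_idx]
        index_seq = plate_bc + cfg.anatomy.pad_base * (
            cfg.anatomy.index_read_len - len(plate_bc)
        )
        for p_idx in range(n_probes):
            for _ in range(counts[p_idx, s_idx]):
                acc_idx = p_idx
                don_idx = p_idx
                if n_probes > 1 and rng.random() < cfg.off_target_rate:
                    don_idx = int(rng.integers(n_probes - 1))
                    if don_idx >= p_idx:
                        don_idx += 1
                read = assemble_read(
                    well_bc,
                    cfg.probes[acc_idx].acceptor_gene_seq,
                    cfg.probes[don_idx].donor_gene_seq,
                    cfg.anatomy,
                )
                rid = f"read{serial}"
                serial += 1
                reads.append((rid, _mutate(read, rng, cfg.error_rate)))
                index_reads.append((rid, _mutate(index_seq, rng, cfg.error_rate)))
                truth_rows.append(
                    (
                        rid,
                        plate_idx,
                        well_idx,
                        cfg.probes[acc_idx].set_id,
                        cfg.probes[don_idx].set_id,
                        acc_idx == don_idx,
                    )
                )
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "plate", "well", "acceptor", "donor", "on_target"],
    )
    return SimResult(reads, index_reads, truth)


# ---------------------------------------------------------------------------
# Analytic retention under the substitution error model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RetentionEstimate:
    """Expected pipeline survival under i.i.d. substitution errors.

    mapped_lo/hi bracket the expected mapped fraction: error patterns
    of weight above the enumeration cutoff are counted as all-fail
    (lo) or all-pass (hi).  on_target_lo/hi bracket the expected
    on-target fraction among mapped reads the same way.
    """

    p_plate: float
    p_parse: float
    p_well: float
    p_map_lo: float
    p_map_hi: float
    mapped_lo: float
    mapped_hi: float
    on_target_lo: float
    on_target_hi: float


def _binom_pmf(n: int, k: int, p: float) -> float:
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


def _enumerate_barcode_assignment(
    bc_set: BarcodeSet, used: list[int], length: int, p: float, max_errors: int = 2
) -> float:
    """P(observed prefix is assigned to *some* barcode) averaged over the
    barcodes in *used*, enumerating exact error patterns up to max_errors."""
    p_total = 0.0
    for idx in used:
        bc = bc_set[idx][:length]
        acc = _binom_pmf(length, 0, p)  # exact match always assigns
        for e in range(1, max_errors + 1):
            ok = 0
            tot = 0
            for pos in itertools.combinations(range(length), e):
                for subs in itertools.product(range(3), repeat=e):
                    chars = list(bc)
                    for q, s in zip(pos, subs):
                        chars[q] = _OTHER[chars[q]][s]
                    tot += 1
                    if assign_barcode("".join(chars), bc_set) != UNASSIGNED:
                        ok += 1
            acc += _binom_pmf(length, e, p) * ok / tot
        p_total += acc
    return p_total / len(used)


def expected_retention(
    cfg: SimConfig,
    mapper: ProbeMapper,
    max_bc_errors: int = 2,
    max_probe_errors: int = 3,
) -> RetentionEstimate:
    """Expected mapped and on-target fractions for an on-target read.

    Substitution errors act independently on the disjoint read segments,
    so survival factorizes: plate assignment (first plate_bc_len index
    bases), AD1 parse (exact or one mismatch), well assignment, probe
    mapping with the post-alignment filters.  Each factor is computed by
    exhaustive enumeration of error patterns up to the stated weight;
    heavier patterns are bracketed between all-fail and all-pass.
    Substitutions in probe-region enumeration rotate the base (A->C->G->
    T->A); the choice only matters through rare cross-probe matches.
    """
    p = cfg.error_rate
    anatomy = cfg.anatomy
    plates_used = sorted({pl for pl, _ in cfg.samples})
    wells_used = sorted({w for _, w in cfg.samples})

    L = anatomy.plate_bc_len
    p_plate = _enumerate_barcode_assignment(
        cfg.plates, plates_used, L, p, max_bc_errors
    )
    p_plate_resid = 1 - sum(_binom_pmf(L, e, p) for e in range(max_bc_errors + 1))

    n_ad1 = len(anatomy.ad1)
    p_parse = _binom_pmf(n_ad1, 0, p) + _binom_pmf(n_ad1, 1, p)

    Lw = anatomy.well_bc_len
    p_well = _enumerate_barcode_assignment(
        cfg.wells, wells_used, Lw, p, max_bc_errors
    )
    p_well_resid = 1 - sum(_binom_pmf(Lw, e, p) for e in range(max_bc_errors + 1))

    # probe-region mapping, weighted by each probe's expected read share
    weights = cfg.expected_matrix().sum(axis=1)
    weights = weights / weights.sum()
    n_reg = anatomy.probe_region_len
    p_map = 0.0
    p_on = 0.0
    for p_idx, probe in enumerate(cfg.probes):
        if weights[p_idx] == 0:
            continue
        region = probe.acceptor_gene_seq + probe.donor_gene_seq
        acc_map = 0.0
        acc_on = 0.0
        for e in range(0, max_probe_errors + 1):
            ok = on = tot = 0
            for pos in itertools.combinations(range(len(region)), e):
                chars = list(region)
                for q_ in pos:
                    chars[q_] = _BASES[(_BASES.index(chars[q_]) + 1) % 4]
                tot += 1
                hit = mapper.map("".join(chars))
                if hit is not None:
                    ok += 1
                    if hit.acceptor_idx == hit.donor_idx:
                        on += 1
            acc_map += _binom_pmf(n_reg, e, p) * ok / tot
            acc_on += _binom_pmf(n_reg, e, p) * on / tot
        p_map += weights[p_idx] * acc_map
        p_on += weights[p_idx] * acc_on
    p_map_resid = 1 - sum(_binom_pmf(n_reg, e, p) for e in range(max_probe_errors + 1))

    lo = p_plate * p_parse * p_well * p_map
    hi = (
        min(p_plate + p_plate_resid, 1.0)
        * p_parse
        * min(p_well + p_well_resid, 1.0)
        * min(p_map + p_map_resid, 1.0)
    )
    on_lo = p_on / min(p_map + p_map_resid, 1.0) if p_map > 0 else 0.0
    on_hi = min((p_on + p_map_resid) / p_map, 1.0) if p_map > 0 else 1.0
    return RetentionEstimate(
        p_plate=p_plate,
        p_parse=p_parse,
        p_well=p_well,
        p_map_lo=p_map,
        p_map_hi=min(p_map + p_map_resid, 1.0),
        mapped_lo=lo,
        mapped_hi=hi,
        on_target_lo=on_lo,
        on_target_hi=on_hi,
    )
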