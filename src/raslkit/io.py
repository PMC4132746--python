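"""Readers and writers for the pipeline's plain-text artifacts.

FASTA/FASTQ go through Biopython; tables are TSV via pandas with fixed
column order so that every writer's output is reloadable by the
corresponding reader byte-for-byte.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .anatomy import ReadAnatomy
from .barcodes import BarcodeSet
from .design import ProbeSet, Transcript
from .thermo import InvalidSequenceError

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "read_fastq_pair",
    "write_probe_table",
    "read_probe_table",
    "write_oligo_fasta",
    "write_barcode_table",
    "read_barcode_table",
    "write_matrix",
    "read_matrix",
    "read_metadata",
    "write_decoy_plan",
]

PROBE_COLUMNS = [
    "set_id",
    "transcript_id",
    "target_start",
    "target_end",
    "acceptor_gene_seq",
    "donor_gene_seq",
    "acceptor_full_oligo",
    "donor_full_oligo",
    "donor_5prime_phosphate",
    "tm",
    "gc",
    "penalty",
    "rank",
]


def read_fasta(path: str | Path) -> list[Transcript]:
    """Load transcripts; ids must be unique, sequences strictly ACGT."""
    out: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if any(b not in "ACGT" for b in seq):
            raise InvalidSequenceError(
                f"record {rec.id!r} contains non-ACGT characters"
            )
        out.append(Transcript(rec.id, seq))
    if not out:
        raise ValueError(f"empty FASTA file {path}")
    return out


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_fastq(path: str | Path, reads: list[tuple[str, str]]) -> None:
    """4-line records; constant quality (the pipeline is quality-blind)."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq_pair(
    reads_path: str | Path,
    index_path: str | Path,
    anatomy: ReadAnatomy | None = None,
    strict: bool = False,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], int]:
    """Load matched read/index FASTQ files.

    Returns (reads, index_reads, n_length_warnings).  Record counts must
    agree; in strict mode, reads deviating from the anatomy's read or
    index length are counted and warned about (but kept).
    """
    reads = [(r.id, str(r.seq)) for r in SeqIO.parse(str(reads_path), "fastq")]
    idx = [(r.id, str(r.seq)) for r in SeqIO.parse(str(index_path), "fastq")]
    if len(reads) != len(idx):
        raise ValueError(
            f"pairing error: {len(reads)} reads vs {len(idx)} index reads"
        )
    n_warn = 0
    if strict and anatomy is not None:
        for (_, seq), (_, iseq) in zip(reads, idx):
            if len(seq) != anatomy.read_len or len(iseq) != anatomy.index_read_len:
                n_warn += 1
        if n_warn:
            warnings.warn(f"{n_warn} read pair(s) deviate from the expected lengths")
    return reads, idx, n_warn


def write_probe_table(path: str | Path, probesets: list[ProbeSet]) -> None:
    """TSV probe table; the acceptor oligo's two 3'-terminal
    ribonucleotides are rendered lowercase."""
    rows = []
    for p in probesets:
        rows.append(
            {
                "set_id": p.set_id,
                "transcript_id": p.transcript_id,
                "target_start": p.target_start,
                "target_end": p.target_end,
                "acceptor_gene_seq": p.acceptor_gene_seq,
                "donor_gene_seq": p.donor_gene_seq,
                "acceptor_full_oligo": p.acceptor_oligo_annotated,
                "donor_full_oligo": p.donor_full_oligo,
                "donor_5prime_phosphate": p.donor_5prime_phosphate,
                "tm": f"{p.tm:.4f}",
                "gc": f"{p.gc:.4f}",
                "penalty": f"{p.penalty:.4f}",
                "rank": p.rank,
            }
        )
    pd.DataFrame(rows, columns=PROBE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_probe_table(path: str | Path) -> list[ProbeSet]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, r in df.iterrows():
        annotated = r["acceptor_full_oligo"]
        ribo = tuple(
            i - len(annotated) for i, b in enumerate(annotated) if b.islower()
        )
        out.append(
            ProbeSet(
                set_id=r["set_id"],
                transcript_id=r["transcript_id"],
                target_start=int(r["target_start"]),
                target_end=int(r["target_end"]),
                acceptor_gene_seq=r["acceptor_gene_seq"],
                donor_gene_seq=r["donor_gene_seq"],
                acceptor_full_oligo=annotated.upper(),
                donor_full_oligo=r["donor_full_oligo"],
                donor_5prime_phosphate=str(r["donor_5prime_phosphate"]) == "True",
                tm=float(r["tm"]),
                gc=float(r["gc"]),
                penalty=float(r["penalty"]),
                rank=int(r["rank"]),
                ribo_positions=ribo or (-2, -1),
            )
        )
    return out


def write_oligo_fasta(path: str | Path, probesets: list[ProbeSet]) -> None:
    recs = []
    for p in probesets:
        recs.append((f"{p.set_id}_acceptor", p.acceptor_oligo_annotated))
        recs.append((f"{p.set_id}_donor", p.donor_full_oligo))
    write_fasta(path, recs)


def write_barcode_table(path: str | Path, bc: BarcodeSet) -> None:
    df = pd.DataFrame(
        {
            "index": range(len(bc)),
            "sequence": bc.barcodes,
            "role": bc.role,
            "min_edit_distance": bc.min_edit_distance,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_barcode_table(path: str | Path) -> BarcodeSet:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    seqs = list(df["sequence"])
    return BarcodeSet(
        barcodes=seqs,
        length=len(seqs[0]),
        min_edit_distance=int(df["min_edit_distance"].iloc[0]),
        role=str(df["role"].iloc[0]),
    )


def write_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("plate", "well"):
        if col not in df.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    return df


def write_decoy_plan(path: str | Path, plan) -> None:
    rows = [
        {
            "set_id": e.set_id,
            "kind": e.kind,
            "mix_ratio": f"{e.mix_ratio:.4f}",
            "predicted_fold_reduction": f"{e.predicted_fold_reduction:.4f}",
        }
        for e in plan
    ]
    pd.DataFrame(
        rows, columns=["set_id", "kind", "mix_ratio", "predicted_fold_reduction"]
    ).to_csv(path, sep="\t", index=False)
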