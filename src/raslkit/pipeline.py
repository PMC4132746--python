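"""End-to-end orchestration: design -> barcodes -> simulate -> demux ->
quantify, with per-stage read-conservation logging.

Given only a seed the pipeline synthesizes a transcriptome, designs
probes against it, generates barcode sets, simulates a pooled run with
ground truth, deconvolutes it back into count matrices, and clusters
the standardized on-target matrix.  Every stage writes its artifact to
the output directory; reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .barcodes import generate_barcodes
from .config import PipelineConfig
from .demux import run_demux
from .design import Transcript, design_probes
from .quantify import standardize_and_cluster
from .simulate import SimConfig, simulate_run

__all__ = ["PipelineStageError", "random_transcriptome", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """Failure wrapped with the name of the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def random_transcriptome(
    n: int, length: int, seed: int = 0, gc: float = 0.5
) -> list[Transcript]:
    """Uniform-composition synthetic transcripts (sense strand, poly(A)
    excluded) for fixtures and pilots."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return [
        Transcript(
            f"synth{i}", "".join(rng.choice(list("ACGT"), size=length, p=p))
        )
        for i in range(n)
    ]


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as e:  # noqa: BLE001 - rewrapped with stage context
            raise PipelineStageError(name, e) from e

    return wrap


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages; returns a summary dict (also written as JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed}

    # --- transcripts ------------------------------------------------------
    if cfg.transcripts_fasta:
        transcripts = _stage("transcripts")(io.read_fasta, cfg.transcripts_fasta)
    else:
        transcripts = random_transcriptome(
            cfg.sim.n_transcripts, cfg.sim.transcript_length, cfg.seed
        )
    io.write_fasta(out / "transcripts.fasta", [(t.id, t.sequence) for t in transcripts])

    # --- probe design -----------------------------------------------------
    def _design():
        ps, stats = design_probes(
            transcripts, None, cfg.design, cfg.thermo, cfg.anatomy
        )
        if not ps:
            raise ValueError("no probe sets survived design")
        return ps, stats

    probesets, design_stats = _stage("design")(_design)
    io.write_probe_table(out / "probes.tsv", probesets)
    io.write_oligo_fasta(out / "oligos.fasta", probesets)
    summary["design"] = design_stats

    # --- barcodes ---------------------------------------------------------
    bc = cfg.barcodes
    wells = _stage("barcodes")(
        generate_barcodes, bc.n_wells, bc.well_length, bc.min_edit, cfg.seed, "well"
    )
    plates = _stage("barcodes")(
        generate_barcodes,
        bc.n_plates,
        bc.plate_length,
        bc.min_edit,
        cfg.seed + 1,
        "plate",
    )
    io.write_barcode_table(out / "wells.tsv", wells)
    io.write_barcode_table(out / "plates.tsv", plates)

    # --- simulate ---------------------------------------------------------
    rng = np.random.default_rng(cfg.seed + 2)
    samples = [(p, w) for p in range(bc.n_plates) for w in range(bc.n_wells)]
    abundance = np.tile(
        np.exp(rng.normal(0, cfg.sim.abundance_log_sd, size=len(probesets)))[:, None],
        (1, len(samples)),
    )
    sim_cfg = SimConfig(
        probes=probesets,
        wells=wells,
        plates=plates,
        samples=samples,
        abundance=abundance,
        total_reads=cfg.sim.total_reads,
        off_target_rate=cfg.sim.off_target_rate,
        error_rate=cfg.sim.error_rate,
        anatomy=cfg.anatomy,
    )
    sim = _stage("simulate")(simulate_run, sim_cfg, cfg.seed + 3)
    io.write_fastq(out / "reads.fastq", sim.reads)
    io.write_fastq(out / "index.fastq", sim.index_reads)
    sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    # --- demultiplex + map ------------------------------------------------
    metadata = pd.DataFrame(
        [
            {"plate": p, "well": w, "condition": f"cond{(p * bc.n_wells + w) % 2}"}
            for p, w in samples
        ]
    )
    metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    res = _stage("demux")(
        run_demux,
        sim.reads,
        sim.index_reads,
        probesets,
        wells,
        plates,
        metadata,
        cfg.anatomy,
        cfg.mapper,
    )
    io.write_matrix(out / "counts_on_target.tsv", res.on_target)
    io.write_matrix(out / "counts_off_target.tsv", res.off_target)
    if res.sample_meta is not None:
        joined = res.sample_meta.join(res.on_target.T)
        joined.to_csv(out / "counts_with_metadata.tsv", sep="\t")
    summary["demux"] = {
        "total": res.stats.total,
        "plate_unassigned": res.stats.plate_unassigned,
        "unparsed": res.stats.unparsed,
        "well_len_filtered": res.stats.well_len_filtered,
        "well_unassigned": res.stats.well_unassigned,
        "no_hit": res.stats.no_hit,
        "mapped_on": res.stats.mapped_on,
        "mapped_off": res.stats.mapped_off,
        "unique_sequences": res.stats.unique_sequences,
        "compression": res.stats.compression,
    }

    # --- quantify ---------------------------------------------------------
    def _cluster():
        if res.on_target.shape[0] >= 2 and res.on_target.shape[1] >= 2:
            cl = standardize_and_cluster(res.on_target.astype(float))
            io.write_matrix(out / "clustered_matrix.tsv", cl.matrix)
            (out / "row_dendrogram.nwk").write_text(cl.row_newick + "\n")
            (out / "col_dendrogram.nwk").write_text(cl.col_newick + "\n")
            return {"row_order": cl.row_order[:5], "col_order": cl.col_order[:5]}
        return None

    summary["cluster"] = _stage("quantify")(_cluster)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
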