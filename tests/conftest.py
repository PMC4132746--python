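"""Shared fixtures: a small designed panel plus barcode sets, reused
across the simulation and demultiplexing tests to keep runtime down."""

from __future__ import annotations

import numpy as np
import pytest

from raslkit.barcodes import generate_barcodes
from raslkit.design import design_probes
from raslkit.pipeline import random_transcriptome
from raslkit.simulate import SimConfig, uniform_abundance


@pytest.fixture(scope="session")
def transcriptome6():
    return random_transcriptome(6, 800, seed=7)


@pytest.fixture(scope="session")
def panel6(transcriptome6):
    """One probe set per transcript (rank-1 only): a 6-plex panel."""
    probesets, _ = design_probes(transcriptome6)
    panel = [p for p in probesets if p.rank == 1]
    assert len(panel) == 6
    return panel


@pytest.fixture(scope="session")
def wells8():
    return generate_barcodes(8, 8, min_edit=2, seed=3, role="well")


@pytest.fixture(scope="session")
def plates2():
    return generate_barcodes(2, 7, min_edit=2, seed=4, role="plate")


@pytest.fixture(scope="session")
def samples16():
    return [(p, w) for p in range(2) for w in range(8)]


@pytest.fixture()
def sim_cfg_factory(panel6, wells8, plates2, samples16):
    def make(**overrides) -> SimConfig:
        kwargs = dict(
            probes=panel6,
            wells=wells8,
            plates=plates2,
            samples=samples16,
            abundance=uniform_abundance(len(panel6), len(samples16)),
            total_reads=20000,
        )
        kwargs.update(overrides)
        return SimConfig(**kwargs)

    return make


@pytest.fixture(scope="session")
def transcriptome50():
    """The 1.5-kb, 50-transcript synthetic design exercise."""
    return random_transcriptome(50, 1500, seed=1)


@pytest.fixture(scope="session")
def designed50(transcriptome50):
    return design_probes(transcriptome50)
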