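"""Pipeline configuration: one YAML file with per-stage sections.

Every constant of the assay's operating point (design thresholds,
read anatomy, mapper scoring/filters, decoy model) is a dataclass
default here and can be overridden per run; nothing is hard-coded at
the call sites.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .align import MapperConfig
from .anatomy import ReadAnatomy
from .design import DesignConfig
from .quantify import DecoyModelConfig
from .thermo import ThermoParams

__all__ = ["BarcodeConfig", "SimSection", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class BarcodeConfig:
    n_wells: int = 8
    n_plates: int = 2
    well_length: int = 8
    plate_length: int = 7
    min_edit: int = 2


@dataclass(frozen=True)
class SimSection:
    """Synthetic-run section; also controls the synthetic transcriptome
    used when no FASTA is supplied."""

    n_transcripts: int = 6
    transcript_length: int = 800
    total_reads: int = 20000
    off_target_rate: float = 0.02
    error_rate: float = 0.005
    abundance_log_sd: float = 1.0  # log-normal spread of probe abundances


@dataclass(frozen=True)
class PipelineConfig:
    design: DesignConfig = field(default_factory=DesignConfig)
    thermo: ThermoParams = field(default_factory=ThermoParams)
    mapper: MapperConfig = field(default_factory=MapperConfig)
    anatomy: ReadAnatomy = field(default_factory=ReadAnatomy)
    barcodes: BarcodeConfig = field(default_factory=BarcodeConfig)
    sim: SimSection = field(default_factory=SimSection)
    decoy: DecoyModelConfig = field(default_factory=DecoyModelConfig)
    seed: int = 0
    transcripts_fasta: str | None = None


_SECTIONS = {
    "design": DesignConfig,
    "thermo": ThermoParams,
    "mapper": MapperConfig,
    "anatomy": ReadAnatomy,
    "barcodes": BarcodeConfig,
    "sim": SimSection,
    "decoy": DecoyModelConfig,
}


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file of per-stage sections;
    unknown keys raise, omitted keys take the documented defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.pop(name, {})
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section) - valid
        if unknown:
            raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
        kwargs[name] = cls(**section)
    for key in ("seed", "transcripts_fasta"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise ValueError(f"unknown top-level config keys: {sorted(raw)}")
    return PipelineConfig(**kwargs)
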