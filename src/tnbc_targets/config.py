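"""Pipeline configuration: thresholds, genomic distances and the RNG seed.

The defaults encode the analysis gates used throughout the pipeline: a
two-fold expression change (|log2 FC| >= 1) at FDR <= 0.05 defines a
differentially expressed gene; candidate targets must be near-novel in the
literature (fewer than two publications), have a solved and druggable
structure, and score at or above the 75th ligand-based druggability
percentile; CpG shores extend 2 kb from islands and shelves 2-4 kb; genome
tracks are averaged in 5-Mbp bins.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised for unknown keys or invariant violations in a config file."""


@dataclass
class PipelineConfig:
    """Analysis thresholds and distances shared by every pipeline stage.

    Attributes
    ----------
    fc_up_threshold : float
        log2 fold-change at or above which a gene can be called "up"
        (default +1, i.e. FC >= 2).
    fc_down_threshold : float
        log2 fold-change at or below which a gene can be called "down"
        (default -1, i.e. FC <= -2).
    fdr_threshold : float
        Benjamini-Hochberg FDR cutoff, inclusive (default 0.05).
    novelty_max_pubs : int
        Exclusive upper bound on publication count at the novelty gate
        (default 2: genes with >= 2 publications are considered known).
    ligand_percentile_min : float
        Inclusive lower bound on the ligand-based druggability percentile
        (default 75).
    posterior_cutoff : float
        Mixture posterior above which a sample is called marker-positive;
        an exact tie is called negative (default 0.5).
    shore_bp : int
        Maximum distance (bp) from a CpG island still counted as "shore".
    shelf_bp : int
        Maximum distance (bp) still counted as "shelf"; beyond is open sea.
    bin_bp : int
        Width of genome bins for averaged fold-change tracks (default 5 Mbp).
    rng_seed : int
        Seed for every stochastic step of a pipeline run.
    """

    fc_up_threshold: float = 1.0
    fc_down_threshold: float = -1.0
    fdr_threshold: float = 0.05
    novelty_max_pubs: int = 2
    ligand_percentile_min: float = 75.0
    posterior_cutoff: float = 0.5
    shore_bp: int = 2000
    shelf_bp: int = 4000
    bin_bp: int = 5_000_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.fc_down_threshold < 0 < self.fc_up_threshold):
            raise ConfigError(
                "fold-change thresholds must satisfy "
                f"fc_down_threshold < 0 < fc_up_threshold, got "
                f"({self.fc_down_threshold}, {self.fc_up_threshold})"
            )
        if not (0 < self.fdr_threshold < 1):
            raise ConfigError(f"fdr_threshold must be in (0, 1), got {self.fdr_threshold}")
        if not (0 <= self.posterior_cutoff <= 1):
            raise ConfigError(f"posterior_cutoff must be in [0, 1], got {self.posterior_cutoff}")
        for name in ("shore_bp", "shelf_bp", "bin_bp"):
            value = getattr(self, name)
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if not self.shore_bp < self.shelf_bp:
            raise ConfigError(
                f"shore_bp ({self.shore_bp}) must be smaller than shelf_bp ({self.shelf_bp})"
            )
        if self.novelty_max_pubs < 1:
            raise ConfigError(f"novelty_max_pubs must be >= 1, got {self.novelty_max_pubs}")
        if not (0 <= self.ligand_percentile_min <= 100):
            raise ConfigError(
                f"ligand_percentile_min must be in [0, 100], got {self.ligand_percentile_min}"
            )
        for name in ("fc_up_threshold", "fc_down_threshold", "fdr_threshold"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file.

    Missing keys take their documented defaults; keys outside the schema are
    a hard error so that typos never silently fall back to defaults.
    """
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    return PipelineConfig(**raw)
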