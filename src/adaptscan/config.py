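"""Pipeline configuration: one schema, defaults sourced from the module constants."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from . import bsa, cnv, popgen, variants

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class BsaBlock:
    window_bp: int = bsa.DEFAULT_WINDOW_BP
    step_bp: int = bsa.DEFAULT_STEP_BP
    high: float = bsa.DEFAULT_HIGH
    low: float = bsa.DEFAULT_LOW
    min_depth: int = bsa.DEFAULT_MIN_DEPTH


@dataclass
class CnvBlock:
    window: int = cnv.DEFAULT_CN_WINDOW
    step: int = cnv.DEFAULT_CN_STEP
    flank: int = cnv.DEFAULT_CN_FLANK


@dataclass
class FilterBlock:
    gq_min: int = 25
    dp_min: int = 3
    require_parents_called: bool = True
    max_missing_fraction: float = 0.0
    maf_min: float = 0.05


@dataclass
class PopgenBlock:
    grid_bp: int = popgen.DEFAULT_GRID_BP
    subsample_fraction: float = popgen.DEFAULT_SUBSAMPLE_FRACTION
    outcrossing_rate: float = popgen.DEFAULT_OUTCROSSING_RATE


@dataclass
class SimulateBlock:
    n_individuals: int = 454
    pool_size: int = 9
    pool_depth: float = 36.0
    markers_per_chrom: int = 2_000
    n_chromosomes: int = 5
    chrom_length: int = 10_000_000


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulateBlock = field(default_factory=SimulateBlock)
    filter: FilterBlock = field(default_factory=FilterBlock)
    bsa: BsaBlock = field(default_factory=BsaBlock)
    cnv: CnvBlock = field(default_factory=CnvBlock)
    popgen: PopgenBlock = field(default_factory=PopgenBlock)

    def to_dict(self) -> dict:
        return asdict(self)

    def filter_config(self) -> variants.FilterConfig:
        return variants.FilterConfig(
            gq_min=self.filter.gq_min,
            dp_min=self.filter.dp_min,
            require_parents_called=self.filter.require_parents_called,
            max_missing_fraction=self.filter.max_missing_fraction,
            maf_min=self.filter.maf_min,
        )


def _update_block(block, values: dict, path: str) -> None:
    allowed = {f.name for f in fields(block)}
    for key, val in values.items():
        if key not in allowed:
            raise ValueError(f"unknown configuration key {path}.{key}")
        setattr(block, key, val)


def load_config(path: str | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a config from an optional YAML file plus flag overrides.

    Unknown keys are rejected before any computation; flag overrides win
    over file values.
    """
    cfg = PipelineConfig()
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        for section, values in overrides.items():
            raw.setdefault(section, {}).update(values) if isinstance(values, dict) else raw.update(
                {section: values}
            )
    blocks = {f.name: f for f in fields(PipelineConfig) if f.name != "seed"}
    for key, val in raw.items():
        if key == "seed":
            cfg.seed = int(val)
        elif key in blocks:
            if not isinstance(val, dict):
                raise ValueError(f"configuration section {key!r} must be a mapping")
            _update_block(getattr(cfg, key), val, key)
        else:
            raise ValueError(f"unknown configuration section {key!r}")
    return cfg
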