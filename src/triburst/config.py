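"""Unified pipeline configuration with validated YAML loading.

One config file holds a block per stage; unknown keys are rejected so a
typo never silently falls back to a default.  The defaults are the
parameter values used throughout the analysis: ISI_N with N = 20, merging
fraction 0.2, minimum 3 participating channels, individual channel
contribution 0.15, detection threshold 4.5× the noise SD with a
200–3000 Hz elliptic band-pass, 5000 surrogate simulations with shifts in
[−20, 20] s, 5-minute analysis bins, and α = 0.05 Bonferroni-corrected
for the family of eight hypotheses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bursts import NBDetectionParams
from .connectivity import CorseParams
from .layout import PlatformLayout
from .spikes import SpikeDetectionParams
from .surrogate import SurrogateParams
from .synthetic import SimulationParams

__all__ = ["QCParams", "StatsParams", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class QCParams:
    """Noise-rejection screening of whole recordings."""

    bin_width: float = 1.0          # s
    rate_limit: float = 40.0        # Hz per electrode
    min_channels_fraction: float = 0.75


@dataclass(frozen=True)
class StatsParams:
    alpha: float = 0.05
    family_size: int = 8
    bin_width: float = 300.0        # s, the 5 min analysis bin


@dataclass(frozen=True)
class PipelineConfig:
    layout: PlatformLayout = field(default_factory=PlatformLayout)
    qc: QCParams = field(default_factory=QCParams)
    spike_detection: SpikeDetectionParams = field(default_factory=SpikeDetectionParams)
    network_bursts: NBDetectionParams = field(default_factory=NBDetectionParams)
    surrogate: SurrogateParams = field(default_factory=SurrogateParams)
    connectivity: CorseParams = field(default_factory=CorseParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    stats: StatsParams = field(default_factory=StatsParams)


_BLOCKS = {
    "layout": PlatformLayout,
    "qc": QCParams,
    "spike_detection": SpikeDetectionParams,
    "network_bursts": NBDetectionParams,
    "surrogate": SurrogateParams,
    "connectivity": CorseParams,
    "simulation": SimulationParams,
    "stats": StatsParams,
}


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {cls.__name__} block: {sorted(unknown)}")
    kwargs = dict(data)
    if cls is PlatformLayout and "compartments" in kwargs:
        kwargs["compartments"] = tuple(str(c) for c in kwargs["compartments"])
    if cls is SurrogateParams and "delta_range" in kwargs:
        kwargs["delta_range"] = tuple(float(v) for v in kwargs["delta_range"])
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a config from YAML (all blocks optional), then apply overrides.

    ``overrides`` is a nested dict with the same block structure; unknown
    blocks or keys raise immediately.
    """
    data: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as f:
            data = yaml.safe_load(f) or {}
    for block, values in (overrides or {}).items():
        data.setdefault(block, {}).update(values)
    unknown = set(data) - set(_BLOCKS)
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    kwargs = {name: _build(cls, data.get(name, {})) for name, cls in _BLOCKS.items()}
    return PipelineConfig(**kwargs)
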