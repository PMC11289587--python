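"""Data model for the three-compartment MEA platform.

The platform consists of three microfluidically separated neuronal
compartments (labelled ``A``, ``B``, ``C``) connected by microtunnel
bundles, each compartment carrying 24 extracellular electrodes sampled at
25 kHz.  Electrodes are addressed by a label such as ``"A07"`` — the
compartment letter followed by a zero-padded index in ``0..23``.

Two containers move through the pipeline:

``RawRecording``
    Per-electrode voltage traces in microvolts, all of equal length.
``SpikeListSet``
    Per-electrode sorted spike timestamps in seconds — the central
    currency of every downstream stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElectrodeId",
    "PlatformLayout",
    "RawRecording",
    "SpikeListSet",
    "DEFAULT_COMPARTMENTS",
]

DEFAULT_COMPARTMENTS = ("A", "B", "C")

_LABEL_RE = re.compile(r"^([A-Za-z])(\d{2})$")


@dataclass(frozen=True, order=True)
class ElectrodeId:
    """One electrode, addressed by compartment letter and index 0-23."""

    compartment: str
    index: int

    def __post_init__(self) -> None:
        if len(self.compartment) != 1 or not self.compartment.isalpha():
            raise ValueError(f"compartment must be a single letter, got {self.compartment!r}")
        if not 0 <= self.index <= 23:
            raise ValueError(f"electrode index must be in 0..23, got {self.index}")

    @property
    def label(self) -> str:
        return f"{self.compartment}{self.index:02d}"

    @classmethod
    def from_label(cls, label: str) -> "ElectrodeId":
        m = _LABEL_RE.match(label)
        if m is None:
            raise ValueError(f"malformed electrode label {label!r} (expected e.g. 'A07')")
        return cls(m.group(1).upper(), int(m.group(2)))


@dataclass(frozen=True)
class PlatformLayout:
    """Geometry and acquisition parameters of one recording platform."""

    compartments: tuple[str, ...] = DEFAULT_COMPARTMENTS
    electrodes_per_compartment: int = 24
    sampling_rate: float = 25_000.0
    plate_id: str = ""

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.electrodes_per_compartment < 1:
            raise ValueError("electrodes_per_compartment must be >= 1")
        if len(set(self.compartments)) != len(self.compartments):
            raise ValueError("duplicate compartment labels")

    @property
    def n_electrodes(self) -> int:
        return len(self.compartments) * self.electrodes_per_compartment

    def electrodes(self, compartment: str | None = None) -> list[ElectrodeId]:
        """All electrodes, or those of one compartment, in label order."""
        comps = self.compartments if compartment is None else (compartment,)
        for c in comps:
            if c not in self.compartments:
                raise KeyError(f"unknown compartment {c!r}")
        return [
            ElectrodeId(c, i)
            for c in comps
            for i in range(self.electrodes_per_compartment)
        ]

    def labels(self, compartment: str | None = None) -> list[str]:
        return [e.label for e in self.electrodes(compartment)]


@dataclass
class RawRecording:
    """Raw multichannel voltage traces (µV) at the layout's sampling rate."""

    layout: PlatformLayout
    traces: dict[str, np.ndarray]  # electrode label -> samples (µV)

    def __post_init__(self) -> None:
        expected = set(self.layout.labels())
        got = set(self.traces)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ValueError(
                f"trace channels do not match layout (missing={missing}, extra={extra})"
            )
        lengths = {len(v) for v in self.traces.values()}
        if len(lengths) != 1:
            raise ValueError(f"traces have unequal lengths: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.traces.values())))

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.layout.sampling_rate


@dataclass
class SpikeListSet:
    """Per-electrode sorted spike timestamps (seconds from recording start)."""

    layout: PlatformLayout
    spikes: dict[str, np.ndarray] = field(default_factory=dict)
    duration: float = 0.0

    def __post_init__(self) -> None:
        known = set(self.layout.labels())
        full: dict[str, np.ndarray] = {}
        for label in self.layout.labels():
            ts = np.asarray(self.spikes.get(label, ()), dtype=float)
            if ts.size and np.any(np.diff(ts) <= 0):
                raise ValueError(f"timestamps for {label} not strictly increasing")
            if ts.size and (ts[0] < 0 or ts[-1] > self.duration + 1e-9):
                raise ValueError(
                    f"timestamps for {label} outside [0, duration={self.duration}]"
                )
            full[label] = ts
        unknown = set(self.spikes) - known
        if unknown:
            raise ValueError(f"unknown electrode labels: {sorted(unknown)}")
        self.spikes = full

    @property
    def n_spikes(self) -> int:
        return int(sum(ts.size for ts in self.spikes.values()))

    def counts(self) -> dict[str, int]:
        return {label: int(ts.size) for label, ts in self.spikes.items()}

    def compartment_labels(self, compartment: str) -> list[str]:
        return self.layout.labels(compartment)
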