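"""Readers and writers for raw recordings and spike lists, plus recording QC.

The HDF5 schema is this package's own: a root group ``recording`` with one
float64 dataset per electrode under ``recording/traces/<label>`` (µV), and
root attributes ``sampling_rate_hz``, ``units`` and ``plate_id``.  A
``channel_map`` argument lets the reader ingest other dialects by renaming
datasets to layout labels.

Spike lists are UTF-8 CSV with the header ``electrode,timestamp_s``.
"""

from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path

import h5py
import numpy as np
import yaml

from .layout import PlatformLayout, RawRecording, SpikeListSet

__all__ = [
    "read_raw_hdf5",
    "write_raw_hdf5",
    "read_spike_csv",
    "write_spike_csv",
    "flag_noisy_recording",
    "load_layout_yaml",
]

log = logging.getLogger(__name__)

_CSV_HEADER = ("electrode", "timestamp_s")


def write_raw_hdf5(recording: RawRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("recording")
        grp.attrs["sampling_rate_hz"] = recording.layout.sampling_rate
        grp.attrs["units"] = "uV"
        grp.attrs["plate_id"] = recording.layout.plate_id
        traces = grp.create_group("traces")
        for label in recording.layout.labels():
            traces.create_dataset(label, data=np.asarray(recording.traces[label], dtype=np.float64))


def read_raw_hdf5(
    path: str | Path,
    layout: PlatformLayout,
    channel_map: dict[str, str] | None = None,
) -> RawRecording:
    """Read a raw multichannel recording.

    Parameters
    ----------
    path
        HDF5 file written by :func:`write_raw_hdf5` or a compatible dialect.
    layout
        Expected platform layout; the file must provide every electrode.
    channel_map
        Optional mapping ``layout label -> dataset name`` for files whose
        channel names differ from the layout's labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with h5py.File(path, "r") as f:
            if "recording" not in f or "traces" not in f["recording"]:
                raise OSError(f"{path}: missing 'recording/traces' group")
            grp = f["recording"]
            traces_grp = grp["traces"]
            fs = float(grp.attrs.get("sampling_rate_hz", layout.sampling_rate))
            if abs(fs - layout.sampling_rate) > 1e-6:
                raise ValueError(
                    f"{path}: file sampling rate {fs} Hz != layout {layout.sampling_rate} Hz"
                )
            traces: dict[str, np.ndarray] = {}
            for label in layout.labels():
                key = channel_map.get(label, label) if channel_map else label
                if key not in traces_grp:
                    raise KeyError(f"{path}: channel for electrode {label!r} absent")
                traces[label] = np.asarray(traces_grp[key][...], dtype=np.float64)
    except OSError as e:
        raise OSError(f"cannot read HDF5 container {path}: {e}") from e
    lengths = {len(v) for v in traces.values()}
    if len(lengths) != 1:
        short = min(traces, key=lambda k: len(traces[k]))
        raise ValueError(f"{path}: electrode {short!r} trace shorter than the rest")
    return RawRecording(layout=layout, traces=traces)


def write_spike_csv(spikes: SpikeListSet, path: str | Path) -> None:
    """Write one row per spike: electrode label, timestamp at µs precision."""
    with open(path, "w", newline="", encoding="utf-8") as f:
        w = csv.writer(f)
        w.writerow(_CSV_HEADER)
        for label in spikes.layout.labels():
            for t in spikes.spikes[label]:
                w.writerow([label, f"{t:.6f}"])


def read_spike_csv(
    path: str | Path,
    layout: PlatformLayout,
    duration: float | None = None,
) -> SpikeListSet:
    """Read a spike-list CSV into a :class:`SpikeListSet`.

    Unknown electrode labels are rejected; duplicate timestamps on one
    electrode are deduplicated with a warning.  ``duration`` defaults to the
    last spike time when not given.
    """
    path = Path(path)
    known = set(layout.labels())
    per_electrode: dict[str, list[float]] = {label: [] for label in known}
    with open(path, newline="", encoding="utf-8") as f:
        reader = csv.reader(f)
        for lineno, row in enumerate(reader, start=1):
            if not row or (lineno == 1 and tuple(h.strip() for h in row) == _CSV_HEADER):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'electrode,timestamp_s', got {row!r}")
            label = row[0].strip()
            if label not in known:
                raise ValueError(f"{path}:{lineno}: unknown electrode label {label!r}")
            try:
                t = float(row[1])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: unparseable timestamp {row[1]!r}") from e
            per_electrode[label].append(t)
    arrays: dict[str, np.ndarray] = {}
    max_t = 0.0
    for label, ts in per_electrode.items():
        arr = np.sort(np.asarray(ts, dtype=float))
        uniq = np.unique(arr)
        if uniq.size != arr.size:
            warnings.warn(
                f"{path}: {arr.size - uniq.size} duplicate timestamps on {label} removed",
                stacklevel=2,
            )
        arrays[label] = uniq
        if uniq.size:
            max_t = max(max_t, float(uniq[-1]))
    dur = float(duration) if duration is not None else max_t
    return SpikeListSet(layout=layout, spikes=arrays, duration=dur)


def flag_noisy_recording(
    spikes: SpikeListSet,
    bin_width: float = 1.0,
    rate_limit: float = 40.0,
    min_channels_fraction: float = 0.75,
) -> list[tuple[float, float]]:
    """Flag intervals of simultaneous excessive spiking across the array.

    A time bin is flagged when the bin-normalized firing rate exceeds
    ``rate_limit`` (Hz) on more than ``min_channels_fraction`` of the
    electrodes at once — the signature of non-biological noise spreading
    over most of the array.  Contiguous flagged bins are merged.  An empty
    list means the recording looks clean.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = max(1, int(np.ceil(spikes.duration / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    n_elec = spikes.layout.n_electrodes
    above = np.zeros(n_bins, dtype=int)
    for ts in spikes.spikes.values():
        counts, _ = np.histogram(ts, bins=edges)
        above += (counts / bin_width) > rate_limit
    flagged = above > min_channels_fraction * n_elec
    intervals: list[tuple[float, float]] = []
    for i in np.flatnonzero(flagged):
        start, end = float(edges[i]), float(edges[i + 1])
        if intervals and intervals[-1][1] == start:
            intervals[-1] = (intervals[-1][0], end)
        else:
            intervals.append((start, end))
    if intervals:
        log.warning("recording flagged noisy in %d interval(s)", len(intervals))
    return intervals


def load_layout_yaml(path: str | Path) -> PlatformLayout:
    """Load a platform layout from a YAML config file."""
    with open(path, encoding="utf-8") as f:
        data = yaml.safe_load(f) or {}
    allowed = {"compartments", "electrodes_per_compartment", "sampling_rate", "plate_id"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown layout keys: {sorted(unknown)}")
    if "compartments" in data:
        data["compartments"] = tuple(str(c) for c in data["compartments"])
    return PlatformLayout(**data)
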