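"""Network-burst detection per compartment via the ISI_N threshold method.

All spikes of a compartment are pooled into a single sorted train and the
span of every N consecutive spikes (ISI_N, default N = 20) is histogrammed
on a log scale.  A bursting network yields a bimodal histogram — short
in-burst spans vs long between-burst spans — and the detection threshold
is placed at the minimum between the two dominant modes.  Initial bursts
(maximal runs of sub-threshold spans) are then refined:

* adjacent bursts are merged when the gap between them is shorter than a
  fraction (default 0.2) of the longer burst's duration;
* optionally, very short bursts are removed (off by default);
* a burst is kept only if at least ``min_channels`` (default 3/24)
  electrodes contribute *sufficiently*: an electrode dominates when its
  in-burst spike count reaches ``min_contribution_fraction`` (default
  0.15) of the mean per-participating-channel count.

If the histogram is unimodal the compartment is reported burst-free with a
diagnostic rather than with an invented fixed threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .layout import SpikeListSet

__all__ = [
    "NBDetectionParams",
    "NetworkBurst",
    "pool_compartment_spikes",
    "isi_n_values",
    "isi_n_threshold",
    "detect_nb_initial",
    "merge_adjacent",
    "remove_short",
    "apply_channel_criteria",
    "detect_network_bursts",
    "InsufficientSpikesError",
]

log = logging.getLogger(__name__)


class InsufficientSpikesError(ValueError):
    """Raised when a pooled train has fewer than N spikes."""


@dataclass(frozen=True)
class NBDetectionParams:
    N: int = 20
    merging_fraction: float = 0.2
    min_duration: float | None = None  # seconds; None disables short-burst removal
    min_channels: int = 3
    min_contribution_fraction: float = 0.15
    histogram_bins_per_decade: int = 40
    smoothing_sd_bins: float = 2.0
    peak_prominence_fraction: float = 0.01
    mean_over_all_channels: bool = False  # divide mean contribution by 24 instead of participants

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.merging_fraction < 0:
            raise ValueError("merging_fraction must be >= 0")
        if not 0 <= self.min_contribution_fraction <= 1:
            raise ValueError("min_contribution_fraction must be in [0, 1]")
        if self.min_channels < 1:
            raise ValueError("min_channels must be >= 1")


@dataclass
class NetworkBurst:
    """One detected synchronous interval within a compartment."""

    compartment: str
    start: float
    end: float
    spike_count: int = 0
    per_channel_counts: dict[str, int] = field(default_factory=dict)
    participating_channels: frozenset[str] = frozenset()
    dominating_channels: frozenset[str] = frozenset()

    @property
    def duration(self) -> float:
        return self.end - self.start

    def to_dict(self) -> dict:
        return {
            "compartment": self.compartment,
            "start": self.start,
            "end": self.end,
            "spike_count": self.spike_count,
            "per_channel_counts": dict(self.per_channel_counts),
            "participating_channels": sorted(self.participating_channels),
            "dominating_channels": sorted(self.dominating_channels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkBurst":
        return cls(
            compartment=d["compartment"],
            start=float(d["start"]),
            end=float(d["end"]),
            spike_count=int(d.get("spike_count", 0)),
            per_channel_counts={k: int(v) for k, v in d.get("per_channel_counts", {}).items()},
            participating_channels=frozenset(d.get("participating_channels", ())),
            dominating_channels=frozenset(d.get("dominating_channels", ())),
        )


def pool_compartment_spikes(spikes: SpikeListSet, compartment: str) -> np.ndarray:
    """Multiset union of one compartment's electrode trains, sorted."""
    labels = spikes.compartment_labels(compartment)
    trains = [spikes.spikes[label] for label in labels]
    if not trains:
        return np.empty(0, dtype=float)
    return np.sort(np.concatenate(trains))


def isi_n_values(train: np.ndarray, N: int) -> np.ndarray:
    """Span of each window of N consecutive spikes: t[i+N-1] - t[i]."""
    t = np.asarray(train, dtype=float)
    if t.size < N:
        return np.empty(0, dtype=float)
    return t[N - 1 :] - t[: t.size - N + 1]


def isi_n_threshold(values: np.ndarray, params: NBDetectionParams) -> float | None:
    """Valley of the bimodal log-histogram of ISI_N spans, in seconds.

    Returns ``None`` when the smoothed histogram has fewer than two peaks
    (unimodal firing — no burst/non-burst separation exists).
    """
    values = np.asarray(values, dtype=float)
    values = values[values > 0]
    if values.size == 0:
        raise InsufficientSpikesError("no ISI_N values available")
    logv = np.log10(values)
    lo, hi = logv.min(), logv.max()
    if hi - lo < 1e-12:
        return None
    n_bins = max(4, int(np.ceil((hi - lo) * params.histogram_bins_per_decade)))
    hist, edges = np.histogram(logv, bins=n_bins)
    smoothed = gaussian_filter1d(hist.astype(float), params.smoothing_sd_bins)
    prominence = params.peak_prominence_fraction * smoothed.max()
    peaks, props = signal.find_peaks(smoothed, prominence=prominence)
    if peaks.size < 2:
        log.info("ISI_N histogram unimodal (%d peak(s)); no threshold", peaks.size)
        return None
    top2 = peaks[np.argsort(smoothed[peaks])[-2:]]
    left, right = int(top2.min()), int(top2.max())
    valley = left + 1 + int(np.argmin(smoothed[left + 1 : right]))
    centers = (edges[:-1] + edges[1:]) / 2
    return float(10 ** centers[valley])


def detect_nb_initial(train: np.ndarray, N: int, threshold: float) -> list[tuple[float, float]]:
    """Initial bursts: maximal runs of windows with ISI_N span <= threshold.

    A burst starts at the first spike of its first qualifying window and
    ends at the last spike of its last qualifying window.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = np.asarray(train, dtype=float)
    spans = isi_n_values(t, N)
    ok = spans <= threshold
    bursts: list[tuple[float, float]] = []
    i = 0
    while i < ok.size:
        if ok[i]:
            j = i
            while j + 1 < ok.size and ok[j + 1]:
                j += 1
            bursts.append((float(t[i]), float(t[j + N - 1])))
            i = j + 1
        else:
            i += 1
    return bursts


def merge_adjacent(
    bursts: list[tuple[float, float]], merging_fraction: float
) -> list[tuple[float, float]]:
    """Merge neighbours whose gap is < fraction × the longer duration.

    Iterated to a fixpoint so that chains of short bursts flanking a long
    one collapse into a single interval.
    """
    merged = list(bursts)
    changed = True
    while changed:
        changed = False
        out: list[tuple[float, float]] = []
        for b in merged:
            if out:
                prev = out[-1]
                gap = b[0] - prev[1]
                longest = max(prev[1] - prev[0], b[1] - b[0])
                if gap < merging_fraction * longest:
                    out[-1] = (prev[0], max(prev[1], b[1]))
                    changed = True
                    continue
            out.append(b)
        merged = out
    return merged


def remove_short(
    bursts: list[tuple[float, float]], min_duration: float | None
) -> list[tuple[float, float]]:
    """Drop bursts shorter than ``min_duration``; None disables the step."""
    if min_duration is None or min_duration <= 0:
        return list(bursts)
    return [b for b in bursts if b[1] - b[0] >= min_duration]


def apply_channel_criteria(
    bursts: list[tuple[float, float]],
    spikes: SpikeListSet,
    compartment: str,
    params: NBDetectionParams,
) -> list[NetworkBurst]:
    """Channel participation filter and NetworkBurst assembly.

    For each burst interval (closed at spike resolution) the per-electrode
    spike counts are computed; electrodes with >= 1 spike participate.  The
    mean channel contribution is the burst spike count divided by the
    number of participating channels (or by all channels when configured),
    and an electrode dominates when its count reaches
    ``min_contribution_fraction`` times that mean.  Bursts with fewer than
    ``min_channels`` dominating electrodes are rejected.
    """
    labels = spikes.compartment_labels(compartment)
    out: list[NetworkBurst] = []
    for start, end in bursts:
        counts: dict[str, int] = {}
        total = 0
        for label in labels:
            ts = spikes.spikes[label]
            c = int(np.searchsorted(ts, end, side="right") - np.searchsorted(ts, start, side="left"))
            counts[label] = c
            total += c
        participating = frozenset(l for l, c in counts.items() if c >= 1)
        if not participating:
            continue
        denom = len(labels) if params.mean_over_all_channels else len(participating)
        mean_contribution = total / denom
        cutoff = params.min_contribution_fraction * mean_contribution
        dominating = frozenset(l for l, c in counts.items() if c >= cutoff and c >= 1)
        if len(dominating) < params.min_channels:
            continue
        out.append(
            NetworkBurst(
                compartment=compartment,
                start=start,
                end=end,
                spike_count=total,
                per_channel_counts=counts,
                participating_channels=participating,
                dominating_channels=dominating,
            )
        )
    return out


def detect_network_bursts(
    spikes: SpikeListSet,
    compartment: str,
    params: NBDetectionParams | None = None,
) -> list[NetworkBurst]:
    """Full per-compartment pipeline: pool, threshold, detect, refine.

    Returns an empty list (with a logged diagnostic) when the compartment
    has too few spikes or a unimodal ISI_N histogram.
    """
    params = params or NBDetectionParams()
    train = pool_compartment_spikes(spikes, compartment)
    if train.size < params.N:
        log.info("compartment %s: %d spikes < N=%d, no bursts", compartment, train.size, params.N)
        return []
    values = isi_n_values(train, params.N)
    threshold = isi_n_threshold(values, params)
    if threshold is None:
        log.info("compartment %s: unimodal ISI_N histogram, no bursts reported", compartment)
        return []
    initial = detect_nb_initial(train, params.N, threshold)
    merged = merge_adjacent(initial, params.merging_fraction)
    kept = remove_short(merged, params.min_duration)
    return apply_channel_criteria(kept, spikes, compartment, params)
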