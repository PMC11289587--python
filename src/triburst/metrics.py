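"""Burst output parameters and paired before/after statistics.

Eight parameters summarize a burst list (network bursts of one
compartment, or circuitry bursts over the whole platform): mean
inter-burst interval, mean burst duration, mean spike frequency in bursts,
percentage of spikes in bursts, mean spikes in bursts, total number of
bursts, mean channels in bursts and mean dominating channels in bursts.
Undefined values (no bursts, or fewer than two for the IBI) propagate as
NaN — never as silent zeros — so they drop out of paired tests instead of
biasing them.

Before/after comparisons use the Wilcoxon matched-pairs signed-rank test
with a Bonferroni-adjusted level for the family of eight hypotheses
(0.05/8 = 0.00625), and a 5-minute binned percent-change table normalized
to the last baseline bin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

from .layout import SpikeListSet

__all__ = [
    "BurstParameterSet",
    "PairedComparison",
    "PARAMETER_NAMES",
    "compute_parameters",
    "paired_wilcoxon",
    "bonferroni_alpha",
    "compare_parameter_sets",
    "binned_percent_change",
    "clip_for_display",
]

PARAMETER_NAMES = (
    "mean_ibi",
    "mean_burst_duration",
    "mean_spike_frequency_in_bursts",
    "percent_spikes_in_bursts",
    "mean_spikes_in_bursts",
    "total_bursts",
    "mean_channels_in_bursts",
    "mean_dominating_channels_in_bursts",
)


@dataclass(frozen=True)
class BurstParameterSet:
    """The eight burst output parameters; NaN marks undefined values."""

    mean_ibi: float = math.nan                       # s
    mean_burst_duration: float = math.nan            # s
    mean_spike_frequency_in_bursts: float = math.nan  # Hz
    percent_spikes_in_bursts: float = math.nan       # %
    mean_spikes_in_bursts: float = math.nan          # count
    total_bursts: int = 0
    mean_channels_in_bursts: float = math.nan        # count
    mean_dominating_channels_in_bursts: float = math.nan  # count

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_series(self) -> pd.Series:
        return pd.Series(self.as_dict(), dtype=float)


@dataclass
class PairedComparison:
    parameter: str
    before: np.ndarray
    after: np.ndarray
    p_value: float
    adjusted_alpha: float

    @property
    def significant_raw(self) -> bool:
        return self.p_value < 0.05

    @property
    def significant_adjusted(self) -> bool:
        return self.p_value < self.adjusted_alpha


def _event_window(ev) -> tuple[float, float]:
    if hasattr(ev, "start"):
        return float(ev.start), float(ev.end)
    return float(ev[0]), float(ev[1])


def compute_parameters(
    bursts: list,
    spikes: SpikeListSet,
    scope: str | None = None,
    min_contribution_fraction: float = 0.15,
    ibi_start_to_start: bool = False,
    frequency_pooled: bool = False,
) -> BurstParameterSet:
    """Compute the eight output parameters for one burst list.

    Parameters
    ----------
    bursts
        Ordered, disjoint events (NetworkBurst, CircuitryEvent, or
        (start, end) pairs).
    spikes
        The recording's spike lists; spike and channel statistics are
        evaluated inside each event window.
    scope
        Compartment name to restrict counting to its 24 electrodes, or
        ``None`` to pool all electrodes (circuitry-level events).
    min_contribution_fraction
        Dominating-channel criterion: in-window count >= fraction × mean
        count per participating channel.
    ibi_start_to_start
        Alternative IBI convention; default is end→start gaps.
    frequency_pooled
        Divide total in-burst spikes by total burst time instead of
        averaging per-burst rates.
    """
    labels = spikes.layout.labels(scope)
    windows = [_event_window(ev) for ev in bursts]
    n = len(windows)
    if n == 0:
        return BurstParameterSet(total_bursts=0)

    durations = np.array([e - s for s, e in windows])
    spike_counts = np.zeros(n)
    channel_counts = np.zeros(n)
    dominating_counts = np.zeros(n)
    for idx, (s, e) in enumerate(windows):
        counts = {}
        for label in labels:
            ts = spikes.spikes[label]
            counts[label] = int(
                np.searchsorted(ts, e, side="right") - np.searchsorted(ts, s, side="left")
            )
        total = sum(counts.values())
        participating = [l for l, c in counts.items() if c >= 1]
        spike_counts[idx] = total
        channel_counts[idx] = len(participating)
        if participating:
            cutoff = min_contribution_fraction * (total / len(participating))
            dominating_counts[idx] = sum(1 for l in participating if counts[l] >= cutoff)

    if ibi_start_to_start:
        ibis = np.array([windows[i + 1][0] - windows[i][0] for i in range(n - 1)])
    else:
        ibis = np.array([windows[i + 1][0] - windows[i][1] for i in range(n - 1)])
    total_spikes_in_scope = int(sum(spikes.spikes[l].size for l in labels))

    with np.errstate(divide="ignore", invalid="ignore"):
        if frequency_pooled:
            mean_freq = float(spike_counts.sum() / durations.sum()) if durations.sum() > 0 else math.nan
        else:
            rates = spike_counts / durations
            mean_freq = float(np.mean(rates[np.isfinite(rates)])) if np.any(np.isfinite(rates)) else math.nan

    return BurstParameterSet(
        mean_ibi=float(np.mean(ibis)) if n >= 2 else math.nan,
        mean_burst_duration=float(np.mean(durations)),
        mean_spike_frequency_in_bursts=mean_freq,
        percent_spikes_in_bursts=(
            100.0 * spike_counts.sum() / total_spikes_in_scope
            if total_spikes_in_scope > 0
            else math.nan
        ),
        mean_spikes_in_bursts=float(np.mean(spike_counts)),
        total_bursts=n,
        mean_channels_in_bursts=float(np.mean(channel_counts)),
        mean_dominating_channels_in_bursts=float(np.mean(dominating_counts)),
    )


def paired_wilcoxon(before, after) -> float:
    """Two-sided Wilcoxon matched-pairs signed-rank p-value.

    Zero differences are dropped (the classical convention); the exact
    null distribution is used for n <= 25.  All-zero differences yield
    p = 1 with a warning.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after must have equal length")
    mask = np.isfinite(before) & np.isfinite(after)
    d = after[mask] - before[mask]
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    if d.size < 2:
        return 1.0
    method = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.pvalue)


def bonferroni_alpha(alpha: float = 0.05, m: int = 8) -> float:
    """Bonferroni-adjusted per-test level alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def compare_parameter_sets(
    before: list[BurstParameterSet],
    after: list[BurstParameterSet],
    alpha: float = 0.05,
    family_size: int = 8,
) -> list[PairedComparison]:
    """Paired Wilcoxon tests for every parameter over matched plates."""
    if len(before) != len(after):
        raise ValueError("before/after plate lists must be paired")
    adj = bonferroni_alpha(alpha, family_size)
    out = []
    for name in PARAMETER_NAMES:
        b = np.array([getattr(p, name) for p in before], dtype=float)
        a = np.array([getattr(p, name) for p in after], dtype=float)
        out.append(PairedComparison(name, b, a, paired_wilcoxon(b, a), adj))
    return out


def binned_percent_change(
    baseline_bins: list[BurstParameterSet],
    exposure_bins: list[BurstParameterSet],
) -> pd.DataFrame:
    """Percent change of each parameter per exposure bin vs the reference.

    The reference is the **last** baseline bin; change is
    100 × (value − reference)/reference.  Columns are undefined (NaN)
    where the reference is undefined or zero.  Values are not clipped here
    — use :func:`clip_for_display` for the ±50% heatmap rendering.
    """
    if not baseline_bins:
        raise ValueError("need at least one baseline bin")
    ref = baseline_bins[-1].as_series()
    rows = {}
    for i, binset in enumerate(exposure_bins):
        v = binset.as_series()
        with np.errstate(divide="ignore", invalid="ignore"):
            change = 100.0 * (v - ref) / ref
        change[~np.isfinite(ref) | (ref == 0)] = np.nan
        rows[f"bin_{i + 1}"] = change
    return pd.DataFrame(rows)


def clip_for_display(table: pd.DataFrame, limit: float = 50.0) -> pd.DataFrame:
    """Clip a percent-change table to ±limit for heatmap rendering only."""
    return table.clip(lower=-limit, upper=limit)
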