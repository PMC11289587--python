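"""Functional connectivity from raw signals: correlated spectral entropy.

CorSE quantifies the connectivity of two electrodes by how similarly the
*spectral content* of their raw signals evolves over time, which makes it
sensitive to slow local-field-potential dynamics rather than to spike
timing alone.  Each trace is cut into windows (default 1 s,
non-overlapping); per window the power spectrum is estimated and its
normalized Shannon entropy

    H = − Σ p_k log p_k / log K,    p_k = P_k / Σ P,   H ∈ [0, 1]

is computed, giving one entropy time series per electrode.  The CorSE
value of a pair is the maximum absolute normalized cross-correlation of
the two mean-removed entropy series over a small lag window.  The full
72×72 matrix is summarized by three intracompartmental averages (276
pairs each) and three intercompartmental averages (576 pairs each).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import signal

from .layout import RawRecording

__all__ = [
    "CorseParams",
    "ConnectivityResult",
    "spectral_entropy_series",
    "corse_pair",
    "connectivity_matrix",
    "connectivity_percent_change",
]


@dataclass(frozen=True)
class CorseParams:
    """window_length in seconds; overlap as a fraction of the window."""

    window_length: float = 1.0
    window_overlap: float = 0.0
    welch_segments: int = 4   # Welch sub-segments per window
    max_lag_windows: int = 5  # cross-correlation lag bound, in windows

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if not 0 <= self.window_overlap < 1:
            raise ValueError("window_overlap must be in [0, 1)")
        if self.max_lag_windows < 0:
            raise ValueError("max_lag_windows must be >= 0")


@dataclass
class ConnectivityResult:
    labels: list[str]
    pair_matrix: np.ndarray = field(repr=False)  # symmetric, unit diagonal, NaN = undefined
    intra_averages: dict[str, float] = field(default_factory=dict)
    inter_averages: dict[str, float] = field(default_factory=dict)
    low_confidence: bool = False

    def to_dict(self) -> dict:
        return {
            "intra_averages": dict(self.intra_averages),
            "inter_averages": dict(self.inter_averages),
            "low_confidence": self.low_confidence,
        }


def spectral_entropy_series(
    trace: np.ndarray, fs: float, params: CorseParams | None = None
) -> np.ndarray:
    """Normalized power-spectrum Shannon entropy per time window.

    All-zero windows yield NaN.  Entropy is invariant under amplitude
    scaling of the trace (the spectrum is normalized to a probability
    distribution before the entropy sum).
    """
    params = params or CorseParams()
    x = np.asarray(trace, dtype=float)
    win = int(round(params.window_length * fs))
    if x.size < win:
        raise ValueError("trace shorter than one window")
    step = max(1, int(round(win * (1 - params.window_overlap))))
    nperseg = max(8, win // params.welch_segments)
    out = []
    for start in range(0, x.size - win + 1, step):
        seg = x[start : start + win]
        if not np.any(seg):
            out.append(math.nan)
            continue
        _, psd = signal.welch(seg, fs=fs, nperseg=nperseg)
        total = psd.sum()
        if total <= 0:
            out.append(math.nan)
            continue
        p = psd / total
        nz = p[p > 0]
        out.append(float(-(nz * np.log(nz)).sum() / math.log(p.size)))
    return np.asarray(out)


def corse_pair(se_a: np.ndarray, se_b: np.ndarray, params: CorseParams | None = None) -> float:
    """Maximum |normalized cross-correlation| of two entropy series.

    Undefined windows are dropped pairwise before correlation.  Constant
    series have zero variance and return NaN.  By Cauchy-Schwarz the
    value lies in [0, 1]; corse_pair(x, x) = 1 at lag 0.
    """
    params = params or CorseParams()
    a = np.asarray(se_a, dtype=float)
    b = np.asarray(se_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("entropy series must have equal length")
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if a.size < 8:
        return math.nan
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return math.nan  # constant series: zero variance
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return math.nan
    best = 0.0
    for lag in range(-params.max_lag_windows, params.max_lag_windows + 1):
        if lag >= 0:
            u, v = a[lag:], b[: b.size - lag]
        else:
            u, v = a[: a.size + lag], b[-lag:]
        if u.size == 0:
            continue
        best = max(best, abs(float(np.dot(u, v))) / (na * nb))
    return min(best, 1.0)


def connectivity_matrix(
    recording: RawRecording, params: CorseParams | None = None
) -> ConnectivityResult:
    """CorSE over all unordered electrode pairs plus compartment averages.

    Deterministic for a fixed input.  When more than half of the pairs are
    undefined the result is flagged low-confidence.
    """
    params = params or CorseParams()
    layout = recording.layout
    labels = layout.labels()
    fs = layout.sampling_rate
    series = {lab: spectral_entropy_series(recording.traces[lab], fs, params) for lab in labels}
    n = len(labels)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1.0)
    idx = {lab: i for i, lab in enumerate(labels)}
    n_undef = 0
    for la, lb in combinations(labels, 2):
        v = corse_pair(series[la], series[lb], params)
        mat[idx[la], idx[lb]] = mat[idx[lb], idx[la]] = v
        if not np.isfinite(v):
            n_undef += 1
    n_pairs = n * (n - 1) // 2

    comp_of = {lab: lab[0] for lab in labels}
    intra: dict[str, float] = {}
    for c in layout.compartments:
        vals = [
            mat[idx[la], idx[lb]]
            for la, lb in combinations([l for l in labels if comp_of[l] == c], 2)
        ]
        intra[c] = _nanmean(vals)
    inter: dict[str, float] = {}
    for ca, cb in combinations(layout.compartments, 2):
        vals = [
            mat[idx[la], idx[lb]]
            for la in labels
            if comp_of[la] == ca
            for lb in labels
            if comp_of[lb] == cb
        ]
        inter[ca + cb] = _nanmean(vals)
    return ConnectivityResult(
        labels=labels,
        pair_matrix=mat,
        intra_averages=intra,
        inter_averages=inter,
        low_confidence=n_undef > 0.5 * n_pairs,
    )


def _nanmean(vals) -> float:
    arr = np.asarray(vals, dtype=float)
    finite = arr[np.isfinite(arr)]
    return float(finite.mean()) if finite.size else math.nan


def connectivity_percent_change(
    before: ConnectivityResult, after: ConnectivityResult
) -> dict[str, float]:
    """Percent change of the six compartment averages (unclipped).

    Undefined baselines yield NaN, never 0.  Clip to ±50 only for heatmap
    display.
    """
    out: dict[str, float] = {}
    for key in list(before.intra_averages) + list(before.inter_averages):
        b = before.intra_averages.get(key, before.inter_averages.get(key))
        a = after.intra_averages.get(key, after.inter_averages.get(key))
        if b is None or a is None or not np.isfinite(b) or b == 0:
            out[key] = math.nan
        else:
            out[key] = 100.0 * (a - b) / b
    return out
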