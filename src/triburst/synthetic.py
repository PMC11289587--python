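"""Ground-truth-annotated synthetic recordings for every pipeline stage.

The generator emulates the study conditions: 30-minute recordings of a
three-compartment platform with homogeneous Poisson background firing
(0.2 Hz per electrode), planted network-burst epochs (~1 s at 20 Hz per
active electrode on half of each compartment's 24 channels), and tunable
cross-compartment coupling — each epoch is realized in all three
compartments (a circuitry burst) with probability ``cb_coupling``, in a
random pair (an intermediate circuitry burst) with probability
``icb_coupling``, and in a single compartment otherwise.

Raw-waveform synthesis adds Gaussian noise, a fixed ~1 ms biphasic spike
template at each spike time, and — for connectivity tests — a narrowband
tone whose slow amplitude envelope is shared across electrodes with
strength ``envelope_coupling``, which modulates the windowed spectral
entropy coherently across channels.

Everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import PlatformLayout, RawRecording, SpikeListSet

__all__ = [
    "SimulationParams",
    "PlantedTruth",
    "gen_spike_lists",
    "gen_raw",
    "spike_template",
    "gen_coupled_traces",
]


@dataclass(frozen=True)
class SimulationParams:
    """Synthetic-recording parameters; defaults follow the study setup."""

    duration: float = 1800.0              # s, one 30 min recording
    background_rate: float = 0.2          # Hz per electrode
    nb_rate: float = 20.0                 # Hz per active electrode during a burst
    nb_duration_mean: float = 1.0         # s
    nb_duration_sd: float = 0.2           # s
    nb_count: int = 100                   # planted burst epochs per recording
    active_channel_fraction: float = 0.5  # fraction of a compartment's electrodes active in a burst
    cb_coupling: float = 0.8              # P(epoch spans all three compartments)
    icb_coupling: float = 0.1             # P(epoch spans exactly two)
    spike_amplitude_snr: float = 8.0      # spike peak / noise SD
    noise_sd: float = 5.0                 # µV
    envelope_coupling: float = 0.0        # shared slow power-modulation strength, [0, 1]
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.cb_coupling <= 1 and 0 <= self.icb_coupling <= 1):
            raise ValueError("coupling probabilities must be in [0, 1]")
        if self.cb_coupling + self.icb_coupling > 1:
            raise ValueError("cb_coupling + icb_coupling must be <= 1")
        if not 0 < self.active_channel_fraction <= 1:
            raise ValueError("active_channel_fraction must be in (0, 1]")
        if min(self.duration, self.nb_duration_mean) <= 0 or self.nb_count < 0:
            raise ValueError("duration, nb_duration_mean must be > 0 and nb_count >= 0")


@dataclass
class PlantedTruth:
    """What was planted: epoch intervals, membership, and true spikes."""

    epochs: list[tuple[float, float, frozenset[str]]] = field(default_factory=list)
    spike_times: dict[str, np.ndarray] = field(default_factory=dict)

    def compartment_intervals(self, compartment: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, members in self.epochs if compartment in members]

    def epochs_with_membership(self, size: int) -> list[tuple[float, float, frozenset[str]]]:
        return [ep for ep in self.epochs if len(ep[2]) == size]


def _place_epochs(rng: np.random.Generator, params: SimulationParams) -> list[tuple[float, float]]:
    """Non-overlapping epochs with a minimum gap of 2× the mean duration."""
    n = params.nb_count
    if n == 0:
        return []
    durations = np.clip(
        rng.normal(params.nb_duration_mean, params.nb_duration_sd, n),
        0.1 * params.nb_duration_mean,
        None,
    )
    gap_min = 2.0 * params.nb_duration_mean
    needed = durations.sum() + (n + 1) * gap_min
    if needed > params.duration:
        raise ValueError(
            f"{n} epochs of ~{params.nb_duration_mean}s with {gap_min}s gaps "
            f"do not fit in {params.duration}s"
        )
    slack = params.duration - needed
    weights = rng.random(n + 1)
    extra = slack * weights / weights.sum()
    epochs = []
    t = 0.0
    for i in range(n):
        t += gap_min + extra[i]
        epochs.append((t, t + durations[i]))
        t += durations[i]
    return epochs


def gen_spike_lists(
    params: SimulationParams | None = None,
    layout: PlatformLayout | None = None,
) -> tuple[SpikeListSet, PlantedTruth]:
    """Generate a spike-list recording with planted multilevel bursts."""
    params = params or SimulationParams()
    layout = layout or PlatformLayout()
    rng = np.random.default_rng(params.seed)

    epochs = _place_epochs(rng, params)
    comps = list(layout.compartments)
    membership: list[frozenset[str]] = []
    for _ in epochs:
        r = rng.random()
        if r < params.cb_coupling:
            membership.append(frozenset(comps))
        elif r < params.cb_coupling + params.icb_coupling:
            pair = rng.choice(len(comps), size=2, replace=False)
            membership.append(frozenset(comps[i] for i in pair))
        else:
            membership.append(frozenset((comps[rng.integers(len(comps))],)))

    n_active = max(1, int(round(params.active_channel_fraction * layout.electrodes_per_compartment)))
    spikes: dict[str, list[np.ndarray]] = {lab: [] for lab in layout.labels()}
    # background: homogeneous Poisson per electrode
    for lab in layout.labels():
        k = rng.poisson(params.background_rate * params.duration)
        spikes[lab].append(rng.uniform(0.0, params.duration, k))
    # planted epochs
    for (start, end), members in zip(epochs, membership):
        dur = end - start
        for c in members:
            labels = layout.labels(c)
            chosen = rng.choice(len(labels), size=n_active, replace=False)
            for idx in chosen:
                k = rng.poisson(params.nb_rate * dur)
                spikes[labels[idx]].append(rng.uniform(start, end, k))

    merged: dict[str, np.ndarray] = {}
    for lab, parts in spikes.items():
        allts = np.concatenate(parts) if parts else np.empty(0)
        merged[lab] = np.unique(allts)  # sorted, strictly increasing

    truth = PlantedTruth(
        epochs=[(s, e, m) for (s, e), m in zip(epochs, membership)],
        spike_times=dict(merged),
    )
    sls = SpikeListSet(layout=layout, spikes=merged, duration=params.duration)
    return sls, truth


def spike_template(fs: float, width_s: float = 1e-3) -> np.ndarray:
    """Biphasic extracellular spike template with unit negative peak."""
    n = max(5, int(round(width_s * fs)))
    t = np.linspace(0, 1, n)
    w = -np.sin(2 * np.pi * t) * np.hanning(n)
    return w / np.abs(w).max()


def _slow_envelope(rng: np.random.Generator, n_samples: int, fs: float) -> np.ndarray:
    """Unit-amplitude slow sinusoid with random frequency and phase."""
    f = rng.uniform(0.05, 0.25)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n_samples) / fs
    return np.sin(2 * np.pi * f * t + phase)


def gen_raw(
    spikes: SpikeListSet,
    params: SimulationParams | None = None,
    tone_freq: float = 2000.0,
    tone_snr: float = 4.0,
) -> RawRecording:
    """Synthesize raw traces from a spike list.

    Each trace is Gaussian noise of ``noise_sd`` µV with the biphasic
    template (peak ``spike_amplitude_snr × noise_sd``) added at every
    spike time.  With ``envelope_coupling > 0`` a tone at ``tone_freq``
    is added whose slow amplitude envelope mixes a shared component (by
    coupling strength c) with an independent one per electrode, so the
    windowed spectral entropy co-varies across electrodes.
    """
    params = params or SimulationParams()
    layout = spikes.layout
    fs = layout.sampling_rate
    n = int(round(spikes.duration * fs))
    rng = np.random.default_rng(params.seed + 1)
    template = spike_template(fs) * params.spike_amplitude_snr * params.noise_sd
    tlen = template.size
    shared = _slow_envelope(rng, n, fs) if params.envelope_coupling > 0 else None
    traces: dict[str, np.ndarray] = {}
    for lab in layout.labels():
        x = rng.normal(0.0, params.noise_sd, n)
        for t in spikes.spikes[lab]:
            i = int(round(t * fs))
            j = min(i + tlen, n)
            if i < n:
                x[i:j] += template[: j - i]
        if shared is not None:
            c = params.envelope_coupling
            own = _slow_envelope(rng, n, fs)
            env = c * shared + (1 - c) * own
            amp = tone_snr * params.noise_sd * 0.5 * (1 + env)
            t_ax = np.arange(n) / fs
            x += amp * np.sin(2 * np.pi * tone_freq * t_ax)
        traces[lab] = x
    return RawRecording(layout=layout, traces=traces)


def gen_coupled_traces(
    n_traces: int,
    duration: float,
    fs: float,
    coupling: float,
    seed: int = 0,
    noise_sd: float = 5.0,
    tone_freq: float = 2000.0,
    tone_snr: float = 4.0,
) -> np.ndarray:
    """Noise traces with a tone whose envelope is shared at strength ``coupling``.

    A lightweight layout-free variant of :func:`gen_raw`'s envelope model
    for connectivity experiments: returns an (n_traces, n_samples) array.
    """
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    shared = _slow_envelope(rng, n, fs)
    t_ax = np.arange(n) / fs
    out = np.empty((n_traces, n))
    for i in range(n_traces):
        own = _slow_envelope(rng, n, fs)
        env = coupling * shared + (1 - coupling) * own
        amp = tone_snr * noise_sd * 0.5 * (1 + env)
        out[i] = rng.normal(0.0, noise_sd, n) + amp * np.sin(2 * np.pi * tone_freq * t_ax)
    return out
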