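import numpy as np
import pytest

from triburst.layout import PlatformLayout, SpikeListSet


@pytest.fixture(scope="session")
def layout():
    """The full platform: 3 compartments x 24 electrodes at 25 kHz."""
    return PlatformLayout()


@pytest.fixture(scope="session")
def mini_layout():
    """A small layout (3 x 4 electrodes) for fast raw-trace tests."""
    return PlatformLayout(electrodes_per_compartment=4, sampling_rate=25_000.0)


def make_spike_set(layout, spikes, duration):
    """SpikeListSet from a sparse {label: iterable} dict."""
    return SpikeListSet(
        layout=layout,
        spikes={k: np.asarray(v, dtype=float) for k, v in spikes.items()},
        duration=duration,
    )


def random_interval_list(rng, duration, n, lattice=0.002, min_len=0.05, max_len=1.0, min_gap=0.05):
    """Disjoint ordered intervals with endpoints on a 2 ms lattice.

    The lattice keeps every pairwise/triple intersection either empty or
    at least one grid cell long, so a 1 ms boolean-grid oracle resolves
    all boundaries exactly.
    """
    ivs = []
    t = float(rng.uniform(0, min_gap * 4))
    for _ in range(n):
        length = rng.uniform(min_len, max_len)
        s = round(t / lattice) * lattice
        e = round((t + length) / lattice) * lattice
        if e >= duration:
            break
        if e > s:
            ivs.append((s, e))
        t = e + rng.uniform(min_gap, 6 * min_gap)
    return ivs


def grid_cb_oracle(interval_lists, duration, dt=0.001):
    """Brute-force boolean-AND oracle: maximal runs where all lists cover."""
    n = int(round(duration / dt))
    mask = np.ones(n, dtype=bool)
    for ivs in interval_lists:
        m = np.zeros(n, dtype=bool)
        for s, e in ivs:
            m[int(round(s / dt)) : int(round(e / dt))] = True
        mask &= m
    return _runs(mask, dt)


def _runs(mask, dt):
    out = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for a, b in zip(idx[::2], idx[1::2]):
        out.append((a * dt, b * dt))
    return out


def grid_icb_oracle(intervals_by_comp, duration, dt=0.001):
    """Pairwise AND runs, excluding runs that overlap a three-way AND run."""
    comps = sorted(intervals_by_comp)
    cb_runs = grid_cb_oracle([intervals_by_comp[c] for c in comps], duration, dt)
    out = {}
    from itertools import combinations

    for ca, cb in combinations(comps, 2):
        runs = grid_cb_oracle([intervals_by_comp[ca], intervals_by_comp[cb]], duration, dt)
        kept = [
            r for r in runs
            if not any(min(r[1], e) > max(r[0], s) for s, e in cb_runs)
        ]
        out[ca + cb] = kept
    return out
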