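# Methods

This note documents the models and procedures implemented in `triburst`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic-data experiments do and do not
demonstrate.

## Platform model

A recording platform carries three compartments (A, B, C) of 24
electrodes each, 72 channels total, sampled at 25 kHz. Electrode labels
are the compartment letter plus a zero-padded index (`A07`). Spike
timestamps are seconds from recording start. Burst intervals are closed
`[start, end]` at spike-time resolution; intersections of measure zero
(point contact) are never events.

Recording-level QC flags time bins (default 1 s) in which the
bin-normalized firing rate exceeds 40 Hz on more than 75 % of electrodes
simultaneously — the signature of array-wide non-biological noise.
Flagged intervals are reported, never silently dropped; the 75 % fraction
and the bin width are configuration values because the rejection rule in
practice is a judgment call made on raster plots.

## Spike detection

Zero-phase elliptic band-pass (order 4, 0.1 dB ripple, 40 dB stopband,
200–3000 Hz, forward–backward) precedes two parallel detectors:

- *Amplitude threshold* at k·σ̂ with k = 4.5 and the robust noise
  estimate σ̂ = median(|x|)/0.6745, which a sparse spike train inflates
  far less than the plain SD. Both polarities are detected (|x| peaks),
  with a 1 ms refractory separation.
- *SWTTEO energy*: stationary-wavelet detail coefficients (Haar, level 2
  at 25 kHz, covering the upper spike band) passed through the Teager
  energy operator ψ[x](n) = x(n)² − x(n−1)x(n+1), rectified and smoothed
  with a 0.5 ms Hamming window. The number M of threshold candidates is
  handed to the energy detector, which picks its own M strongest peaks
  (refractory-separated; ties broken by earlier time for determinism).

A candidate is accepted only when a selected energy peak lies within
1 ms, so the output is always a subset of the threshold candidates. The
filter design constants, wavelet, level and windows are engineering
defaults exposed in configuration, not claims about any external
implementation. On synthetic 25 kHz traces with spike peaks at 8× the
noise SD the consensus detector reaches ≥ 95 % sensitivity and precision
(measured in the test suite and by `scripts/acceptance.py`).

## Network-burst detection (ISI_N)

All spikes of one compartment are pooled into a single sorted train and
the span of every N consecutive spikes, t[i+N−1] − t[i] with N = 20, is
histogrammed in log10 with 40 bins per decade over the observed range,
smoothed with a Gaussian kernel of SD 2 bins. In a bursting network the
distribution is bimodal — short in-burst spans versus long between-burst
spans — and the threshold is the abscissa of the minimum bin strictly
between the two most prominent local maxima (prominence ≥ 1 % of the
maximum). With fewer than two peaks the compartment is reported
burst-free with a diagnostic; inventing a fixed fallback threshold would
silently change the method's semantics, so none is used.

Initial bursts are maximal runs of qualifying windows; a burst starts at
the first spike of its first qualifying window and ends at the last spike
of its last qualifying window. Refinement steps:

1. *Adaptive merging*: neighbouring bursts merge when the gap
   (end → next start) is shorter than 0.2 × the longer of the two
   durations, iterated to a fixpoint.
2. *Short-burst removal*: disabled by default; a duration floor can be
   configured.
3. *Channel criteria*: per burst, electrodes with ≥ 1 spike participate;
   the mean channel contribution is the burst spike count divided by the
   number of participating channels (dividing by all 24 is available in
   configuration); an electrode *dominates* when its count reaches
   0.15 × that mean; bursts with fewer than 3 dominating electrodes are
   rejected.

### Boundary accuracy

The boundary convention together with a valley threshold has one known
consequence: a background spike within (threshold − in-burst window span)
of a burst edge is absorbed into a qualifying window and extends the
reported interval. At the synthetic study conditions (24 × 0.2 Hz pooled
background, ~1 s bursts at 240 Hz pooled, valley ≈ 0.2 s) every planted
burst is recovered and no false bursts appear, but roughly a fifth of
bursts carry a boundary error between 0.1 and ~0.15 s (mean per-side
error ≈ 30 ms). This is a property of the ISI_N method at these rates,
not of the implementation; burst-level statistics (counts, durations at
the ~1 s scale, spike counts) are essentially unaffected.

## Circuitry-level events

CBs are maximal intervals where all three compartments have an ongoing NB
(three-way interval intersection via a linear sweep; zero inter-compartment
delay is assumed because the many microtunnels make propagation delays
negligible — a symmetric lag tolerance is configurable, default 0). ICBs
are maximal pairwise intersections; a candidate that overlaps any CB with
positive measure is excluded entirely rather than trimmed, which avoids
double counting and sub-second ICB fragments flanking every CB (trimming
is available as a configuration switch). Plate labels: *full synchrony*
when every NB in every compartment overlaps some CB; *no-ICB* when no
intermediate events remain.

The implementation is verified against a brute-force 1 ms boolean-AND
grid oracle on randomized interval triples (boundaries within 1 ms).

## Surrogate randomness test

The test metric is the cumulative CB duration. Each surrogate shifts each
compartment's NB intervals by an independent delta drawn uniformly from
[−20, 20] s, wrapping circularly modulo the recording duration (an
interval crossing the boundary splits in two). Circular wrap preserves
each compartment's total burst time; a truncating shift would not. For
the n = n_simulations + 1 alignments, u_i = |x_i − mean of the others|,
and the empirical p is the 1-based descending rank of u_observed divided
by n. Ties place the observed value first (the anti-conservative
direction; the opposite is configurable) — for a continuous metric ties
have measure zero. Non-randomness is declared at p ≤ 0.05.

Calibration: on compartments with independently placed bursts the
rejection rate at p ≤ 0.05 sits at the nominal 5 % (within the binomial
confidence band over 200 seeded runs at 500 surrogates each); on a
perfectly coupled plate with 5000 surrogates p reaches the attainable
minimum 1/5001 < 0.005.

## Burst output parameters and statistics

Eight parameters per burst list: mean IBI (end → start gaps, requiring
≥ 2 bursts), mean duration, mean spike frequency in bursts (per-burst
rates averaged; pooled total-spikes/total-time is configurable), percent
of spikes in bursts, mean spikes in bursts, total bursts, mean channels
and mean dominating channels in bursts. NB-scope statistics count the
compartment's 24 electrodes; CB-scope statistics pool all 72, since CBs
are platform-wide events. Undefined values propagate as NaN — never as
zeros, which would bias paired tests.

Before/after comparisons use the two-sided Wilcoxon matched-pairs
signed-rank test (zero differences dropped; exact null distribution for
n ≤ 25) at the Bonferroni-adjusted level α/m = 0.05/8 = 0.00625 for the
family of eight parameters at one synchrony level. The exact p is
verified in the tests against exhaustive 2ⁿ sign enumeration. Time-variant
effects are summarized as percent changes of each parameter in 5-minute
bins relative to the last baseline bin; the table is never clipped, and
the ±50 % clamp exists only for heatmap rendering.

## CorSE functional connectivity

Each raw trace is cut into 1 s non-overlapping windows (length and
overlap configurable); per window a Welch-averaged periodogram is
normalized to a probability distribution over its K frequency bins and
H = −Σ p log p / log K ∈ [0, 1] computed. All-zero windows are undefined
and dropped pairwise. The CorSE value of an electrode pair is the maximum
absolute normalized cross-correlation of the two mean-removed entropy
series over lags up to 5 windows (by Cauchy–Schwarz the value is ≤ 1, and
a series against itself gives exactly 1 at lag 0). Constant entropy
series have no variance and yield a missing value; a result with more
than half of its 2556 pairs missing is flagged low-confidence. The whole
broadband signal is used — no sub-band split — so slow local-field
components contribute alongside spikes. Compartment-level summaries are
the 3 intra-averages (276 pairs each) and 3 inter-averages (576 pairs
each); percent changes between conditions follow the same
never-clip-the-table rule as above.

Because entropy is invariant under amplitude scaling, a pure amplitude
envelope on white noise is invisible to CorSE; the synthetic coupling
model therefore modulates *spectral content* (below).

## Synthetic data

`gen_spike_lists` emulates the study conditions: 30-minute recordings,
homogeneous Poisson background at 0.2 Hz per electrode, 100 planted burst
epochs of duration ~N(1 s, 0.2 s) in which half of a compartment's
electrodes fire at 20 Hz (inhomogeneous Poisson with a rectangular rate
profile — the simplest profile with unambiguous onset/offset truth).
Epochs are non-overlapping with a minimum gap of twice the mean duration,
so the disjoint-NB invariant holds by construction. Each epoch is
realized in all three compartments with probability `cb_coupling` (0.8),
in a random pair with `icb_coupling` (0.1), and in a single compartment
otherwise; `nb_count` counts epochs per recording, since a strict
per-compartment count is ill-defined once epochs are shared. Everything
is bit-reproducible from the seed.

`gen_raw` adds Gaussian noise (5 µV SD), a fixed ~1 ms biphasic template
(peak 8× noise SD) at each spike time, and — for connectivity
experiments — a 2 kHz tone whose slow (0.05–0.25 Hz) amplitude envelope
mixes a shared component at strength c with an independent one per
electrode. The tone concentrates spectral power when strong, so the
windowed entropy tracks the envelope and mean CorSE grows monotonically
with c.

What the generator does *not* emulate: spike waveform diversity and
overlap, non-stationary background rates, genuine LFP dynamics,
inter-compartment propagation delays, electrode-specific noise, and
pharmacologically induced regime changes. Passing tests therefore
demonstrate the correctness and calibration of the algorithms under the
stated statistical conditions, not detection performance on biological
recordings.

## Problem sizes in the test suite

The suite and the acceptance script scale simulations to desk size as the
package's own defaults for automated verification: three 30-minute spike
list recordings for burst recovery, 600 s recordings for classification
and calibration, 10 s / 60 s raw traces for spike detection and
connectivity, 200 × 500 surrogate runs for the type-I rate and one
5000-surrogate run for power. Seeds are fixed in the tests; the
acceptance script derives all seeds from its `--seed` argument.

## Known limitations

- Burst boundaries inherit the ISI_N absorption effect described above.
- The unimodal-histogram fallback reports "no bursts" rather than
  attempting a fixed threshold; tonically firing compartments will look
  burst-free.
- The surrogate test shifts NB intervals, not spike trains; under pure
  translation the two are equivalent because the metric depends only on
  NB times, but surrogates that require re-detection (e.g., rate-modulated
  shuffles) are out of scope.
- CorSE values depend on the window length and lag bound; defaults (1 s,
  5 windows) are engineering choices exposed in configuration.
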