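# Methods

## The estimator

The package computes a period-domain power spectrum by ensemble averaging.
Given a zero-mean, unit-variance signal `x` of length `N` and a candidate
period `w` (integer samples), the `n = ⌊N/w⌋` whole segments of length `w`
are averaged element-wise into the ensemble mean `e_w`; any trailing
remainder (`N mod w` samples) is discarded. The spectral point is the
`√n`-scaled RMS ensemble power. In the implemented form everything reduces
to segment sums:

    S_w = (1/√N) · ‖ Σ_{i<n} x[i·w : (i+1)·w] ‖₂

Two conventions are fixed here and used consistently:

* **Normalization** is to population variance (divisor `N`), both in
  `normalize_signal` and in every internal standardization. `Signal`
  objects carry a `normalized` flag that is verified on construction.
* **Scaling** uses `1/√N` rather than the algebraically exact `1/√(n·w)`.
  The two differ by at most a factor `√(N/(n·w)) ≤ √(1 + w/N)` — under
  0.6 % relative on the 8192-sample window with periods ≤ 325 — and the
  `1/√N` form is the one that makes the streaming update divide-free.

With these conventions, unit-variance white noise has a flat spectral
baseline with grid mean ≈ 1 (the `√n` factor exactly counters the `1/√n`
decay of an averaged noise ensemble), and an exactly `w₀`-periodic
unit-variance signal with `N = n·w₀` attains `S_{w₀} = √n = √(N/w₀)`.
These two closed forms anchor the test suite.

**Period grid.** Candidate periods for a band `(f_lo, f_hi)` are all
integers from `⌊rate/f_lo⌋` down to `⌊rate/f_hi⌋`, with frequencies
`f = rate/w`. Flooring at both edges reproduces the canonical 977 Hz,
3–12 Hz grid of 245 periods, 325..81 — the top frequency 977/81 =
12.06 Hz slightly exceeds the band edge by construction, and this fidelity
is preferred over strict band containment. The local resolution
`rate/w − rate/(w+1) ≈ rate/w²` is finest at low frequencies; its grid
mean (≈ 0.0373 Hz on the canonical grid) is the single-figure summary
used for comparison against the uniform `rate/N` DFT bin spacing. When
quoting the printed comparison figures, the DFT numbers (0.122 Hz,
74 band bins) use the rounded 1 kHz rate, while the period-grid mean
resolution is a property of the actual 977 Hz grid; the resulting ratio
is ≈ 3.3.

**Half-period shortcut.** Segment sums for period `w` can be formed by
adding the two halves of the sum vector for `2w` when `2w` is also on the
grid. This halves the arithmetic for the lower half of the period range
but silently drops the final segment whenever `⌊N/w⌋` is odd, so the
direct path is the package reference and the shortcut
(`nse_spectrum_offline_halved`, CLI `--halved`) is an opt-in optimization.
On the canonical grid the chain runs two levels deep (81..162 fold from
162..324, and 162 itself folds from 324).

## Streaming form

The streaming estimator replaces the block average by a first-order
exponential moving average with weights `c1 = (n−1)/n`, `c2 = 1/n`, chosen
so the effective averaging depth matches the block segment count for each
period. Per period the state is a ring buffer of `w` slots (one ensemble
estimate per phase position), a wrap index, and a running power
`P_w = Σ_j e[j]²` maintained incrementally by removing the old squared
slot value and adding the new one. One input sample advances every
period's index by one, refreshes exactly one slot per period, and yields a
complete spectrum `S_w = n·√P_w / √N`; the move size is fixed at one
sample. All per-period state is stored in flat arrays so an update is a
handful of vectorized operations over the 245-period axis (~10 µs per
sample per channel in pure numpy on commodity hardware — reported by
`nse benchmark`, never asserted).

Numerical and semantic choices:

* **Warm-up.** The stream starts from an all-zero state and emits from the
  first sample. For the first `min(w)` samples every period holds the same
  filled slots, so the spectrum is flat up to rounding; parameter
  extraction treats such spectra (relative range ≤ 1e-9) as degenerate,
  and the multichannel driver records NaN parameter rows during warm-up
  rather than failing. After one full window the zero initial state still
  retains weight `(1−1/n)ⁿ ≈ e⁻¹` in every slot — a uniform amplitude
  attenuation that cancels under any shape alignment (z-scoring) but means
  raw streaming amplitudes at `k = N` sit below their block counterparts.
  Callers wanting converged absolute amplitudes should discard the first
  `N` outputs.
* **Index phase.** The first sample lands on slot 0 and the stored index
  equals `(k−1) mod w` thereafter. Any consistent phase yields identical
  spectra (the power is a norm over the buffer), so one was fixed and
  documented.
* **Update order** within a sample: read old slot → write new slot →
  adjust power; all periods are updated before the spectrum is considered
  valid for that sample.
* **Drift.** The incremental power can go microscopically negative; it is
  clamped at zero before the square root (logged at debug level once per
  state), and `StreamState.resynchronize()` recomputes it exactly. Tests
  hold incremental and recomputed power to 1e-6 relative agreement over
  thousands of updates.
* Inputs are assumed pre-normalized; no running normalization is applied.
  Non-finite samples raise immediately, carrying the sample counter.

Each ring slot is mathematically the scalar recursion `y ← c1·y + c2·x`
applied to the phase-subsampled input series; the test suite asserts this
to exact float equality, which pins the implementation to the recursion
rather than to any numerically similar variant.

## Spectral parameters

DF/DA are the frequency and magnitude of the band's global maximum, with
ties broken toward the lowest frequency. No harmonic screening is applied:
the analysis grid is confined to 3–12 Hz, so the second harmonic of any
DF above 6 Hz falls outside the band, and for lower DFs the generator's
cycle-scale spectral content keeps the fundamental dominant (see below).
The lowest-frequency tie-break also resolves the exact-periodicity corner
case where a signal periodic at `w₀` produces equal spectral values at
integer divisors of `w₀`. MP and SP are the mean and population standard
deviation of the min–max-normalized profile; both are invariant under
positive affine transforms of the spectrum, so they compare across
estimators and scalings.

## DFT baseline

The comparison baseline recomputes a radix-2 FFT magnitude spectrum in
full at every sliding-window position (hop M ≥ 1, no incremental
shortcut), via `numpy.fft.rfft` with the `|X_k|/N` one-sided magnitude
convention. Only spectral shape is ever compared across estimators, so
this convention is internal and documented rather than matched to the
ensemble estimator's units.

## Synthetic electrograms

The generator emulates fractionated atrial electrograms: repeating
activation complexes at a programmable dominant frequency (3–12 Hz) with
cycle-length jitter, amplitude structure, broadband noise, optional
secondary periodicity and optional stepwise frequency changes. Signals
are standardized to zero mean, unit variance, exactly as the estimator
expects, and generation is bit-deterministic given the spec and seed.

Model choices, and why they were made:

* **Sample-clock quantization.** The nominal cycle length is
  `round(rate/df)` samples (`SyntheticSpec.effective_df` exposes the
  realized frequency, within half a grid step of the programmed one). A
  sub-sample-precise clock sustained over thousands of cycles would drift
  phase linearly across the analysis window and systematically smear the
  fundamental on any integer-period grid — an idealization with no
  physiologic counterpart.
* **Lattice-phase jitter.** Each event is displaced from its lattice
  position by an i.i.d. Gaussian offset (sd `jitter_frac · interval`,
  clipped to ±0.45 interval). Successive cycle lengths then vary with sd
  `√2·jitter_frac·interval`, but the long-run rate stays pinned to the
  programmed frequency. The alternative — accumulating i.i.d. interval
  perturbations — makes event times random-walk, so the realized mean
  rate itself drifts by ~`df·jitter/√n_cycles` and no estimator could
  recover the programmed frequency to within the fine local grid
  resolution.
* **Morphology.** Each activation complex is a burst of `deflections`
  (default 5) biphasic derivative-of-Gaussian deflections, each
  `complex_width_ms` (default 20 ms) wide, scattered once per record over
  `duty_frac` (default 0.65) of the cycle so the morphology repeats cycle
  to cycle, riding on a cycle-scale biphasic slow wave (`slow_wave_amp`,
  default 1.0, σ = interval/6). The slow wave matters: a signal whose
  activity is confined to less than half its cycle has exactly equal odd-
  and even-harmonic power, so its spectrum ties at DF and 2·DF and noise
  decides the argmax. Recorded electrogram spectra peak at the activation
  rate itself, and the cycle-scale component is what carries that
  first-harmonic content; with it, programmed frequencies are recovered
  reliably across the band.
* **Composition.** The event train (primary plus optional secondary) is
  scaled to unit variance before noise is added, so `noise_sd` is the
  noise-to-signal amplitude ratio; `event_amplitude = 0` produces
  noise-only records. Frequency schedules switch the lattice interval at
  stated sample indices without transition smoothing.

**Cohorts.** `generate_cohort` draws `n` records per labeled class from
templates. The defaults contrast a highly periodic class (jitter 0.03,
noise 0.35 — emulating the organized activity of sustained AF) with a
disorganized one (jitter 0.12, noise 0.9), and each record's DF is
perturbed by a zero-mean Gaussian (`df_spread_hz`, default 1 Hz, clipped
to [3.2, 11.8]) so classes have frequency distributions rather than
lines. On such cohorts the periodic class scores higher DA and lower MP —
the direction reported for persistent vs paroxysmal AF — but no clinical
magnitudes are claimed: the generator reproduces repetition structure,
jitter and noise, not conduction physiology, electrode geometry,
far-field artifacts, or the acquisition bandpass, so passing tests
demonstrate estimator correctness on signals with known ground truth, not
clinical performance.

## What the tests and the acceptance script measure

Problem sizes were chosen to exercise the published operating point while
keeping the default suite fast: the full 8192-sample window and 245-point
grid wherever a claim depends on them (baseline flatness, peak laws, DF
recovery over programmed frequencies {3.5, 5, 7, 9, 11.5} Hz × 20
replicates, offline-vs-streaming agreement over 50 records), brute-force
oracles on a 100 Hz grid (periods 33..8) where exact loop transcriptions
are the point, and a 16-channel × 4096-window × 8192-update run with one
spectrum per input sample as the multichannel experiment-shape check.

Offline-vs-streaming agreement at `k = N` is assessed after z-scoring both
spectra (the shape alignment under which offline and real-time traces are
overlapped): stationary jitter-free records agree to RMS < 0.1, while
realistic jittered/noisy records sit around 0.1–0.45 — the moving average
weights recent noise differently than the block average, and this spread
is consistent with agreement figures reported on clinical recordings.
Paired DA (after alignment), DF, MP and SP differences across cohorts are
centered on zero; DF agrees exactly on stationary records.

`scripts/acceptance.py --seed S --out results/acceptance.json` recomputes
all headline quantities from scratch at these sizes and writes them as
JSON; every random draw derives from the single seed.

## Known limitations

* The estimator contract requires normalized input; behavior on
  un-normalized signals is not specified (no scale covariance is
  promised).
* The halved offline path is approximate for odd segment counts, by one
  segment's contribution.
* Streaming amplitudes before one full window are systematically
  attenuated (warm-up); only shapes should be compared there.
* The generator's realism gaps are listed above; in particular it does
  not model the 30–500 Hz acquisition bandpass, and timing/throughput
  figures (µs per update, channel counts per sampling interval) are
  hardware- and interpreter-dependent, reported informationally by
  `nse benchmark` and never asserted.
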