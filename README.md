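# nse — real-time ensemble-average spectral estimation

`nse` implements a power spectral estimator designed for real-time
dominant-frequency analysis of periodic biomedical signals — its motivating
application is intracardiac bipolar electrograms recorded during atrial
fibrillation (AF), where the frequency of the largest spectral peak in the
3–12 Hz electrophysiologic band tracks the local atrial activation rate and
is used to guide catheter ablation.

## The estimator

For a zero-mean, unit-variance signal `x` of length `N`, the ensemble mean
at candidate period `w` (samples) averages the `n = ⌊N/w⌋` consecutive
length-`w` segments:

    e_w[j] = (1/n) Σ_i x[i·w + j],      j = 0..w-1

A periodic signal reinforces under this averaging while noise cancels like
`1/√n`. The spectral point at `w` is the `√n`-scaled RMS ensemble power,
computed from segment sums as

    S_w = (1/√N) · ‖ Σ_i x_{w,i} ‖₂

so that white noise has a flat baseline near 1 across all periods, and an
exactly `w₀`-periodic signal with `N = n·w₀` peaks at `S_{w₀} = √n`.
Scanning every integer period in the band (`f = rate/w`; at 977 Hz and
3–12 Hz: `w` = 325 down to 81, a 245-point spectrum) gives a mean local
resolution of ≈0.037 Hz — more than 3× finer than the 0.122 Hz bins of an
8192-point DFT.

The streaming form replaces the block average with an exponential moving
average held in a per-period ring buffer: each new input sample touches one
slot per period,

    e[ind] ← c1·e[ind] + c2·x,   c1 = (n-1)/n,  c2 = 1/n,

and the running power `P_w = Σ_j e[j]²` is maintained by a
difference-of-squares update, so a complete 245-point spectrum costs a few
multiply-accumulates per period per sample — fast enough to update every
channel of a multichannel recording at the 977 Hz sampling rate.

Four parameters summarize each spectrum: dominant amplitude **DA** and
frequency **DF** (the band's largest peak), and **MP**/**SP**, the mean and
standard deviation of the min–max-normalized spectral profile (low MP =
peaky, organized spectrum).

The package also ships a deliberately unoptimized sliding-window radix-2
DFT baseline for head-to-head comparison, and a synthetic
fractionated-electrogram generator (jittered trains of multi-deflection
activation complexes over a cycle-scale depolarization wave, plus noise,
optional secondary periodicity and frequency schedules) so the whole
pipeline can be exercised with known ground truth.

## Worked example

```sh
$ nse simulate --out cohort.txt --n-channels 3 --df 7.2 --jitter 0.04 \
      --noise 0.4 --seed 11
wrote 3 channels x 16384 samples to cohort.txt

$ nse offline --input cohort.txt --out spectra.tsv --out-params params.csv
channel 0: DA=8.960 DF=7.184 Hz MP=0.034 SP=0.087
channel 1: DA=8.716 DF=7.184 Hz MP=0.037 SP=0.087
channel 2: DA=8.921 DF=7.184 Hz MP=0.033 SP=0.087

$ nse compare --input cohort.txt --window 8192
channel 0: offline-vs-stream NRMS=0.0929
channel 1: offline-vs-stream NRMS=0.1041
channel 2: offline-vs-stream NRMS=0.0983
DFT resolution 0.1193 Hz over 75 band bins; period-grid mean resolution
0.0373 Hz over 245 points (ratio 3.20x)
```

The simulated records are programmed at 7.2 Hz; the generator realizes
that on the sample clock as a 136-sample cycle, i.e. 977/136 = 7.184 Hz,
and the estimator recovers exactly that frequency on all three channels.
The DA values (~8.9) are the peak heights in baseline units — far above
the white-noise baseline of 1 — and the low MP (~0.03) says the spectrum
is a narrow peak over a flat floor. `nse compare` streams each channel
per-sample and overlaps the k = 8192 streaming spectrum with the block
spectrum of the same samples: after shape alignment they differ by an RMS
of ~0.1 standard units. Other subcommands: `nse stream` (per-sample
streaming with parameter tables per emission) and `nse benchmark`
(informational wall-clock timing of streaming updates vs full DFT
recomputation).

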