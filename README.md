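# emgonset

Onset detection for **slowly activated muscle** from single-channel surface
EMG (sEMG).

Muscles dominated by slow-twitch fibres — the soleus during walking is the
canonical case — switch on gradually: the sEMG amplitude rises over hundreds
of milliseconds with no sharp edge, and classical onset detectors (fixed
amplitude thresholds, Teager–Kaiser energy, RMS windowing, wavelet energy)
trigger late or not at all.  This package implements a threshold-free
detector that tracks the **normalised Shannon entropy of the Hilbert
marginal spectrum** over sliding windows and marks the onset at the steepest
drop of the smoothed entropy trend, together with the four classical
baselines, ablation variants, a seeded synthetic slow-activation EMG
generator with known ground truth, and an evaluation harness.  It is aimed
at researchers in neuromuscular electrophysiology, gait analysis and
rehabilitation engineering who need reproducible onset estimates and a
controlled test bed for comparing detectors.

## Method

Given a band-passed signal window `x_k`, empirical mode decomposition (EMD)
writes it as intrinsic mode functions plus a residual,

```
x(t) = Σ_{i=1..M} c_i(t) + r_M(t),
```

each `c_i` obtained by iteratively subtracting the mean of the cubic-spline
envelopes through its extrema.  The Hilbert transform lifts each IMF to its
analytic signal `z_i(t) = c_i(t) + j·H{c_i}(t)`, giving the instantaneous
amplitude `A_i(t) = |z_i(t)|` and frequency `ω_i(t) = dφ_i/dt`.  Integrating
the resulting time–frequency distribution over time yields the marginal
spectrum `h(ω)` — the cumulative amplitude contribution of each frequency
bin.  Normalising `p_i = h_i / Σ_k h_k` and taking

```
MSE = −Σ_i p_i ln p_i / ln n      ∈ [0, 1]
```

gives a scale-free measure of spectral spread: ≈1 at rest (broadband noise),
lower once muscle activity concentrates spectral mass in the EMG band.  Over
windows of length `L` (128 ms, 50 % overlap) this produces an entropy
sequence `M = [MSE_1 … MSE_K]`, smoothed by a centred moving average into a
trend `T`.  The onset is the steepest drop of the trend:

```
Δ_k = T_{k+1} − T_k,   k* = argmin_k Δ_k,   t* = t0 + (k* − 1)·s,
```

with `s` the window step in seconds.  No amplitude threshold is involved
anywhere, so the detector is invariant to gain and electrode scaling.

## Worked example

```python
from emgonset import MseOnset, SynthSpec, ThresholdOnset, generate

sig, t_on = generate(SynthSpec(seed=2, snr_db=30.0, rise=0.5, t_on=2.0))
res = MseOnset(sig).fit()
print(res.summary())
```

prints

```
Onset detection results
===============================================
method                                      mse
n samples                                  7500
sampling rate (Hz)                         1500
duration (s)                             4.9993
onset detected                             True
k* (1-based window)                          32
t* (s)                                   1.9840
-----------------------------------------------
filter.low_hz                              20.0
filter.high_hz                            450.0
window.length_ms                          128.0
window.overlap                              0.5
detector.smooth_len                           5
detector.reject_delta                       0.0
min trend slope                        -0.01936
===============================================
```

The generator placed the true ramp start at `t_on = 2.0 s`; the entropy
detector reports `t* = 1.984 s` (window 32, one 64 ms step early), while the
30 %-of-maximum amplitude threshold baseline on the same record fires at
`2.257 s` — a quarter second later, because the amplitude is still climbing
when the spectral redistribution is already visible.  `res.diagnostics["M"]`
and `res.diagnostics["T"]` hold the raw and smoothed entropy sequences and
`res.plot()` draws the signal with the trend and the detected onset.

The same pipeline is available from the shell:

```
emg-onset simulate --seed 2 --rise-ms 500 --out sig.csv
emg-onset detect --input sig.csv --method mse
emg-onset benchmark --n 20 --seed0 1000 --out bench/
```

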