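# Methods

This note documents the models, parameter choices and numerical conventions
behind `emgonset`, and what the synthetic benchmark can and cannot show.

## Signal model and pipeline

The package assumes a uniformly sampled single-channel sEMG record that
begins at rest and transitions once into activity.  The detection pipeline
is:

1. **Band-pass 20–450 Hz** — a 5th-order Butterworth prototype applied
   forward and backward (`sosfiltfilt`), so the magnitude response is that
   of a 10th-order filter and the phase response is identically zero;
   zero-phase filtering matters because the entire point of the exercise is
   event *timing*.  Edges are handled by odd reflection padding of about
   three periods of the 20 Hz corner (225 samples at 1500 Hz); signals
   shorter than that are rejected rather than filtered unstably.
2. **Sliding windows** — length 128 ms, 50 % overlap (192/96 samples at
   1500 Hz).  Window `k` (1-based) starts at `t0 + (k−1)·s`; trailing
   samples that do not fill a window are dropped.  A sensitivity scan of
   window lengths in the 96–192 ms range is available through
   `window.length_ms`.
3. **Per-window z-scoring** (population 1/N variance).  Each window is
   normalised independently *after* extraction; overlapping samples
   therefore receive different scalings in different windows, which is
   irrelevant downstream because the entropy is scale-invariant anyway.  A
   window whose standard deviation is below `1e−12 · max(1, max|w|)` maps
   to zeros (scale-aware degenerate guard).
4. **EMD per window** — each window is decomposed independently (the
   per-window pipeline; the alternative of windowing a single global
   decomposition is deliberately not the default, though the
   `mse-nowindow` ablation provides a global-decomposition variant).  At
   most 6 modes are extracted.
5. **Hilbert marginal spectrum** — 45 equal-width bins over 0–450 Hz
   (10 Hz resolution, matching the pass band); amplitude-weighted by
   default (`hht.power_spectrum = true` switches to squared amplitude for
   sensitivity studies).
6. **Entropy, trend, slope** — normalised Shannon entropy per window,
   5-window centred moving average, first difference, earliest argmin.

## EMD conventions

The sifting stop rule is nowhere near standardised; the choices here are
classical and config-exposed:

- **Cauchy criterion** `SD = Σ(h_prev − h_new)² / Σ h_prev² < 0.2`
  (`emd.sd_tol`), at most 100 passes per mode (`emd.max_sift_iters`).  A
  candidate is only accepted once it additionally satisfies both defining
  IMF conditions: |#extrema − #zero-crossings| ≤ 1, and envelope-mean
  magnitude ≤ 0.1 × RMS over the 10 %-trimmed interior.  Without the extra
  conditions roughly a third of noise-input modes accepted by the bare SD
  rule fail the count check.
- **Envelopes** — natural cubic splines through the interior extrema, with
  the two nearest extrema mirrored about each end to damp edge swings;
  linear interpolation when fewer than four knots exist on a side.
- **Extrema** — strict sign changes of the first difference; a flat
  plateau at a turning point counts once, at its midpoint (deterministic
  tie handling).
- **Completeness is structural**: the residual is maintained as the running
  remainder, so IMFs + residual reconstruct the input to round-off for any
  stop rule.
- Decomposition stops when the residual is monotonic or has fewer than two
  maxima or minima.

Instantaneous frequency is the central-difference derivative of the
unwrapped analytic phase.  The first and last 5 % of samples
(`hht.edge_exclude`) and any sample with `f ≤ 0` or `f ≥ fs/2` are excluded
from spectrum accumulation via a validity mask — these are Hilbert/spline
end artefacts, not physical content, and clamping them would bias the low
bins.  Frequencies above `f_max` accumulate into the last bin.

## Detector variants and rejection rules

- `mse` — the full pipeline above.  Always detects by construction
  (an argmin always exists); an optional rejection rule declares "no onset"
  when the steepest drop is shallower than `detector.reject_delta`
  (default 0 = off, 0.02 when enabled by the benchmark).
- `energy-slope` — replaces the entropy with per-window mean squared
  amplitude (max-normalised, and *not* z-scored, which would erase the
  feature).  Because activation raises energy, the decision statistic is
  the steepest **rise** of the smoothed energy trend; a literal
  steepest-drop rule on energy would point away from the onset.
- `mse-only` — no slope analysis: the onset is the global minimum of the
  entropy trend.  Its rejection rule needs a depth, not a slope:
  "no onset" when `median(T) − min(T) ≤ detector.reject_depth`
  (default 0.1).  The value comes from a noise-floor argument: on
  stationary records the smoothed trend has spread ≈ 0.007 (per-window
  entropy noise ≈ 0.016 averaged over 5 windows), so the median-to-minimum
  gap over ~75 windows stays below ~0.05, while a genuine rest-to-active
  entropy transition at these settings is of order 0.1.
- `mse-nowindow` — the "no sliding window" variant: one EMD of the whole
  record, then the entropy of the *cumulative* marginal spectrum evaluated
  every `s` samples, differenced and scanned for the steepest drop.  This
  is one defensible reading of removing the window mechanism (a global
  decomposition admits several); it is documented as this package's
  construction, not as a canonical procedure.

Baselines: 30 %-of-maximum crossing on a rectified + 10 Hz zero-phase
linear envelope; Teager–Kaiser energy smoothed over 50 ms against
`μ_b + 8σ_b` of the opening 300 ms with a 2×50 ms persistence requirement;
per-window RMS and DWT detail energy (db4, 4 levels) against `μ_b + 3σ_b`
of the opening windows with 2-window persistence.  All baselines assume the
opening `baseline.baseline_ms` of the record is quiescent.  Note that with
the default 300 ms baseline the `μ_b + 3σ_b` level is estimated from only
~5 windows and is itself noisy; occasional false alarms on stationary input
are expected, and vanish when the baseline period is extended.

The slope rule is fixed to the steepest *drop* for the entropy modes
(activation concentrates the spectrum, lowering entropy); no sign switch is
exposed.

## Synthetic generator

`synth.generate` emulates the target phenomenon — a quiescent baseline
followed by a gradual activation with a *known* onset:

    x(t) = b(t) + e(t)·a(t)

- `b`: Gaussian noise band-limited to 20–450 Hz, σ = 1 — a flat in-band
  measurement baseline.
- `a`: Gaussian noise shaped by the Stulen–De Luca sEMG power spectrum
  (corner frequencies 60/120 Hz) inside the band, scaled to
  `σ_a = 10^(snr_db/20)`.  The concentrated activation spectrum against the
  flat baseline reproduces the spectral redistribution that the entropy
  detector keys on; a generator whose activation shared the baseline's
  spectral shape would, by construction, present no spectral transition at
  all and could not exercise the method.
- `e`: smoothstep `3u² − 2u³` over `[t_on, t_on + rise]` — continuous with
  continuous slope, zero before, one after.

Ground truth is the **ramp start** `t_on`, the earliest physiologic
activity.  `snr_db=None` produces a pure-baseline negative case.  Every
record is reproducible from its integer seed, and
`make_benchmark_set(n, …)` builds a half-positive/half-negative labelled
set with rises drawn uniformly from a range.

What the generator does **not** model: motor-unit action-potential
structure, gait-cycle periodicity, movement artefact, mains interference,
electrode lift-off, or multi-muscle crosstalk.  Passing synthetic tests
demonstrates the pipeline's correctness and its behaviour under controlled
spectral transitions; it does not certify performance on clinical
recordings.

## Evaluation conventions

A detection within `eval.tolerance_s` (0.2 s) of the truth on a positive
record is a true positive; a miss or an out-of-tolerance detection is a
false negative; any detection on a negative record is a false positive.
Onset RMSE is computed over true positives only.  Detection advance of
method X is `mean(t_ref − t_X)` over records where both X and the reference
(the threshold baseline) detect, so the reference's own advance is 0 by
construction.  Rates with empty denominators are reported as absent, never
as 0.  The benchmark runner switches rejection rules on (otherwise
negatives cannot be scored) and computes the per-window entropy trend once
per signal, shared between `mse` and `mse-only`.

## Known limitations

- **Localisation precision scales with SNR and rise duration.**  The
  rest-to-active entropy contrast at these settings is bounded by the
  spectra themselves: ≈ 0.93 for the flat in-band baseline vs ≈ 0.83 for
  the De Luca-shaped activation over 45 bins — about 0.10 end to end.
  Spread over a 0.5–2 s rise, the true trend slope per 64 ms step is
  0.003–0.013, which at 10 dB SNR is the same order as the smoothed-trend
  estimation noise (σ_Δ ≈ 0.005 from 192-sample windows).  The steepest
  measured drop is then frequently a noise excursion, and even when the
  genuine drop wins it sits where activation power rivals baseline power —
  a substantial fraction of the rise *after* the ramp start.  At 30 dB SNR
  the same pipeline localises the ramp start to within one window step
  (see the worked example and the high-SNR unit tests).  Claims of
  ramp-start accuracy at low SNR should therefore be treated with caution
  for *any* detector of this family.
- The method is offline: the trend and its differences are computed over
  the whole record.  No incremental update is provided.
- Per-window EMD on 192 samples cannot resolve content below ~15 Hz and
  carries non-trivial edge effects despite envelope mirroring and the
  5 % mask.
- The benchmark problem size (50 records of 5 s at 1500 Hz) was chosen as
  a desk-scale experiment that a laptop reruns in under a minute; all of
  its parameters are config-exposed for larger studies.
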