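# Methods

## Measurement model

Both assessments are treated as observations of a latent point process:
tap-cycle completions or syllable utterances at times `t_1 < … < t_n`.
All features derive from these event times alone:

* **mean frequency** `(n − 1)/(t_n − t_1)` — computed over the
  first-to-last-event span rather than the nominal recording length, so a
  late start or early stop does not bias the rate downward;
* **COV of frequency** `SD(1/d)/mean(1/d)` with `d` the inter-event
  intervals, sample SD (ddof = 1). The name says "coefficient of
  variance"; a plain variance of frequency would carry units of Hz², so
  the standard dimensionless CV reading is implemented;
* **IIV** `Var(d)` (unbiased), in s²: interval-domain rhythm variability;
* **DoS**: ordinary-least-squares slope of instantaneous frequency `1/d_k`
  against cycle midpoints `(t_k + t_{k+1})/2`, in Hz/s; negative values
  mean slowing. An alternative estimator (difference of half-means divided
  by the half-midpoint spacing) is available via `dos_method =
  "half_difference"`.

Fewer than 3 events leave every feature undefined (NaN with a
`defined=False` flag); undefined values propagate through agreement
analysis by pairwise deletion, with the per-cell `n` reported.

## Tapping pipeline

1. **Aperture**: Euclidean distance between index fingertip and thumb tip
   per frame (2D pixels for video; 3D device units for sensors). The
   distance is translation-invariant and scale-equivariant, so after
   min–max normalization the features are invariant to camera distance
   and coordinate origin.
2. **Normalization**: min–max to [0, 1]; a constant curve means no
   tapping and raises a degenerate-signal error.
3. **Segmentation**: peaks of the (optionally 3-point-smoothed) normalized
   aperture with prominence ≥ 0.10 and pairwise separation ≥ 0.125 s
   (capping detection at 8 Hz, above physiological tapping rates). Peak
   times are refined by a 3-point parabolic fit: at 30 fps the frame
   quantum is 33 ms, which alone would contribute COV ≈ 0.05 at 3.5 Hz;
   sub-frame interpolation removes most of that artifact. Separation is
   enforced in time (strongest-peak-first), so irregular timestamps from
   dropped frames are handled exactly. A flat curve yields zero events,
   not an error.

Timestamps default to frame/fps (0-based) when a landmark file has no
explicit times. Gaps from dropped frames are analyzed as-is (no
interpolation); peak prominence, not sample spacing, drives detection.

## Speech pipeline

All audio is resampled to 22 050 Hz so hop geometry is uniform across
heterogeneous phone recordings.

1. **Spectral gating**: STFT with a 2048-sample window at 44.1/48 kHz
   equivalent (power-of-two scaled at other rates), 75% overlap. The
   per-bin noise profile (mean, SD of magnitude) comes from the
   lowest-energy 10% of frames; magnitude below `mean + 1.5·SD` is reduced
   by a spectral-subtraction mask (floor 0.05) smoothed over 3 frames ×
   3 bins. Digital silence passes through unchanged.
2. **Onset envelope**: half-wave-rectified first difference of log
   mel-band energies (40 bands, ~25 ms window, 10 ms hop), summed over
   bands and min–max normalized. The log is floored 40 dB below the
   spectrogram's global maximum: a gated noise floor then contributes no
   flux, which is what makes denoising *help* detection (log-domain flux
   is otherwise level-invariant, so attenuating noise would change
   nothing).
3. **Syllable picking**: local maxima above
   `1.5 × (1 s moving mean + 0.05)`, separated by ≥ 0.1 s (≤ 10
   syllables/s). "pa", "ta" and "ka" are not distinguished — every
   detected onset counts as one syllable, and syllable "duration" for IIV
   is the inter-onset interval (onsets, not segment boundaries, are what
   the detector produces).

A silent recording is reported as 0 events with undefined features rather
than an error: silence is an empirical outcome of a valid recording
attempt, unlike a constant displacement curve, which indicates a broken
keypoint stream.

## Agreement statistics

Differences are oriented smartphone − gold. The default test is the
classical paired t test (`t = mean(d)/(SD(d)/√n)`, df = n − 1, two-sided);
a Welch two-sample unequal-variance mode (Welch–Satterthwaite df) is
selectable because method-comparison reports sometimes use either reading
— both are labeled explicitly in outputs and neither is privileged.
Zero-variance differences are degenerate: t = 0 and p = 1 when the mean
difference is zero (identical devices), ±∞/0 otherwise, always flagged.

Bland–Altman limits of agreement use a fixed 1.96 multiplier on the
unbiased SD of differences (configurable; the small-sample t quantile is
not used). Tolerance accounting (`pct_within_tolerance`) is boundary
inclusive: |d| = tol counts as within.

## Synthetic data

The generator states one latent schedule and observes it twice, mimicking
a validation study's paired design:

* inter-event intervals are log-normal with the requested CV around
  `1/f(t)`, `f(t) = base + slope·t` — log-normal keeps durations positive
  at high jitter;
* **tapping**: a raised-cosine aperture with full opening at each latent
  event, sampled at 30 fps (2D pixels, fixed thumb, additive Gaussian
  keypoint noise, optional independently dropped frames) and at 60 Hz
  (3D, two sensors, smaller noise; sensors never drop frames). Placing
  aperture peaks *at* events rather than mid-interval matters: mid-interval
  peaks would average adjacent intervals and shrink recovered COV/IIV by
  √2, breaking parameter-recovery consistency;
* **speech**: each syllable is a band-limited noise burst (300–3000 Hz)
  with a sharp attack and damped decay; background Gaussian noise is
  scaled from the clean-signal RMS to the requested SNR. The phone channel
  gets a 5 dB SNR penalty and a 300 Hz–8 kHz band-pass coloration (a
  typical phone-microphone response, asserted rather than estimated);
  a zero signal amplitude is the literal silence limit;
* defaults reflect the validation cohort: 10 s recordings, tapping rates
  ~N(2.55, 0.67) Hz, syllable rates ~N(2.96, 0.47) Hz, jitter CV uniform
  in [0.05, 0.15], cohort sizes 29/24/19 (tap) and 29/29 (talk).

What the generator does **not** emulate: landmark-detector failure modes
(occlusion, identity switches), sensor drift or electromagnetic
interference, reverberation, non-stationary background noise, or
articulatory acoustics (bursts are noise, not speech). A green recovery
test therefore establishes correctness of the signal-processing chain
under the stated noise model, not robustness to real-world capture
artifacts.

## Numerical choices

* Sample statistics use ddof = 1 throughout (COV, IIV, SD of differences).
* Min–max degeneracy threshold: range ≤ 1e-12 (relative) is constant.
* Peak-time parabolic refinement is clamped to the neighboring frame
  interval; non-concave fits fall back to the frame time.
* t-test p-values come from the t distribution survival function; the
  Welch df is kept fractional.
* The 3-point moving average before peak picking is on by default and
  config-removable; it suppresses single-frame landmark jitter at a peak
  time cost well below the frame quantum.

## Limitations

* The exact feature formulas of the original instrument's supplementary
  material were not available; COV/IIV/DoS follow the standard readings
  documented above and may differ in detail.
* Real cohort data are not redistributable, so agreement p-values from
  published tables are not reproduction targets; the agreement machinery
  is validated against closed forms and reference implementations instead.
* Onset detection is tuned for isolated syllable bursts at ≥ 2 Hz; slow
  connected speech or strongly reverberant rooms will need different
  thresholds.
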