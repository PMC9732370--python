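# Methods

This note documents the models and procedures implemented in `tfdenoise`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic testbed does and does not show.

## The time-frequency denoising pipeline

A single trial x(t) (one channel, typically 1 s at 250 Hz after
preprocessing) is mapped to a complex time-frequency matrix X(t, f) by a
short-time Fourier transform, the magnitude image |X| is decomposed by
bidimensional empirical mode decomposition (BEMD) into sub-images of
decreasing spatial frequency, each sub-image (including the residue) is
filtered by non-local means (NLM), the filtered sub-images are summed back
into a magnitude image, negative values are clipped to zero, the original
phase is reattached, and the inverse STFT returns a trial of the original
length.

The underlying assumption is that the ERP's energy density occupies smooth,
self-similar low-frequency structure in the time-frequency image, while
broadband noise (most visibly EMG above 30 Hz) lands in the fast-varying
sub-images where NLM's patch averaging suppresses it.

### STFT (module `tfr`)

Analysis and synthesis are delegated to `scipy.signal.ShortTimeFFT`, which
inverts via the canonical dual window and is exact to rounding error
whenever the window/hop pair is invertible.  Non-invertible configurations
are rejected when the config object is constructed.  Frame k is centred at
sample k·hop; the signal is implicitly zero-extended at the edges so every
sample carries synthesis weight.

Defaults: Hann window of 64 samples (256 ms at 250 Hz), hop 16 (75 %
overlap), one-sided 64-point FFT.  This gives ~3.9 Hz frequency resolution
— the 2–30 Hz ERP band occupies about 8 informative rows — and a 33 × ~19
image for a 1-s trial, small enough for full-image NLM.  Window type,
length, hop and FFT length are all config keys; results depend on them, and
every CLI output records the resolved configuration in a JSON sidecar.

### BEMD (module `bemd`)

Each mode is extracted by 2-D sifting: strict local maxima/minima over
8-neighbourhoods (mirror boundary; plateaus produce no extremum, which
keeps tie handling deterministic), envelope surfaces through each extrema
set, subtraction of the envelope mean, repeated until the normalised
squared change between consecutive sifts,
SD = Σ (h_{p−1} − h_p)² / h_{p−1}², drops below 0.25, or 10 sifts have
run.  Grid cells with |h_{p−1}| < 1e−12 are excluded from the SD sum (the
criterion divides by h² and is undefined at zeros).  The envelope mean is
recomputed from the current iterate at every sift — the standard sifting
recursion.  Each accepted BIMF is literally subtracted from the running
residue, so Σ BIMFs + residue equals the input exactly, and decomposition
of −M yields exactly the negated modes of M.

Envelope surfaces over scattered extrema: with ≥ 16 support points the
extrema set is half-sample-mirrored across all four borders (standard
boundary mitigation — otherwise envelopes dive outside the extrema hull)
and fitted with `CloughTocher2DInterpolator`, a C1 piecewise-cubic
scattered-data interpolant that passes exactly through the support values;
with fewer points, or when the point configuration is degenerate
(collinear), the fit falls back to linear interpolation with
nearest-neighbour fill outside the hull.  A smoothing bivariate spline was
rejected because it does not interpolate its support points.

Defaults: 5 BIMFs (the fifth sub-image of a 1-s ERP trial is already
residue-like trend), SD threshold 0.25, at most 10 sifts per mode (bounds
runtime; sift counts are reported in the result).

### NLM (module `nlm`)

Pixel estimates are convex combinations over the search region (the whole
image by default, matching the small TFR images):
NL F(i) = Σⱼ w(i,j) F(j), w(i,j) = exp(−d(i,j)/h²)/c(i), where d(i,j) is
the Gaussian-weighted (std `a` = 1 px, normalised kernel) squared distance
between the 5×5 patches centred on i and j, with mirror padding at the
borders.  Pixel i participates in its own average with its natural weight
(d = 0); no centre-weight substitution tricks.

The attenuation coefficient h is the only sensitive parameter.  By default
it is tied to a robust per-image noise scale, h = 0.6·σ̂ with
σ̂ = median(|∇F|)/0.6745, which makes the filter scale-free across BIMFs
whose amplitudes differ by orders of magnitude; a fixed h can be set in the
config.  The vectorised implementation (pairwise patch distances via
`scipy.spatial.distance.cdist`) is held to a literal per-pixel transcription
of the defining formulas within 1e−10 in the test suite.

### Recombination and phase

Filtered sub-images are summed (`recombine="sum"`).  Summation, not
averaging, is what makes the chain with the NLM stage disabled collapse to
istft(stft(x)) = x — the plumbing adds no distortion — and is consistent
with the completeness identity; a `mean` mode (which scales the
reconstruction by 1/(N+1)) is provided for comparison with the literal
"superimpose and average" reading.  The residue is filtered like the BIMFs.
The magnitude is filtered and the original phase reused
(`filter_target="magnitude"`); a `real_imag` mode filtering both Cartesian
planes independently is available for comparison.

## Baselines (module `baselines`)

**EMD/EEMD.**  1-D sifting with natural-cubic-spline envelopes through
strict extrema (up to two extrema mirrored beyond each end), Cauchy-type SD
stop (threshold 0.2, at most 12 sifts), monotone-residue termination;
completeness is exact by construction.  EEMD averages the IMFs of 100
noise-perturbed decompositions (white noise, SD 0.2 × signal SD, one seeded
generator for the whole ensemble), index-aligned with zero padding for
shorter decompositions.  Ensemble means, not sums, are used.  The spline
evaluator is a lean tridiagonal solve because the ensemble calls it tens of
thousands of times per trial.

**FastICA.**  Centring, eigenvalue whitening (with an explicit rank check),
symmetric fixed-point iteration with the log-cosh contrast and symmetric
decorrelation, seeded initial rotation, tolerance on the rotation change.
Non-convergence raises an error carrying iteration diagnostics.  IMF
channels are only quasi-independent, so the fixed point can stall at a
small residual delta; the EEMD-ICA denoiser therefore retries a few seeds
and then accepts the near-converged iterate with a warning (scikit-learn
behaves the same way, and is used as an independent cross-check in the
tests, never as the implementation).

**EEMD-ICA** unmixes the [IMFs; residue] matrix and keeps the source with
the highest |Pearson correlation| to the supplied reference, sign-aligned
and least-squares rescaled to the trial (correlation is scale-invariant;
rescaling only aids plotting).  Note the method's own selection step
consumes the reference — the evaluation target — as prescribed; this leak
is documented rather than "fixed".

**EEMD-CCA** computes the first canonical variate between the IMF matrix
and its one-sample delay.  The canonical system is solved by SVD of the
whitened cross-covariance with a ridge of 1e−8 × trace on each covariance
block; the variate is computed on the overlapping T−1 columns and
front-padded with its first value to restore the trial length.

**Wavelet thresholding**: db4, level ⌊log₂N⌋−2 (capped at the wavelet's
maximum useful level, minimum 1), universal threshold √(2 ln N)·σ̂ with
σ̂ = median(|d₁|)/0.6745, soft shrinkage of all detail levels,
approximation untouched.

## Synthetic testbed (module `synthetic`)

Each 1-s, 250 Hz trial is the sum of Gaussian-windowed components — an
N1-like negativity (peak 0.15 s, width 30 ms, 5 µV) and a P3-like
positivity (peak 0.35 s, width 60 ms, 10 µV) — with per-trial latency
jitter (SD 20 ms, shared across components) and amplitude jitter (CV 0.15),
plus structured noise: pink 1/f background, a 10 Hz alpha sinusoid with
random phase, and 30–120 Hz band-passed white noise standing in for EMG,
mixed at equal unit amplitudes.  The noise of every trial is rescaled so
the realised SNR, 10·log₁₀(‖clean‖²/‖noise‖²), hits the −5 dB default
exactly; a 56-trial block mirrors a typical target-detection block.  The
jitter magnitudes and component shapes are choices of plausible ERP
morphology, not fits to any dataset.

What the generator does **not** emulate: eye blinks and other transients,
non-stationary noise levels, electrode geometry or volume conduction,
overlapping stimulus responses at fast presentation rates.  Passing
benchmarks on this testbed therefore show that the pipeline preserves a
jittered low-frequency template against stationary structured noise better
than the baselines — not that it ranks the same way on any particular real
recording.

## Evaluation (module `evaluate`)

Each method denoises each trial; the Pearson correlation with the
across-trial mean reference is recorded per trial, raw trials entering as
the "original" column.  The conventional reference includes the trial under
test, which biases all correlations slightly upward;
`reference_policy="loo"` provides the leave-one-out alternative.  Method
pairs are compared by a two-sided paired t-test on Fisher z-transformed
correlations (correlations are bounded; the z-transform normalises);
a Wilcoxon signed-rank variant is available.  Identical paired samples are
reported as p = 1.

## Problem sizes and tolerances

The shipped tests and the acceptance script run at desk scale: 56-trial
blocks, 33 × ~19 time-frequency images, 100-member EEMD ensembles, 16×16
NLM oracle images, 32×32 BEMD completeness matrices.  Key numerical
contracts: STFT round trip < 1e−8 (measured ~1e−15), BEMD completeness
< 1e−8 (exact by construction), NLM vs literal definition < 1e−10,
pipeline identity with NLM disabled < 1e−6.  All randomness flows through
explicit integer seeds; the main denoising path contains no randomness at
all.

## Known limitations

* BEMD on scattered extrema is not a uniquely defined operation; results
  depend on the interpolant and boundary scheme (documented above).
* Full-image NLM is O(P²) in the pixel count — fine for STFT images of
  1-s trials, expensive for long recordings or high-resolution transforms.
* EEMD-ICA's component selection consumes the evaluation reference, so its
  benchmark scores are optimistic by construction.
* The wavelet baseline stands in for MATLAB's default threshold estimator
  with the standard universal-threshold recipe; exact numerical parity with
  MATLAB outputs is not a goal.
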