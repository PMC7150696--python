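# Methods

This note records the models, defaults and numerical choices behind
`fastscan`, and what the synthetic experiments do and do not establish.

## Acquisition model

Frames are grayscale rasters whose fast-scan direction is horizontal; the
video-rate defaults are 0.04 s/frame with an active (pixel-collecting)
fraction of 0.8, against a slow-scan reference fraction of 0.9. Frame `t` of
a simulated stack is

    noise( gain_t · H * ( shift_t(truth) ) + offset_t )

where `H*` is the detector's scan-direction low-pass applied per row in the
frequency domain, `shift_t` a translational drift (optionally varying across
the field), `gain/offset` a slow charging-like brightness drift, and the
noise a scaled-Poisson shot stage followed by additive Gaussian readout.
Generation-time shifts may be sub-pixel and use periodic cubic B-spline
resampling (evaluated as four separable taps per axis, identical to
`scipy.ndimage.map_coordinates` on the same spline coefficients). The
restoration path, by contrast, never interpolates; only the simulator is
allowed to create new pixel values, because it plays the role of the
physical specimen.

### Synthetic specimen texture

The ground truth is a sum of Gaussian-smoothed white-noise fields, normalized
to [0, 1]. Two presets:

- **default** — smoothing scales (σ, weight) = (12, 0.6), (5, 0.4),
  (1.1, 0.45), (0, 0.07): smooth relief plus granularity concentrated near
  8-px wavelengths, with a small unsmoothed floor so ≈2% of the spectral
  power lies above half-Nyquist. This is the generic "textured specimen".
- **granular** — (16, 0.35), (6, 0.35), (2, 0.5), (0, 0.6): strong
  pixel-scale grain, emulating the appearance of an inverse-filtered
  high-magnification frame whose structural details span one or a few
  pixels.

The distinction matters because two requirements pull the spectrum in
opposite directions. Exact integer-shift recovery at amplitude SNR 0.25
needs a sharp correlation peak, i.e. a large fraction of power at high
spatial frequency (the granular preset; with the default texture the peak is
too broad and the argmax wanders). Conversely, the flatness of the *aligned*
integration curve is limited by sub-pixel rounding jitter: integer alignment
of drift δ per frame leaves residuals in (−0.5, 0.5] px whose phase average
attenuates the high-pass band; the attenuation grows as (f·structure)², so a
spectrum dominated by near-cutoff (≈8 px) structure loses ~4% while a
grain-dominated one loses ~13%. Registration experiments therefore use the
granular preset and curve experiments the default — each preset emulates the
image content actually present at that stage of the real pipeline
(registration operates on restored, re-whitened frames).

Noise is calibrated by `NoiseModel.for_target_snr`: amplitude SNR is defined
as std(signal)/std(noise), so σ = std(truth)/SNR.

## Transfer measurement and inverse filtering

`measure_detector_response` averages, over frames, the per-frame normalized
horizontal and vertical spectral line profiles (256 lines each by default),
divides the horizontal by the vertical to cancel the noise floor, and clips
to [0, 1]. Profiles are folded to positive frequencies, exclude DC, and are
normalized so the mean of the lowest 5% of frequencies is 1. A vertical
profile deviating from flat by more than 0.15 triggers a warning (specimen
structure in supposedly defocused frames). The estimate is unbiased as a
ratio of same-statistics averages; at 100 frames of 480×640 its RMS error
against a known transfer is ≈0.3%.

The inverse filter is the plain capped reciprocal of the (moving-average
smoothed, window 9 bins) measured profile, renormalized to gain 1 at the
lowest frequency and clipped to [1, gain_cap] (default cap 10). No Wiener
regularization: noise control is the job of frame integration, and a plain
reciprocal leaves the signal spectrum exactly flat below the cap-active
frequency. Filtering is linear and shift-invariant along rows, so applying
it per frame or once after integration gives the same result; per frame is
the default. Note that after renormalization capped bins sit marginally
below the nominal cap, so "cap-active" should be detected via H < 1/cap, not
by comparing gains to the cap.

The sharpness high-pass is isotropic with a Gaussian transition,
T(f) = 1 − exp(−ln2·(f·s)²), half-amplitude at wavelength s (`structure_size`,
default 8 px at 640×480). T depends only on f·s, which yields the scaling
rule: double the pixel count, double the parameter. The exact shape is not
critical, but comparisons at different `structure_size` only agree closely
when the measured structure is fine relative to both cutoffs; for images
with substantial content between the two passbands the absolute score
differs (the *relative* ordering used for drift diagnosis and ROI selection
is unaffected).

## Covariance SNR

Population (1/N) moments over the evaluation region give Cov and Var;
S_σ = √Cov, N_σ = √(√(Var₁Var₂) − Cov). The amplitude ratio S_σ/N_σ is the
reported SNR (it is what grows as √n under integration); its square, the
power ratio Cov/(√(Var₁Var₂) − Cov), is exposed alongside. Negative
covariance (possible on noise-only regions) clamps S_σ to 0 with a flag
rather than erroring; a vanishing noise estimate flags infinite SNR. The
blanking correction multiplies an SNR by √(reference_fraction /
active_fraction), normalizing scan modes to equal effective
signal-collection time.

## Registration

ZNCC is computed exactly for every valid placement (FFT cross-correlation
plus integral-image window statistics), values clipped to [−1, 1];
zero-variance windows score 0 and a zero-variance template is an error. The
pyramid decimates by 2 with 2×2 box averaging, runs a full search at the
coarsest level (default depth keeps the coarsest template side ≥ 32 px,
hard floor 8 px) and refines within ±2 px per finer level; ties break toward
the smallest |dy|+|dx|, then dy, then dx. For a 256×256 template in a
640×480 frame the 3-level pyramid evaluates <7% of the full search's
placements.

`align_stack` matches an ROI template per frame inside the ROI dilated by
`search_margin` (default 64 px; the ROI plus margin must fit in the frame).
The default reference is a running mean of already-aligned patches, seeded
by frame 0 — template SNR grows with every accepted frame, which is what
keeps matching reliable at single-frame SNR 0.25. Frames whose peak score
falls below 5/√(ROI pixels) — five times the correlation noise floor — are
flagged, excluded from integration and from the running mean, but still
reported with their best-guess shift. The threshold is size-adaptive because
the genuine peak at SNR 0.25 is ≈0.06 (far above the floor of any usefully
sized ROI) while a 16×16 surface has a noise *ceiling* of ≈0.3; no fixed
absolute value serves both.

## Integration and the optimal frame count

Averaging uses pure integer index offsets with a per-pixel contribution
count; border pixels shifted out of every frame stay invalid (count 0). The
integration curve splits the stack into even/odd-index halves (independent
noise, identical view), aligns each half independently, integrates both to
each checkpoint n (perfect squares up to 256 by default, uniform in √n) and
records S_σ(HPF) of the pair on a fixed central region that excludes the
widest shift margin. `estimate_optimal_n` returns the largest n whose score
is within `tolerance_fraction` (default 0.05) of the curve maximum; the
total integration then uses 2n frames.

## Montage under spatially varying drift

One integration per anchor ROI; blend weights are a nearest-anchor
partition (by distance to ROI center) with a linear feather: raw weight
clip(1 − (dᵢ − d_min)/(2·feather_width), 0, 1), zeroed where a partial has
no data, then normalized. A pixel whose nearby partials are all invalid
falls back to the nearest valid anchor; pixels valid nowhere stay invalid.
The ramp slope bounds the output step across a seam between two partials at
(max − min)/feather_width per pixel (default feather 64 px), and blending is
a convex per-pixel combination — no resampling, preserving the
no-interpolation contract end to end. ROI candidates are ranked by aligning
both halves with each candidate and scoring S_σ(HPF) restricted to the
evaluation region; under spatially varying drift the local anchor wins and a
candidate spanning mixed drift scores lower.

## Experiment sizes and seeds

The reference experiments (`fastscan.experiments`) use: 480×640 frames for
estimator, transfer and registration runs; 512 frames of 384×512 for the
integration-curve contrast (drift 0.1 px/frame along the scan, single-frame
SNR 1.0 so the per-checkpoint estimator noise, <1%, is far below the 5%
band under test); 120 frames of 256×512 with ±6 px opposing edge drift for
the montage contrast. All randomness derives from a single integer seed via
a fixed affine map, and identical seeds give bit-identical stacks.

## Limitations

- Drift is translational only (globally or linearly interpolated across
  columns); rotation, scale and non-rigid distortion are out of scope, as is
  physically modeled charging (the brightness surrogate is a monotone
  exponential) and depth-of-focus blur.
- The synthetic specimen is stationary Gaussian texture; real micrographs
  have nonstationary structure, so passing tests demonstrate correctness of
  the estimators and the alignment/integration logic, not performance
  guarantees on any particular specimen.
- Integer-only alignment trades a quantifiable few percent of near-Nyquist
  contrast (rounding jitter) for the guarantee that no pixel is ever
  interpolated.
- The measured-transfer workflow assumes the vertical axis is undegraded; a
  detector with vertical roll-off would bias the horizontal estimate.
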