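# fastscan

Restoration and drift-robust integration of fast-scan (video-rate) SEM frame
stacks.

## The problem

Slow single-pass scanning is the traditional way to get a sharp, low-noise
scanning-electron-microscope image, but on nonconductive specimens (uncoated
biological material such as foraminifera shells) the dwell time promotes
charging: anomalous brightness, drift and distortion. Video-rate ("TV-scan")
acquisition at ~0.04 s/frame keeps the charge distribution stable, at two
costs this package removes in software:

1. **Detector bandwidth.** At video rate the detector chain low-passes the
   signal along the fast-scan (horizontal) direction. The transfer H(f) is
   measured from defocused pure-noise frames (averaged spectral line
   profiles; the vertical profile is the flat reference) and flattened with a
   capped inverse filter, gain = clip(1/H(f), 1, cap).
2. **Noise.** A single frame can have amplitude SNR ≈ 0.25. Averaging n
   aligned frames raises the SNR by √n — provided the frames are aligned,
   otherwise drift blurs the result.

Quality is tracked with the two-image covariance statistics of a same-view
pair (t₁, t₂):

    S_σ = √Cov(t₁, t₂)            (signal amplitude)
    N_σ = √(√(Var₁·Var₂) − Cov)   (noise amplitude)
    SNR = S_σ / N_σ

S_σ computed after an isotropic high-pass (largest passed structure ≈ 8 px at
640×480) — **S_σ(HPF)** — is the fine-structure sharpness score: any blur
introduced by integration drops it immediately. The pipeline:

- aligns frames by zero-mean normalized cross-correlation of a template ROI,
  coarse-to-fine over an image pyramid, **integer shifts only** (no
  interpolation, so no resampling blur; every output pixel is a convex
  combination of original frame pixels);
- splits the stack into odd/even halves, integrates each to a series of
  checkpoints and plots S_σ(HPF) of the pair against √n — the integration
  curve that diagnoses drift and yields the optimal frame count;
- under spatially varying drift, integrates once per anchor ROI and blends
  the partials into a seam-suppressed montage so each region keeps its
  sharpest version.

## Worked example

A synthetic 256-frame stack (640×480, single-frame SNR 1.0) drifting
0.1 px/frame along the scan direction:

```python
import fastscan as fs

truth = fs.make_ground_truth(480, 640, seed=7)
drift = fs.DriftModel.constant_rate((0.0, 0.1), 256)
noise = fs.NoiseModel.for_target_snr(truth.pixels, 1.0, seed=7)
stack = fs.simulate_stack(truth, drift, None, noise, None, 256, seed=7)

roi = fs.ROI(160, 208, 320, 432)
spec = fs.FilterSpec(8)
plain   = fs.integration_curve(stack, [1, 4, 16, 36, 64, 121], aligned=False, spec=spec)
aligned = fs.integration_curve(stack, [1, 4, 16, 36, 64, 121], aligned=True,
                               roi=roi, spec=spec, search_margin=32)
```

which prints:

```
   n   unaligned   aligned
    1    0.0360     0.0362
    4    0.0348     0.0350
   16    0.0270     0.0346
   36    0.0182     0.0345
   64    0.0136     0.0345
  121    0.0100     0.0345
optimal n (unaligned halves): 4
optimal n (aligned halves):   121
SNR of the two 128-frame integrations: 10.3  (sqrt(128) = 11.3)
blanking-corrected vs slow scan:       10.9
```

Without alignment the cumulative drift (~26 px by the end) erases the fine
structure — S_σ(HPF) falls to 28% of its first point, and the optimal-n rule
says to stop at 4 frames per half. With ZNCC alignment the curve stays flat
(within 5%), all 121 checkpointed frames per half are usable, and the SNR of
the 128-frame integrations reaches 10.3, close to the √128 ≈ 11.3 ideal (the
deficit is the sub-pixel rounding jitter of interpolation-free alignment).
The blanking correction puts the value on the footing of a slow scan that
spends 90% rather than 80% of its acquisition time collecting pixels.

The same stages are available as a CLI:

```sh
fastscan simulate --height 480 --width 640 --n-frames 64 --drift 0,0.1 --snr 0.25 --seed 7 --out stack.tif
fastscan measure-mtf --in noise_stack.tif --out mtf.csv
fastscan restore --in stack.tif --mtf mtf.csv --gain-cap 10 --out restored.tif
fastscan align-integrate --in restored.tif --roi 112,192,368,448 --out integrated.tif --shifts shifts.csv
fastscan montage --in restored.tif --rois rois.json --feather 64 --out montage.tif
fastscan run --config run.yaml
```

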