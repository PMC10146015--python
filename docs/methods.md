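# Methods

## Model

The pipeline maps a co-registered slice triplet (T2WI, ADC, DWI) to a
scalar "suspicion" image by a fixed, training-free transform.  Its core
assumption is the PI-RADS concordance pattern for clinically
significant peripheral-zone cancer: low T2WI, low ADC, high DWI.
After inverting T2WI and ADC, a suspicious voxel is bright on all three
channels of the RGB stack `(T2WI⁻¹, ADC⁻¹, DWI)`; in CIELAB this means
high lightness *L* and near-zero chroma `C = √(a*² + b*²)`.  The output
is

```
intensity = uint8(255·L/100) − uint8(C)      (saturating subtraction)
```

Voxels where the sequences *disagree* — most importantly T2
shine-through, where DWI is bright but ADC is bright too — acquire
chroma and are suppressed.  Conversely, lesions visible on T2WI only
(the typical equivocal transition-zone PI-RADS 3 pattern) produce
strong chroma and are *not* highlighted; this insensitivity is by
design: the method targets high and very-high-risk lesions
(PI-RADS 4/5), not equivocal ones.

The intensity image is thresholded into empirical PI-RADS bands
(3: [100, 164], 4: [165, 189], 5: [190, 220], both bounds inclusive).
Intensities below 100 and above 220 are unassigned; a config option
(`ThresholdBands.with_extended_pr5`) extends the top band to 255, since
above-band values tend to accompany extraprostatic invasion but no
established rule covers them.

### Assumptions

- Sequences are scanner-aligned axial obliques with equal slice
  thickness (≤ 3 mm) and gap; no registration is attempted.
- Inputs are, or can be windowed to, 8-bit grayscale without losing the
  relative contrast the pattern relies on.
- DWI is acquired at a high b value (≥ 800, typically 1500 s/mm²) so
  benign tissue is suppressed.

## Key parameters

| parameter | default | units | why |
|---|---|---|---|
| working resolution `out_size` | 600 | px | standard display-resolution grid all sequences are resampled to |
| interpolation | bicubic + antialiasing | — | default of the resize routine the method was developed with; configurable |
| luminance scale | 255/100 | — | maps CIELAB L ∈ [0, 100] onto 8 bits; written as 255·L/100 so L = 50 hits the 127.5 tie exactly and rounds up |
| rounding | half away from zero | — | the saturating-integer-cast convention; applied at every 8-bit cast |
| jet LUT length | 256 (64 optional) | entries | affects rendering only, never the intensity mask |
| PI-RADS bands | [100,164] / [165,189] / [190,220] | 8-bit intensity | empirical cut points on the per-class intensity histograms |
| pairing tolerance | 1.5 | mm | half the maximum allowed slice thickness |
| `min_overlap_fraction` | 0.25 | — | a lesion counts as detected when a quarter of its pixels light up in its band; pixel-exact overlap is unattainable given edge-labeling subjectivity |
| window percentiles | (1, 99) | % | robust linear window for raw 12/16-bit data; `saturate` mode reproduces the literal 8-bit cast for pre-windowed inputs |

Component analysis uses 8-connectivity, the standard choice for 2-D
lesion blobs.  Conversion to CIELAB assumes sRGB companding with the
D65 reference white.

## Numerical choices

- Every 8-bit cast rounds half away from zero and clips to [0, 255];
  the chroma image is cast to 8 bits *before* the subtraction so the
  arithmetic stays bit-compatible with the original formulation.
- The RGB→LAB transform is implemented directly (sRGB → XYZ(D65) →
  CIELAB with the IEC 61966-2-1 matrix) so that a scalar per-pixel
  re-implementation can reproduce the pipeline bit-for-bit; it agrees
  with `skimage.color.rgb2lab` to ~1e-2 (the residual reflects constant
  precision, not formula differences).
- A degenerate percentile window (constant slice) yields an all-zero
  image plus a warning rather than an error.
- Dice of two empty masks is defined as 1.
- Detection accuracy over zero ground-truth components is reported as
  NaN/None (undefined), never as 0 or 1.

## Synthetic phantoms

`bpfuse.phantom` renders a prostate as concentric ellipses — a
T2-bright peripheral zone around a T2-intermediate transition zone with
a smoothed-noise T2 texture — inside darker pelvic background, plus
disk lesions with per-pattern mean signals:

| pattern | (t2, adc, dwi) | ground-truth label |
|---|---|---|
| pr5 | (50, 50, 205) | 3 |
| pr4 | (82, 82, 172) | 2 |
| pr3_tz | (100, 170, 70) — ADC/DWI equal the TZ base | 1 |
| extraprostatic | (50, 50, 205) | 4 |
| shine_through | (210, 230, 200) | 0 (confounder) |
| prostatitis | (150, 140, 110) | 0 (confounder) |

These constants are calibration constants, not measured values: they
were fixed once by running noiseless phantoms through the pipeline so
that the fused pr5 lesion mean lands inside [190, 220] and pr4 inside
[165, 189] (`scripts/calibrate_phantom.py` reproduces the check:
pr5 → 209.8, pr4 → 178.9 at σ = 0), and are frozen thereafter.  Noise
is clipped additive Gaussian (default σ = 8 in 8-bit units); at display
scale the difference from Rician noise is immaterial to threshold-band
behaviour.  Lesions are disks because the method is purely per-pixel —
shape realism (spiculation, "erased charcoal" texture), bias fields,
k-space artifacts and inter-sequence misalignment are *not* simulated.
A green phantom test therefore establishes that the arithmetic and the
band logic behave as designed under the assumed signal model; it does
not establish clinical detection performance, which depends on exactly
the effects the phantom omits.

## Design choices where the design was open

- **Windowing of raw data.**  How scanner-depth data were reduced to
  8 bits upstream of the original algorithm is unknown.  Default here:
  percentile windowing (1, 99) for raw DICOM/NIfTI; `saturate` mode
  reproduces the literal cast for already-8-bit inputs.
- **Monotone-suspicion regime.**  Fused intensity increases with lesion
  DWI only up to the achromatic point (DWI equal to the inverted
  T2/ADC level); beyond it blue chroma grows and intensity correctly
  falls again.  The documented monotonicity property — and its test
  ladder — covers the approach toward the concordant pattern
  (DWI 125 → 205, ADC/T2 130 → 50 in 20-unit steps ending at the pr5
  defaults), which is the clinically meaningful regime.
- **Greedy slice pairing** on the T2WI series as anatomical reference.
  Greedy nearest-position matching may pair across slice indices when a
  neighbouring slice is closer than the same-index one; this is
  intentional (it maximises usable triples) and verified against an
  optimal unique assignment on small series.
- **Above-band intensities** classify as background by default; the
  extended-pr5 option exists because such values often accompany
  extraprostatic invasion, but no validated rule assigns them.

## Limitations

- No registration: misaligned sequences blur the pattern and are the
  main real-world failure mode; the phantom does not model this.
- PI-RADS 3 lesions are by construction barely highlighted; the bands'
  PI-RADS 3/4 boundary is the least reliable.
- The band constants were derived on one scanner/protocol family;
  other protocols likely need re-derived cut points.
- DICOM reading requires the optional `pydicom` dependency; DCE
  sequences are deliberately unsupported.
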