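"""Three-sequence bpMRI fusion: T2WI + ADC + DWI -> tumor-intensity mask.

The algorithm exploits the PI-RADS signal pattern of clinically
significant prostate cancer — hypointense on T2WI and the ADC map,
hyperintense on high-b-value DWI.  Inverting T2WI and ADC makes a
suspicious voxel bright on all three channels; stacking them as RGB
makes such voxels near-achromatic (gray/white) while voxels whose
sequences disagree acquire chroma.  In CIELAB, subtracting the chroma
magnitude sqrt(a*^2 + b*^2) from the lightness therefore yields an
intensity image that is high exactly where all three sequences concur
on suspicion — and cancels T2 shine-through (high DWI but also high
ADC), which shows up as chroma, not lightness.

Steps, in pipeline order:

1. resize every sequence to ``out_size`` x ``out_size``, 8-bit grayscale
2. invert T2WI and ADC (``255 - x``); DWI is NOT inverted
3. stack as RGB: R = inverted T2WI, G = inverted ADC, B = DWI
4. convert RGB (sRGB-encoded, D65 white) to CIELAB
5. scale L (0-100) by 2.55 to an 8-bit luminance; keep a*, b* untouched
6. combined = uint8(sqrt(a*^2 + b*^2)); intensity = luminance - combined
   (saturating); render with a 'jet' lookup table

All 8-bit casts round half away from zero and saturate, matching a
MATLAB integer cast.  The combined-channels image is cast to 8-bit
*before* the subtraction, preserving the exact arithmetic of the
original formulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from skimage.transform import resize as _sk_resize

from .io import SliceTriplet, round_half_away, u8_saturate

__all__ = [
    "FusionConfig",
    "LabChannels",
    "FusionResult",
    "resize_to",
    "invert",
    "stack_rgb",
    "rgb_to_lab",
    "extract_channels",
    "combined_channels",
    "intensity_mask",
    "apply_jet",
    "fuse",
    "make_panel",
]

#: luminance scale: CIELAB L in [0, 100] -> 8-bit
LUMINANCE_SCALE = 2.55

# sRGB -> XYZ (D65) primaries matrix, IEC 61966-2-1
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
# D65 reference white
_WHITE_XYZ = np.array([0.95047, 1.0, 1.08883])

_INTERP_ORDER = {"nearest": 0, "bilinear": 1, "bicubic": 3}


@dataclass
class FusionConfig:
    """Pipeline parameters.

    out_size
        Side of the square working resolution (default 600 px).
    interpolation
        Resampling kernel for step 1; bicubic with antialiasing by
        default (the behaviour of the MATLAB resize the method was
        developed with).
    colormap_entries
        Length of the jet lookup table (256, or 64 for the historical
        MATLAB figure default).  Affects rendering only, never the
        intensity mask.
    """

    out_size: int = 600
    interpolation: Literal["bicubic", "bilinear", "nearest"] = "bicubic"
    colormap_entries: int = 256

    def __post_init__(self) -> None:
        if self.out_size < 1:
            raise ValueError("out_size must be >= 1")
        if self.colormap_entries not in (64, 256):
            raise ValueError("colormap_entries must be 64 or 256")
        if self.interpolation not in _INTERP_ORDER:
            raise ValueError(f"unknown interpolation: {self.interpolation!r}")


@dataclass
class LabChannels:
    """CIELAB decomposition: L in [0, 100], a*/b* signed chroma axes."""

    luminance: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        if not (self.luminance.shape == self.alpha.shape == self.beta.shape):
            raise ValueError("LAB channel dimensions differ")


@dataclass
class FusionResult:
    """All intermediate and final products of one fused slice."""

    t2_inv: np.ndarray
    adc_inv: np.ndarray
    rgb: np.ndarray
    lab: LabChannels
    luminance8: np.ndarray
    combined: np.ndarray
    intensity: np.ndarray
    jet_rgb: np.ndarray


def resize_to(img: np.ndarray, cfg: FusionConfig) -> np.ndarray:
    """Step 1: resample an 8-bit image to ``out_size`` x ``out_size``."""
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("cannot resize an empty image")
    shape = (cfg.out_size, cfg.out_size)
    if img.shape == shape:
        return img.astype(np.uint8)
    order = _INTERP_ORDER[cfg.interpolation]
    antialias = cfg.interpolation != "nearest" and img.shape[0] > cfg.out_size
    out = _sk_resize(
        img.astype(np.float64),
        shape,
        order=order,
        anti_aliasing=antialias,
        preserve_range=True,
        mode="edge",
    )
    return u8_saturate(out)


def invert(img: np.ndarray) -> np.ndarray:
    """Step 2: ``255 - x`` so that hypointense lesions become bright."""
    img = np.asarray(img)
    if img.dtype != np.uint8 and (img.min() < 0 or img.max() > 255):
        raise ValueError("invert expects values in [0, 255]")
    return (255 - img.astype(np.int16)).astype(np.uint8)


def stack_rgb(t2_inv: np.ndarray, adc_inv: np.ndarray, dwi: np.ndarray) -> np.ndarray:
    """Step 3: channel-stack (inverted T2WI, inverted ADC, DWI) as RGB."""
    for name, img in (("t2_inv", t2_inv), ("adc_inv", adc_inv), ("dwi", dwi)):
        if np.asarray(img).shape != np.asarray(t2_inv).shape:
            raise ValueError(f"dimension mismatch in sequence {name}: "
                             f"{np.asarray(img).shape} vs {np.asarray(t2_inv).shape}")
    return np.stack([t2_inv, adc_inv, dwi], axis=-1).astype(np.uint8)


def _srgb_companding_inverse(s: np.ndarray) -> np.ndarray:
    return np.where(s <= 0.04045, s / 12.92, ((s + 0.055) / 1.055) ** 2.4)


def _lab_f(t: np.ndarray) -> np.ndarray:
    delta = 6.0 / 29.0
    return np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)


def rgb_to_lab(rgb: np.ndarray) -> LabChannels:
    """Step 4: convert 8-bit sRGB to CIELAB under the D65 illuminant."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("rgb_to_lab expects an HxWx3 image")
    linear = _srgb_companding_inverse(rgb.astype(np.float64) / 255.0)
    xyz = linear @ _SRGB_TO_XYZ.T
    f = _lab_f(xyz / _WHITE_XYZ)
    lum = 116.0 * f[..., 1] - 16.0
    alpha = 500.0 * (f[..., 0] - f[..., 1])
    beta = 200.0 * (f[..., 1] - f[..., 2])
    return LabChannels(luminance=lum, alpha=alpha, beta=beta)


def extract_channels(lab: LabChannels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Step 5: 8-bit luminance (L x 2.55) plus untouched a*, b*.

    Computed as ``255 * L / 100`` so that e.g. L = 50 scales to exactly
    127.5 (and rounds up to 128); the literal constant 2.55 is not
    representable in binary floating point and would land a hair below
    the tie.
    """
    luminance8 = u8_saturate(lab.luminance * 255.0 / 100.0)
    return luminance8, lab.alpha, lab.beta


def combined_channels(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Step 6a: 8-bit chroma magnitude ``uint8(sqrt(a*^2 + b*^2))``."""
    if np.asarray(alpha).shape != np.asarray(beta).shape:
        raise ValueError("alpha and beta dimensions differ")
    return u8_saturate(np.sqrt(np.square(alpha) + np.square(beta)))


def intensity_mask(luminance8: np.ndarray, combined: np.ndarray) -> np.ndarray:
    """Step 6b: saturating subtraction ``max(0, luminance8 - combined)``."""
    if luminance8.shape != combined.shape:
        raise ValueError("luminance8 and combined dimensions differ")
    diff = luminance8.astype(np.int16) - combined.astype(np.int16)
    return np.clip(diff, 0, 255).astype(np.uint8)


def jet_lut(entries: int = 256) -> np.ndarray:
    """Jet lookup table (entries x 3, floats in [0, 1]).

    The standard piecewise-linear blue -> cyan -> yellow -> red ramps:
    entry 0 is dark blue (0, 0, 0.5), the last entry dark red
    (0.5, 0, 0).
    """
    from matplotlib import colormaps

    return np.asarray(colormaps["jet"](np.linspace(0.0, 1.0, entries)))[:, :3]


def apply_jet(intensity: np.ndarray, cfg: FusionConfig | None = None) -> np.ndarray:
    """Step 6c: pseudocolor the intensity mask via a jet lookup table.

    For a 64-entry table, 8-bit values index entry ``v * 64 // 256``.
    """
    cfg = cfg or FusionConfig()
    lut = jet_lut(cfg.colormap_entries)
    idx = np.asarray(intensity, dtype=np.int64)
    if cfg.colormap_entries != 256:
        idx = idx * cfg.colormap_entries // 256
    return lut[idx]


def fuse(triplet: SliceTriplet, cfg: FusionConfig | None = None) -> FusionResult:
    """Run the full six-step fusion pipeline on one slice triplet."""
    cfg = cfg or FusionConfig()
    t2 = resize_to(triplet.t2, cfg)
    adc = resize_to(triplet.adc, cfg)
    dwi = resize_to(triplet.dwi, cfg)
    t2_inv = invert(t2)
    adc_inv = invert(adc)
    rgb = stack_rgb(t2_inv, adc_inv, dwi)
    lab = rgb_to_lab(rgb)
    luminance8, alpha, beta = extract_channels(lab)
    combined = combined_channels(alpha, beta)
    intensity = intensity_mask(luminance8, combined)
    jet_rgb = apply_jet(intensity, cfg)
    return FusionResult(
        t2_inv=t2_inv,
        adc_inv=adc_inv,
        rgb=rgb,
        lab=lab,
        luminance8=luminance8,
        combined=combined,
        intensity=intensity,
        jet_rgb=jet_rgb,
    )


def make_panel(triplet: SliceTriplet, result: FusionResult,
               cfg: FusionConfig | None = None) -> np.ndarray:
    """Six-panel uint8 RGB figure: T2WI, ADC, DWI / RGB, intensity, jet.

    Composed by array tiling (no plotting library) so repeated runs are
    byte-identical.
    """
    cfg = cfg or FusionConfig()

    def as_rgb(img: np.ndarray) -> np.ndarray:
        img = resize_to(img, cfg) if img.ndim == 2 else img
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        return img.astype(np.uint8)

    jet8 = u8_saturate(result.jet_rgb * 255.0)
    top = np.hstack([as_rgb(triplet.t2), as_rgb(triplet.adc), as_rgb(triplet.dwi)])
    bottom = np.hstack([result.rgb, as_rgb(result.intensity), jet8])
    return np.vstack([top, bottom])
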