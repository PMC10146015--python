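"""Shared fixtures and the scalar per-pixel fusion oracle.

The oracle re-implements fusion steps 2-6 (inversion through intensity
mask) as plain Python loops over pixels, with the standard sRGB -> XYZ
(D65) -> CIELAB formulas written out scalar by scalar.  It shares no
code with the vectorised pipeline and exists to pin down the arithmetic
and rounding conventions bit-for-bit.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from bpfuse import LesionSpec, PhantomSpec

# sRGB primaries matrix and D65 white, IEC 61966-2-1
_M = [
    [0.4124564, 0.3575761, 0.1804375],
    [0.2126729, 0.7151522, 0.0721750],
    [0.0193339, 0.1191920, 0.9503041],
]
_WHITE = [0.95047, 1.0, 1.08883]


def _lab_f(t: float) -> float:
    d = 6.0 / 29.0
    return float(np.cbrt(t)) if t > d**3 else t / (3 * d * d) + 4.0 / 29.0


def _inv_companding(s: float) -> float:
    return s / 12.92 if s <= 0.04045 else ((s + 0.055) / 1.055) ** 2.4


def _u8(x: float) -> int:
    r = math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)
    return min(255, max(0, r))


def scalar_pixel_intensity(t2: int, adc: int, dwi: int) -> int:
    """Fusion steps 2-6 for a single pixel, straight-line scalar code."""
    r, g, b = 255 - int(t2), 255 - int(adc), int(dwi)
    lin = [_inv_companding(v / 255.0) for v in (r, g, b)]
    xyz = [sum(_M[k][c] * lin[c] for c in range(3)) for k in range(3)]
    fx, fy, fz = (_lab_f(xyz[k] / _WHITE[k]) for k in range(3))
    lum = 116.0 * fy - 16.0
    alpha = 500.0 * (fx - fy)
    beta = 200.0 * (fy - fz)
    lum8 = _u8(lum * 255.0 / 100.0)
    comb = _u8(math.sqrt(alpha * alpha + beta * beta))
    return max(0, lum8 - comb)


def scalar_fuse_intensity(t2: np.ndarray, adc: np.ndarray,
                          dwi: np.ndarray) -> np.ndarray:
    """Per-pixel scalar re-implementation of the fused intensity mask."""
    h, w = t2.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for i in range(h):
        for j in range(w):
            out[i, j] = scalar_pixel_intensity(t2[i, j], adc[i, j], dwi[i, j])
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230330)


@pytest.fixture
def random_triplet(rng):
    """A random 32x32 uint8 (t2, adc, dwi) triple."""
    return tuple(rng.integers(0, 256, (32, 32), dtype=np.uint8) for _ in range(3))


@pytest.fixture
def pr5_phantom_spec() -> PhantomSpec:
    """Noiseless phantom with one peripheral-zone PI-RADS 5 lesion."""
    return PhantomSpec(
        lesions=[LesionSpec(center=(128.0, 200.0), radius=12.0, pattern="pr5")],
        noise_sigma=0.0,
        seed=7,
    )
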