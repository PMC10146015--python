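"""Synthetic bpMRI phantoms with ground-truth lesion masks.

Emulates the signal structure the fusion method assumes: a prostate
gland with a T2-bright peripheral zone and a T2-intermediate,
heterogeneous transition zone; lesions rendered as filled disks whose
per-sequence mean signals follow the PI-RADS patterns — clinically
significant cancer is hypointense on T2WI and ADC and hyperintense on
high-b-value DWI, T2 shine-through is hyperintense on BOTH ADC and DWI,
and equivocal transition-zone lesions differ from background on T2WI
only.  Zero-mean Gaussian noise (clipped to [0, 255]) stands in for
acquisition noise; at 8-bit display scale the distinction from Rician
noise is immaterial to threshold-band behaviour.

The per-pattern signal constants are calibration constants: they were
fixed once by running noiseless phantoms through the fusion pipeline so
that the fused lesion means land inside the empirical PI-RADS bands
(see scripts/calibrate_phantom.py), and are not tuned thereafter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import json

import numpy as np
from scipy import ndimage

from .io import SliceTriplet, u8_saturate, write_image
from .evaluate import LABEL_PR3, LABEL_PR4, LABEL_PR5, LABEL_EXTRAPROSTATIC

__all__ = [
    "LesionPattern",
    "LesionSpec",
    "PhantomSpec",
    "PATTERNS",
    "default_signal_model",
    "background_signal",
    "generate_phantom",
    "generate_suite",
    "save_phantom",
]

LesionPattern = Literal[
    "pr3_tz", "pr4", "pr5", "extraprostatic", "shine_through", "prostatitis"
]

#: canonical pattern order used by generate_suite
PATTERNS: tuple[str, ...] = (
    "pr3_tz", "pr4", "pr5", "extraprostatic", "shine_through", "prostatitis"
)

#: pattern -> ground-truth label; confounders stay background
PATTERN_LABELS = {
    "pr3_tz": LABEL_PR3,
    "pr4": LABEL_PR4,
    "pr5": LABEL_PR5,
    "extraprostatic": LABEL_EXTRAPROSTATIC,
    "shine_through": 0,
    "prostatitis": 0,
}

# background mean signals (t2, adc, dwi), 8-bit units
_BG_PELVIS = (90, 110, 45)        # extra-prostatic pelvic tissue
_BG_PERIPHERAL = (200, 180, 60)   # T2-bright peripheral zone
_BG_TRANSITION = (130, 170, 70)   # T2-intermediate transition zone

# per-pattern lesion mean signals (t2, adc, dwi), calibrated against the
# fusion pipeline so fused means land in the PI-RADS bands (pr5 -> [190, 220],
# pr4 -> [165, 189]); frozen — see scripts/calibrate_phantom.py
_PATTERN_SIGNALS: dict[str, tuple[int, int, int]] = {
    "pr5": (50, 50, 205),
    "pr4": (82, 82, 172),
    "pr3_tz": (100, 170, 70),          # ADC/DWI equal the transition-zone base
    "extraprostatic": (50, 50, 205),   # high-grade tumor extending outward
    "shine_through": (210, 230, 200),  # long T2: bright ADC *and* bright DWI
    "prostatitis": (150, 140, 110),    # benign mimic, mild diffusion change
}


def default_signal_model(pattern: str) -> tuple[int, int, int]:
    """Default (t2, adc, dwi) mean signal levels for a lesion pattern."""
    try:
        return _PATTERN_SIGNALS[pattern]
    except KeyError:
        raise ValueError(
            f"unknown lesion pattern: {pattern!r}; expected one of {PATTERNS}"
        ) from None


def background_signal(zone: Literal["pelvis", "peripheral", "transition"]) -> tuple[int, int, int]:
    """Base (t2, adc, dwi) mean signal of a background compartment."""
    return {"pelvis": _BG_PELVIS, "peripheral": _BG_PERIPHERAL,
            "transition": _BG_TRANSITION}[zone]


@dataclass
class LesionSpec:
    """A circular lesion: center (row, col) px, radius px, signal pattern.

    ``signal_levels`` defaults to the calibrated per-pattern constants.
    """

    center: tuple[float, float]
    radius: float
    pattern: str
    signal_levels: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown lesion pattern: {self.pattern!r}")
        if self.radius < 2:
            raise ValueError("lesion radius must be >= 2 px")
        if self.signal_levels is None:
            self.signal_levels = default_signal_model(self.pattern)
        if any(not (0 <= v <= 255) for v in self.signal_levels):
            raise ValueError("signal_levels must be in [0, 255]")


@dataclass
class PhantomSpec:
    """Parametric description of one synthetic bpMRI slice triplet.

    size
        Square image side in px (native resolution, before the fusion
        pipeline's own resize).
    gland_center / gland_axes
        Prostate ellipse (row, col) center and semi-axes, px.
    tz_fraction
        Area fraction of the gland occupied by the transition zone
        (a concentric ellipse with axes scaled by sqrt(tz_fraction)).
    lesions
        Non-overlapping lesion disks, each fully inside the image.
    noise_sigma
        Std. dev. of the additive Gaussian noise, 8-bit units.
    seed
        Seed for the noise and texture; identical specs+seed reproduce
        bit-identical phantoms.
    """

    size: int = 256
    gland_center: tuple[float, float] | None = None
    gland_axes: tuple[float, float] = (80.0, 100.0)
    tz_fraction: float = 0.45
    lesions: list[LesionSpec] = field(default_factory=list)
    noise_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 16:
            raise ValueError("phantom size must be >= 16 px")
        if self.gland_center is None:
            self.gland_center = (self.size / 2.0, self.size / 2.0)
        if any(a <= 0 for a in self.gland_axes):
            raise ValueError("gland semi-axes must be > 0")
        if not (0 < self.tz_fraction < 1):
            raise ValueError("tz_fraction must be in (0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for les in self.lesions:
            r, c = les.center
            if not (les.radius <= r <= self.size - 1 - les.radius
                    and les.radius <= c <= self.size - 1 - les.radius):
                raise ValueError(
                    f"lesion at {les.center} radius {les.radius} exceeds image bounds"
                )


def _disk_mask(size: int, center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[:size, :size]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _ellipse_mask(size: int, center: tuple[float, float],
                  axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[:size, :size]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[SliceTriplet, np.ndarray]:
    """Render a phantom triplet and its ground-truth label mask.

    The label mask marks pr3_tz/pr4/pr5/extraprostatic lesions with
    labels 1/2/3/4; confounder patterns (shine_through, prostatitis)
    remain background (0) — they are precisely the structures the
    ground truth must NOT flag.  Noise never alters the mask.
    """
    size = spec.size
    rng = np.random.default_rng(spec.seed)

    gland = _ellipse_mask(size, spec.gland_center, spec.gland_axes)
    tz_axes = tuple(a * np.sqrt(spec.tz_fraction) for a in spec.gland_axes)
    tz = _ellipse_mask(size, spec.gland_center, tz_axes)
    pz = gland & ~tz

    channels = []
    for ch in range(3):
        img = np.full((size, size), float(_BG_PELVIS[ch]))
        img[pz] = _BG_PERIPHERAL[ch]
        img[tz] = _BG_TRANSITION[ch]
        channels.append(img)

    # transition-zone T2 heterogeneity: smoothed noise texture, drawn
    # before the per-sequence noise so the draw order is stable
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=6.0)
    tex_std = texture.std()
    if tex_std > 0:
        channels[0][tz] += (10.0 * texture / tex_std)[tz]

    label_mask = np.zeros((size, size), dtype=np.uint8)
    lesion_masks = []
    for les in spec.lesions:
        m = _disk_mask(size, les.center, les.radius)
        for prev in lesion_masks:
            if np.any(m & prev):
                raise ValueError(
                    f"overlapping lesions: disk at {les.center} intersects an "
                    "earlier lesion (ground truth would be ambiguous)"
                )
        lesion_masks.append(m)
        for ch in range(3):
            channels[ch][m] = les.signal_levels[ch]
        label_mask[m] = PATTERN_LABELS[les.pattern]

    imgs = []
    for ch in range(3):
        noisy = channels[ch]
        if spec.noise_sigma > 0:
            noisy = noisy + rng.normal(0.0, spec.noise_sigma, (size, size))
        imgs.append(u8_saturate(noisy))

    triplet = SliceTriplet(t2=imgs[0], adc=imgs[1], dwi=imgs[2],
                           slice_id=f"phantom-seed{spec.seed}")
    return triplet, label_mask


# ---------------------------------------------------------------------------
# suite generation
# ---------------------------------------------------------------------------

def _suite_spec(pattern: str, index: int, seed: int, size: int,
                noise_sigma: float) -> PhantomSpec:
    """One suite member: a single lesion of `pattern`, varied pose."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, PATTERNS.index(pattern), index]))
    center = (size / 2.0, size / 2.0)
    axes = (size * 0.31, size * 0.39)
    radius = float(rng.uniform(8.0, 16.0))
    theta = float(rng.uniform(0.0, 2.0 * np.pi))
    if pattern == "pr3_tz":
        # inside the transition zone
        rad_frac = float(rng.uniform(0.0, 0.35))
    elif pattern == "extraprostatic":
        # outside the gland but inside the image
        rad_frac = 1.35
    else:
        # mid-peripheral-zone ring
        rad_frac = float(rng.uniform(0.80, 0.85))
    lesion_center = (
        center[0] + rad_frac * axes[0] * np.sin(theta),
        center[1] + rad_frac * axes[1] * np.cos(theta),
    )
    lesion_center = (
        float(np.clip(lesion_center[0], radius + 1, size - radius - 2)),
        float(np.clip(lesion_center[1], radius + 1, size - radius - 2)),
    )
    phantom_seed = int(rng.integers(0, 2**31 - 1))
    return PhantomSpec(
        size=size,
        gland_center=center,
        gland_axes=axes,
        lesions=[LesionSpec(center=lesion_center, radius=radius, pattern=pattern)],
        noise_sigma=noise_sigma,
        seed=phantom_seed,
    )


def generate_suite(
    n_per_pattern: int,
    seed: int = 0,
    size: int = 256,
    noise_sigma: float = 8.0,
    patterns: tuple[str, ...] = PATTERNS,
) -> list[tuple[SliceTriplet, np.ndarray]]:
    """Balanced, seeded phantom suite covering every lesion pattern.

    Returns ``n_per_pattern * len(patterns)`` (triplet, label mask)
    pairs, grouped by pattern in the order of ``patterns``: entries
    ``[k * n_per_pattern : (k + 1) * n_per_pattern]`` carry the k-th
    pattern.  Lesion sizes and positions vary per entry; the whole
    suite is reproducible from ``seed``.
    """
    if n_per_pattern < 1:
        raise ValueError("n_per_pattern must be >= 1")
    out = []
    for pattern in patterns:
        for i in range(n_per_pattern):
            spec = _suite_spec(pattern, i, seed, size, noise_sigma)
            out.append(generate_phantom(spec))
    return out


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def save_phantom(spec: PhantomSpec, out_dir: str | Path,
                 nifti: bool = False) -> list[Path]:
    """Write a phantom as per-sequence PNGs, a label-mask PNG and a JSON
    sidecar with the spec; optionally also as NIfTI volumes (one slice).

    Returns the list of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    triplet, label_mask = generate_phantom(spec)
    written = []
    for name, img in (("t2", triplet.t2), ("adc", triplet.adc),
                      ("dwi", triplet.dwi), ("labels", label_mask)):
        p = out_dir / f"{name}.png"
        write_image(img, p)
        written.append(p)
    sidecar = out_dir / "phantom.json"
    sidecar.write_text(json.dumps(asdict(spec), indent=2))
    written.append(sidecar)
    if nifti:
        import nibabel as nib

        for name, img in (("t2", triplet.t2), ("adc", triplet.adc),
                          ("dwi", triplet.dwi)):
            p = out_dir / f"{name}.nii.gz"
            vol = img[:, :, np.newaxis].astype(np.int16)
            nib.save(nib.Nifti1Image(vol, np.eye(4)), str(p))
            written.append(p)
    return written
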