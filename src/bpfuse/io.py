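"""Reading, validation and pairing of multi-sequence MRI slice data.

Supports DICOM series (optional, requires pydicom), NIfTI-1 volumes and
8-bit grayscale PNG slices.  Raw scanner intensities are normalised to
8-bit grayscale either by saturating cast (the literal semantics of a
MATLAB ``uint8`` cast, appropriate for data that is already windowed) or
by percentile windowing (appropriate for raw 12/16-bit data).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from PIL import Image

logger = logging.getLogger("bpfuse")

SequenceKind = Literal["T2WI", "ADC", "DWI"]

#: default pairing tolerance: half the maximum slice thickness (3 mm)
DEFAULT_PAIRING_TOLERANCE_MM = 1.5

#: default percentile window for raw (non-8-bit) data
DEFAULT_WINDOW_PERCENTILES = (1.0, 99.0)


def round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round half away from zero (the MATLAB integer-cast convention).

    numpy's ``round`` rounds half to even; every 8-bit cast in this
    package goes through this function instead so that 127.5 -> 128.
    """
    x = np.asarray(x, dtype=np.float64)
    return np.where(x >= 0, np.floor(x + 0.5), np.ceil(x - 0.5))


def u8_saturate(x: np.ndarray | float) -> np.ndarray:
    """Round half away from zero and clip to [0, 255], returning uint8."""
    return np.clip(round_half_away(x), 0, 255).astype(np.uint8)


@dataclass(eq=False)
class RawSlice:
    """One 2-D slice of one MRI sequence, at native bit depth.

    Parameters
    ----------
    pixels
        2-D non-negative integer (or float) array in scanner units.
    slice_position_mm
        Position along the patient z axis, millimetres.
    pixel_spacing_mm
        (row, col) spacing in millimetres.
    sequence_kind
        One of ``"T2WI"``, ``"ADC"``, ``"DWI"``.
    source_id
        Opaque provenance string (file name, SOP instance UID, ...).
    """

    pixels: np.ndarray
    slice_position_mm: float
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    sequence_kind: SequenceKind | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if np.min(self.pixels) < 0:
            raise ValueError("pixel values must be >= 0")
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise ValueError("pixel_spacing_mm must be > 0")


@dataclass(eq=False)
class SliceTriplet:
    """Co-registered 8-bit T2WI / ADC / DWI slices of identical shape."""

    t2: np.ndarray
    adc: np.ndarray
    dwi: np.ndarray
    slice_id: str = ""

    def __post_init__(self) -> None:
        for name in ("t2", "adc", "dwi"):
            img = np.asarray(getattr(self, name))
            if img.ndim != 2:
                raise ValueError(f"{name} must be 2-D")
            if img.dtype != np.uint8:
                if img.min() < 0 or img.max() > 255:
                    raise ValueError(f"{name} values outside [0, 255]")
                img = img.astype(np.uint8)
            setattr(self, name, img)
        if not (self.t2.shape == self.adc.shape == self.dwi.shape):
            raise ValueError(
                "sequence dimensions differ: "
                f"t2 {self.t2.shape}, adc {self.adc.shape}, dwi {self.dwi.shape}"
            )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_dicom_series(path: Path, sequence_kind: SequenceKind | None) -> list[RawSlice]:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "DICOM input requires the optional dependency 'pydicom' "
            "(pip install bpfuse[dicom])"
        ) from exc
    slices: list[RawSlice] = []
    for f in sorted(path.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(f))
            arr = ds.pixel_array
        except Exception as exc:
            raise IOError(f"unreadable DICOM file: {f}") from exc
        try:
            z = float(ds.ImagePositionPatient[2])
        except Exception:
            z = float(getattr(ds, "InstanceNumber", len(slices)))
            logger.warning("no ImagePositionPatient in %s; using instance number", f)
        spacing = tuple(float(v) for v in getattr(ds, "PixelSpacing", (1.0, 1.0)))
        slices.append(
            RawSlice(arr, z, (spacing[0], spacing[1]), sequence_kind, source_id=f.name)
        )
    return slices


def _read_nifti(path: Path, sequence_kind: SequenceKind | None) -> list[RawSlice]:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise IOError(f"unreadable NIfTI file: {path}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI volume, got shape {data.shape}")
    affine = img.affine
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1]))
    slices = []
    for k in range(data.shape[2]):
        z = float(affine[2, 2] * k + affine[2, 3])
        slices.append(
            RawSlice(
                np.abs(data[:, :, k]),
                z,
                spacing,
                sequence_kind,
                source_id=f"{path.name}[{k}]",
            )
        )
    return slices


def _read_png_slices(path: Path, sequence_kind: SequenceKind | None) -> list[RawSlice]:
    files = sorted(path.glob("*.png")) if path.is_dir() else [path]
    files = [f for f in files if f.is_file()]
    # optional sidecar with geometry: {"positions_mm": [...], "spacing_mm": [r, c]}
    sidecar = (path if path.is_dir() else path.parent) / "geometry.json"
    positions = None
    spacing = (1.0, 1.0)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        positions = meta.get("positions_mm")
        spacing = tuple(meta.get("spacing_mm", (1.0, 1.0)))
    else:
        logger.warning(
            "PNG input %s has no geometry.json sidecar; "
            "using slice index as position with unit spacing",
            path,
        )
    slices = []
    for i, f in enumerate(files):
        try:
            arr = np.asarray(Image.open(f).convert("L"))
        except Exception as exc:
            raise IOError(f"unreadable PNG file: {f}") from exc
        z = float(positions[i]) if positions is not None else float(i)
        slices.append(RawSlice(arr, z, spacing, sequence_kind, source_id=f.name))
    return slices


def read_series(
    path: str | Path,
    format: Literal["dicom", "nifti", "png"],
    sequence_kind: SequenceKind | None = None,
) -> list[RawSlice]:
    """Read one sequence's slices, sorted by slice position ascending.

    Parameters
    ----------
    path
        A directory (DICOM, PNG) or a volume file (NIfTI ``.nii``/``.nii.gz``,
        single PNG).
    format
        Input format.
    sequence_kind
        Caller hint recorded on each slice (``"T2WI"``/``"ADC"``/``"DWI"``).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such path: {path}")
    if format == "dicom":
        slices = _read_dicom_series(path, sequence_kind)
    elif format == "nifti":
        slices = _read_nifti(path, sequence_kind)
    elif format == "png":
        slices = _read_png_slices(path, sequence_kind)
    else:
        raise ValueError(f"unsupported format: {format!r}")
    if not slices:
        raise IOError(f"no readable slices in {path}")
    slices.sort(key=lambda s: s.slice_position_mm)
    return slices


# ---------------------------------------------------------------------------
# slice pairing
# ---------------------------------------------------------------------------

def pair_slices(
    t2_series: Sequence[RawSlice],
    adc_series: Sequence[RawSlice],
    dwi_series: Sequence[RawSlice],
    tolerance_mm: float = DEFAULT_PAIRING_TOLERANCE_MM,
) -> list[tuple[RawSlice, RawSlice, RawSlice]]:
    """Match slices across the three sequences by axial position.

    Greedy nearest-position matching with T2WI as the anatomical
    reference: for each T2 slice in order, the nearest unused ADC and
    DWI slices within ``tolerance_mm`` are claimed.  Every returned
    triple has pairwise position differences <= ``tolerance_mm`` and no
    slice appears in more than one triple.  An empty result is not an
    error (a study may simply yield no common slice); a warning is
    logged instead.
    """
    if tolerance_mm < 0:
        raise ValueError("tolerance_mm must be >= 0")
    used_adc: set[int] = set()
    used_dwi: set[int] = set()
    triples = []
    for t2 in t2_series:
        best = {}
        for name, series, used in (
            ("adc", adc_series, used_adc),
            ("dwi", dwi_series, used_dwi),
        ):
            cand = [
                (abs(s.slice_position_mm - t2.slice_position_mm), i)
                for i, s in enumerate(series)
                if i not in used
                and abs(s.slice_position_mm - t2.slice_position_mm) <= tolerance_mm
            ]
            best[name] = min(cand)[1] if cand else None
        ia, id_ = best["adc"], best["dwi"]
        if ia is None or id_ is None:
            continue
        if abs(adc_series[ia].slice_position_mm - dwi_series[id_].slice_position_mm) > tolerance_mm:
            continue
        used_adc.add(ia)
        used_dwi.add(id_)
        triples.append((t2, adc_series[ia], dwi_series[id_]))
    if not triples:
        logger.warning("pair_slices: no common slice found within %.2f mm", tolerance_mm)
    return triples


# ---------------------------------------------------------------------------
# 8-bit conversion
# ---------------------------------------------------------------------------

def to_uint8(
    raw: RawSlice | np.ndarray,
    mode: Literal["saturate", "window"] = "window",
    window_percentiles: tuple[float, float] = DEFAULT_WINDOW_PERCENTILES,
) -> np.ndarray:
    """Convert a raw slice to 8-bit grayscale.

    ``mode="saturate"`` reproduces a saturating integer cast: round half
    away from zero, clip to [0, 255].  ``mode="window"`` linearly maps
    the [low, high] percentile range of the slice onto [0, 255], then
    rounds and clips.  A constant image under windowing degenerates to
    all zeros with a warning.
    """
    pixels = raw.pixels if isinstance(raw, RawSlice) else np.asarray(raw)
    if mode == "saturate":
        return u8_saturate(pixels)
    if mode == "window":
        lo_p, hi_p = window_percentiles
        if not (0 <= lo_p <= 100 and 0 <= hi_p <= 100 and lo_p < hi_p):
            raise ValueError("window_percentiles must satisfy 0 <= lo < hi <= 100")
        lo, hi = np.percentile(pixels, [lo_p, hi_p])
        if hi <= lo:
            warnings.warn("degenerate window (constant image); output is all zeros")
            logger.warning("to_uint8: degenerate window on %s",
                           getattr(raw, "source_id", "<array>"))
            return np.zeros(pixels.shape, dtype=np.uint8)
        scaled = (pixels.astype(np.float64) - lo) / (hi - lo) * 255.0
        return u8_saturate(scaled)
    raise ValueError(f"unknown mode: {mode!r}")


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale or RGB image as a lossless PNG."""
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise ValueError("write_image expects a uint8 image")
    if img.ndim not in (2, 3):
        raise ValueError("write_image expects a 2-D grayscale or HxWx3 RGB image")
    try:
        Image.fromarray(img).save(str(path), format="PNG")
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot write image to {path}: {exc}") from exc


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG written by :func:`write_image` back as a numpy array."""
    try:
        return np.asarray(Image.open(str(path)))
    except Exception as exc:
        raise IOError(f"cannot read image from {path}: {exc}") from exc
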