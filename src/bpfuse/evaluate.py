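"""PI-RADS threshold-band classification and segmentation evaluation.

The fused intensity image concentrates suspicious tissue in the upper
intensity range; empirical cut points split it into three PI-RADS
bands.  Ground truth is the label-wise intersection of two readers'
segmentations.  Evaluation reports per-label intensity histograms,
Dice overlap of each band against its ground-truth class, and
component-level detection accuracy.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

logger = logging.getLogger("bpfuse")

#: ground-truth / prediction label codes
LABEL_BACKGROUND = 0
LABEL_PR3 = 1
LABEL_PR4 = 2
LABEL_PR5 = 3
LABEL_EXTRAPROSTATIC = 4

LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_PR3: "PI-RADS 3",
    LABEL_PR4: "PI-RADS 4",
    LABEL_PR5: "PI-RADS 5",
    LABEL_EXTRAPROSTATIC: "extraprostatic",
}

#: 8-connectivity structuring element for 2-D lesion blobs
_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ThresholdBands:
    """Closed integer intensity intervals for PI-RADS 3/4/5.

    Defaults are the empirical cut points on the fused-intensity
    histogram: PI-RADS 3 [100, 164], PI-RADS 4 [165, 189],
    PI-RADS 5 [190, 220].  Intensities below 100 or above 220 are
    unassigned (label 0) unless ``extend_pr5`` widens the top band
    to 255.
    """

    pr3: tuple[int, int] = (100, 164)
    pr4: tuple[int, int] = (165, 189)
    pr5: tuple[int, int] = (190, 220)

    def __post_init__(self) -> None:
        for name in ("pr3", "pr4", "pr5"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 255):
                raise ValueError(f"band {name}=[{lo}, {hi}] outside [0, 255] or empty")
        if not (self.pr3[1] < self.pr4[0] and self.pr4[1] < self.pr5[0]):
            raise ValueError("bands must be disjoint and ordered pr3 < pr4 < pr5")

    def with_extended_pr5(self) -> "ThresholdBands":
        """Widen the PI-RADS 5 band to reach 255."""
        return ThresholdBands(self.pr3, self.pr4, (self.pr5[0], 255))

    def band_for(self, label: int) -> tuple[int, int]:
        return {LABEL_PR3: self.pr3, LABEL_PR4: self.pr4, LABEL_PR5: self.pr5}[label]


def intersect_masks(reader_a: np.ndarray, reader_b: np.ndarray) -> np.ndarray:
    """Label-wise intersection of two readers' masks.

    A pixel keeps its label only where both readers assigned the same
    nonzero label; everywhere else it becomes background.  Pixels where
    the readers assigned *different* nonzero labels indicate a data
    error and are logged.
    """
    a = np.asarray(reader_a)
    b = np.asarray(reader_b)
    if a.shape != b.shape:
        raise ValueError(f"mask dimensions differ: {a.shape} vs {b.shape}")
    conflicts = int(np.count_nonzero((a != b) & (a > 0) & (b > 0)))
    if conflicts:
        logger.warning("intersect_masks: %d pixels with conflicting nonzero labels "
                       "set to background", conflicts)
    return np.where(a == b, a, 0)


def binarize_band(intensity: np.ndarray, band: tuple[int, int]) -> np.ndarray:
    """True where ``band[0] <= intensity <= band[1]`` (inclusive bounds)."""
    lo, hi = band
    if not (0 <= lo <= hi <= 255):
        raise ValueError(f"band [{lo}, {hi}] outside [0, 255]")
    intensity = np.asarray(intensity)
    return (intensity >= lo) & (intensity <= hi)


def classify_pixels(intensity: np.ndarray, bands: ThresholdBands | None = None) -> np.ndarray:
    """Assign each pixel a PI-RADS label (1/2/3) by band membership.

    Out-of-band intensities map to 0; the extraprostatic class (4) is a
    ground-truth-only label and is never produced.
    """
    bands = bands or ThresholdBands()
    intensity = np.asarray(intensity)
    out = np.zeros(intensity.shape, dtype=np.uint8)
    for label in (LABEL_PR3, LABEL_PR4, LABEL_PR5):
        out[binarize_band(intensity, bands.band_for(label))] = label
    return out


def region_histogram(intensity: np.ndarray, gt: np.ndarray) -> dict[int, np.ndarray]:
    """Per-label 256-bin histogram of fused intensities.

    For each label present in ``gt``, counts of the intensity values
    over that label's pixels; bin index equals the 8-bit intensity.
    """
    intensity = np.asarray(intensity)
    gt = np.asarray(gt)
    if intensity.shape != gt.shape:
        raise ValueError(f"dimensions differ: {intensity.shape} vs {gt.shape}")
    out = {}
    for label in np.unique(gt):
        out[int(label)] = np.bincount(
            intensity[gt == label].ravel(), minlength=256
        )[:256]
    return out


def resize_labels(labels: np.ndarray, out_size: int) -> np.ndarray:
    """Nearest-neighbour resize of an integer label mask to out_size².

    Used to carry a ground-truth mask along when the fusion pipeline
    resamples its input to the working resolution.
    """
    from skimage.transform import resize as _sk_resize

    labels = np.asarray(labels)
    if labels.shape == (out_size, out_size):
        return labels
    out = _sk_resize(labels, (out_size, out_size), order=0,
                     preserve_range=True, anti_aliasing=False)
    return out.astype(labels.dtype)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask dimensions differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(a & b)) / denom


def detection_accuracy(
    intensity: np.ndarray,
    gt: np.ndarray,
    target_label: int,
    bands: ThresholdBands | None = None,
    min_overlap_fraction: float = 0.25,
) -> tuple[int, int, float]:
    """Component-level detection of a PI-RADS class.

    Ground-truth 8-connected components of ``target_label`` count as
    detected when at least ``min_overlap_fraction`` of their pixels fall
    inside the class's intensity band.  Returns
    ``(detected, total, accuracy)``; accuracy is NaN when there are no
    components (undefined).
    """
    if target_label not in (LABEL_PR3, LABEL_PR4, LABEL_PR5):
        raise ValueError("target_label must be 1, 2 or 3")
    if not (0 < min_overlap_fraction <= 1):
        raise ValueError("min_overlap_fraction must be in (0, 1]")
    bands = bands or ThresholdBands()
    band_mask = binarize_band(intensity, bands.band_for(target_label))
    labeled, n_comp = ndimage.label(np.asarray(gt) == target_label, structure=_CONN8)
    detected = 0
    for comp in range(1, n_comp + 1):
        inside = band_mask[labeled == comp]
        if inside.mean() >= min_overlap_fraction:
            detected += 1
    accuracy = detected / n_comp if n_comp else float("nan")
    return detected, n_comp, accuracy


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def evaluate_slice(
    intensity: np.ndarray,
    gt: np.ndarray,
    bands: ThresholdBands | None = None,
    min_overlap_fraction: float = 0.25,
) -> dict:
    """Full per-slice evaluation record (detection, Dice, histograms)."""
    bands = bands or ThresholdBands()
    record: dict = {"classes": {}, "histograms": {}}
    for label, counts in region_histogram(intensity, gt).items():
        record["histograms"][str(label)] = counts.tolist()
    for label in (LABEL_PR3, LABEL_PR4, LABEL_PR5):
        det, total, acc = detection_accuracy(
            intensity, gt, label, bands, min_overlap_fraction
        )
        d = dice(binarize_band(intensity, bands.band_for(label)),
                 np.asarray(gt) == label)
        record["classes"][str(label)] = {
            "name": LABEL_NAMES[label],
            "detected": det,
            "total": total,
            "accuracy": None if total == 0 else acc,
            "dice": d,
        }
    return record


def write_report(records: dict[str, dict], out_json: str | Path,
                 out_csv: str | Path | None = None) -> None:
    """Write per-slice evaluation records as JSON plus a CSV summary."""
    out_json = Path(out_json)
    out_json.write_text(json.dumps(records, indent=2, sort_keys=True))
    if out_csv is None:
        return
    with open(out_csv, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slice_id", "label", "class", "detected", "total",
                         "accuracy", "dice"])
        for slice_id in sorted(records):
            for label, cls in sorted(records[slice_id]["classes"].items()):
                writer.writerow([
                    slice_id, label, cls["name"], cls["detected"], cls["total"],
                    "" if cls["accuracy"] is None else f"{cls['accuracy']:.4f}",
                    f"{cls['dice']:.4f}",
                ])


#: histogram plot colors per ground-truth class (PI-RADS 3/4/5, extraprostatic)
_HIST_COLORS = {LABEL_PR3: "gold", LABEL_PR4: "darkorange",
                LABEL_PR5: "red", LABEL_EXTRAPROSTATIC: "black"}


def plot_region_histograms(histograms: dict[int, np.ndarray],
                           out_path: str | Path) -> None:
    """Plot per-class intensity histograms (yellow/orange/red/black)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for label, color in _HIST_COLORS.items():
        if label in histograms and histograms[label].sum() > 0:
            ax.plot(np.arange(256), histograms[label], color=color,
                    label=LABEL_NAMES[label])
    ax.set_xlabel("fused intensity")
    ax.set_ylabel("pixel count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(str(out_path), dpi=100)
    plt.close(fig)
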