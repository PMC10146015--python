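"""One-off calibration of the phantom signal constants.

Runs noiseless single-lesion phantoms through the full fusion pipeline
and prints the mean fused intensity over each lesion pattern, so the
per-pattern signal levels in bpfuse.phantom can be checked against the
PI-RADS bands (pr5 -> [190, 220], pr4 -> [165, 189]).  The constants
were fixed from this script's output once and are not retuned.

Usage: python scripts/calibrate_phantom.py
"""

import numpy as np

from bpfuse import FusionConfig, PhantomSpec, LesionSpec, fuse, generate_phantom
from bpfuse.phantom import PATTERNS
from skimage.transform import resize


def lesion_mean(pattern: str, noise_sigma: float = 0.0, out_size: int = 600) -> float:
    in_tz = pattern == "pr3_tz"
    spec = PhantomSpec(
        lesions=[LesionSpec(center=(128, 128) if in_tz else (128, 200),
                            radius=12, pattern=pattern)],
        noise_sigma=noise_sigma,
        seed=7,
    )
    triplet, _ = generate_phantom(spec)
    result = fuse(triplet, FusionConfig(out_size=out_size))
    lesion = np.zeros((spec.size, spec.size), dtype=float)
    rr, cc = np.ogrid[:spec.size, :spec.size]
    c = spec.lesions[0].center
    lesion[(rr - c[0]) ** 2 + (cc - c[1]) ** 2 <= (spec.lesions[0].radius - 2) ** 2] = 1.0
    lesion_big = resize(lesion, (out_size, out_size), order=0) > 0.5
    return float(result.intensity[lesion_big].mean())


if __name__ == "__main__":
    for sigma in (0.0, 8.0):
        print(f"noise_sigma = {sigma}")
        for pattern in PATTERNS:
            print(f"  {pattern:15s} mean fused intensity = "
                  f"{lesion_mean(pattern, sigma):7.2f}")
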