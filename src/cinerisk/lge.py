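"""Core scar and gray-zone quantification from LGE signal intensities.

The thresholding rule: core scar is every pixel in the hyper-enhanced
region whose signal intensity (SI) exceeds 50% of the maximal SI within
that region; gray zone is every myocardial pixel whose SI lies strictly
between the peak SI of normal (non-enhanced) myocardium and that same
half-maximal threshold.  Pixels exactly at the half-maximal SI satisfy
neither strict inequality and are left unclassified (counted separately).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScarQuantification", "quantify_scar"]

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclass
class ScarQuantification:
    core_px: int
    gray_px: int
    core_g: float
    gray_g: float
    total_g: float
    max_si: float
    normal_peak_si: float
    unclassified_px: int = 0  # pixels exactly at the half-maximal threshold

    def __post_init__(self) -> None:
        if min(self.core_px, self.gray_px, self.core_g, self.gray_g, self.total_g) < 0:
            raise ValueError("scar quantities must be non-negative")
        if abs(self.total_g - (self.core_g + self.gray_g)) > 1e-9 * max(1.0, self.total_g):
            raise ValueError("total_g must equal core_g + gray_g")


def quantify_scar(
    image: np.ndarray,
    myocardium_mask: np.ndarray,
    hyperenhanced_mask: np.ndarray,
    voxel_volume_mm3: float,
    density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML,
    gray_within_hyperenhanced_only: bool = False,
) -> ScarQuantification:
    """Apply the SI-threshold rule to one slice (or a stack summed over slices).

    Masses are ``count * voxel_volume_mm3 * density / 1000`` grams
    (1 mm^3 = 1e-3 mL).  By default the gray-zone search domain is the full
    myocardium, since the rule's lower bound references normal myocardium;
    set ``gray_within_hyperenhanced_only`` to restrict it to the
    hyper-enhanced region.
    """
    image = np.asarray(image, dtype=float)
    myo = np.asarray(myocardium_mask, dtype=bool)
    he = np.asarray(hyperenhanced_mask, dtype=bool)
    if not (image.shape == myo.shape == he.shape):
        raise ValueError("image and masks must share a shape")
    if voxel_volume_mm3 <= 0:
        raise ValueError("voxel volume must be positive")
    if not myo.any():
        raise ValueError("empty myocardium mask")
    if np.any(he & ~myo):
        raise ValueError("hyperenhanced region must lie within the myocardium")

    px_to_g = voxel_volume_mm3 * density_g_per_ml / 1000.0
    if not he.any():
        return ScarQuantification(0, 0, 0.0, 0.0, 0.0, max_si=0.0, normal_peak_si=0.0)

    normal = myo & ~he
    if not normal.any():
        raise ValueError("no normal myocardium left to anchor the gray-zone lower bound")
    max_si = float(image[he].max())
    normal_peak_si = float(image[normal].max())
    half = 0.5 * max_si

    core = he & (image > half)
    gray_domain = he if gray_within_hyperenhanced_only else myo
    gray = gray_domain & (image > normal_peak_si) & (image < half)
    unclassified = gray_domain & (image == half) & (image > normal_peak_si)

    core_px, gray_px = int(core.sum()), int(gray.sum())
    return ScarQuantification(
        core_px=core_px,
        gray_px=gray_px,
        core_g=core_px * px_to_g,
        gray_g=gray_px * px_to_g,
        total_g=(core_px + gray_px) * px_to_g,
        max_si=max_si,
        normal_peak_si=normal_peak_si,
        unclassified_px=int(unclassified.sum()),
    )
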