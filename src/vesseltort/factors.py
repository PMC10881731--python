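"""Per-segment anatomical factors: caliber, artery/vein probability,
distances to the optic disc and the fovea.

These factors weight the importance of each vessel segment in the global
tortuosity score. Caliber comes from the Euclidean distance transform of the
binary vascular map (skeleton pixels sit at roughly half the local caliber,
so the mean transform value is doubled). The artery/vein factor averages the
soft class maps along the segment and normalizes them so artery and vein
probabilities are complementary. Distances are mean Euclidean pixel
distances from the segment pixels to the landmark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

__all__ = [
    "SegmentFactors",
    "compute_caliber",
    "compute_av_probability",
    "compute_distance",
    "reversed_od_distance",
]


@dataclass
class SegmentFactors:
    """Measured anatomical factors of one vessel segment.

    ``L_c`` is the segment length in pixels (pixel count), ``f_cal`` the
    caliber in px, ``f_av`` the probability of being an artery in [0, 1],
    and ``f_dod`` / ``f_dfov`` mean distances (px) to optic disc and fovea.
    """

    L_c: int
    f_cal: float
    f_av: float
    f_dod: float
    f_dfov: float
    assigned_class: str  # "artery" | "vein"

    def __post_init__(self) -> None:
        if self.f_cal <= 0:
            raise ValueError("caliber must be positive")
        if not 0.0 <= self.f_av <= 1.0:
            raise ValueError("f_av must lie in [0, 1]")
        if self.f_dod < 0 or self.f_dfov < 0:
            raise ValueError("distances must be non-negative")


def _path_index(path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(path)
    if pts.size == 0:
        raise ValueError("empty path")
    return pts[:, 0].astype(int), pts[:, 1].astype(int)


def compute_caliber(vessel_mask: np.ndarray, path: np.ndarray) -> float:
    """Mean vessel caliber (px) along a centerline path.

    The distance transform assigns each mask pixel its distance to the mask
    border, i.e. about half the local caliber on the centerline; the mean
    over the path is doubled to express the caliber in pixels.
    """
    rows, cols = _path_index(path)
    mask = np.asarray(vessel_mask, dtype=bool)
    if not mask[rows, cols].all():
        raise ValueError("path contains pixels outside the vessel mask")
    edt = distance_transform_edt(mask)
    return float(2.0 * edt[rows, cols].mean())


def compute_av_probability(
    artery_prob: np.ndarray, vein_prob: np.ndarray, path: np.ndarray
) -> tuple[float, str]:
    """Normalized artery probability of a segment and its assigned class.

    The soft maps are averaged along the path; because the multi-label maps
    are not complementary (a crossing pixel can be both artery and vein), the
    artery probability is normalized as ``a / (a + v)`` so that the vein
    probability is its complement. Class is artery iff f_av > 0.5 (ties go
    to vein).
    """
    rows, cols = _path_index(path)
    a = float(np.asarray(artery_prob, dtype=float)[rows, cols].mean())
    v = float(np.asarray(vein_prob, dtype=float)[rows, cols].mean())
    if a + v <= 0:
        warnings.warn(
            "segment has zero artery and vein probability; f_av set to 0.5",
            stacklevel=2,
        )
        return 0.5, "vein"
    f_av = a / (a + v)
    return f_av, ("artery" if f_av > 0.5 else "vein")


def compute_distance(landmark: tuple[int, int], path: np.ndarray) -> float:
    """Mean Euclidean distance (px) from the path pixels to a landmark."""
    rows, cols = _path_index(path)
    return float(np.hypot(rows - landmark[0], cols - landmark[1]).mean())


def reversed_od_distance(d_od: float, k: float = 600.0) -> float:
    """Reversed optic-disc distance ``Rd_OD = k - d_OD``, clamped at 0.

    ``k`` is chosen slightly larger than the largest optic-disc distance
    expected in the data (default 600 px) so nearby vessels get the largest
    weight instead of the smallest.
    """
    if d_od < 0:
        raise ValueError("d_od must be non-negative")
    if d_od > k:
        warnings.warn(
            f"d_OD={d_od:.1f} exceeds k={k}; reversed distance clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return float(k - d_od)
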