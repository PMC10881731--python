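"""Per-vessel explanation maps.

Each map paints the extracted vessel skeleton with one scalar per segment:
the tortuosity, any anatomical factor, or the segment's net contribution
``tau_vi * f_i / sum_j f_j`` to the global score (contributions sum exactly
to ``tau_f``, so a contribution map is a complete decomposition of the
prediction). Scalar kinds use a perceptually uniform continuous colormap
clipped to the given bounds; the artery/vein kind uses two categorical
colors (red arteries, green veins). Rendering is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image
from scipy.ndimage import binary_dilation

from .score import ImageAssessment

__all__ = ["FactorMap", "render_factor_map", "render_contribution_map", "save_map"]

_ARTERY_RGB = (214, 39, 40)  # red
_VEIN_RGB = (44, 160, 44)  # green
_BACKGROUND_RGB = (255, 255, 255)


@dataclass
class FactorMap:
    """A rendered per-segment map plus its metadata.

    ``values`` holds the per-pixel scalar (NaN background); ``rgb`` is the
    colored 8-bit image; ``metadata`` records the kind, color-scale bounds,
    and any model context so the rendering is self-describing.
    """

    values: np.ndarray
    rgb: np.ndarray
    metadata: dict = field(default_factory=dict)

    def segment_sum(self) -> float:
        """Sum of the distinct per-segment values (one per segment)."""
        return float(np.nansum(self.metadata.get("segment_values", [])))


def _paint(
    shape: tuple[int, int],
    paths: list[np.ndarray],
    values: list[float],
    dilate_px: int = 0,
) -> np.ndarray:
    canvas = np.full(shape, np.nan)
    for path, value in zip(paths, values):
        mask = np.zeros(shape, dtype=bool)
        mask[path[:, 0], path[:, 1]] = True
        if dilate_px > 0:
            mask = binary_dilation(mask, iterations=dilate_px)
        canvas[mask] = value
    return canvas


def render_factor_map(
    shape: tuple[int, int],
    paths: list[np.ndarray],
    values: list[float],
    kind: str = "scalar",
    scale: tuple[float, float] | None = None,
    cmap: str = "viridis",
    dilate_px: int = 1,
) -> FactorMap:
    """Paint per-segment scalars (or artery/vein classes) onto the skeleton.

    ``kind="av"`` interprets values as artery probabilities and colors
    segments categorically; any other kind maps values through ``cmap``
    clipped to ``scale`` (defaults to the per-image min/max).
    """
    if len(paths) != len(values):
        raise ValueError("one value per segment required")
    value_img = _paint(shape, paths, values, dilate_px)
    rgb = np.full((*shape, 3), _BACKGROUND_RGB, dtype=np.uint8)
    on = ~np.isnan(value_img)
    if kind == "av":
        artery = on & (value_img > 0.5)
        vein = on & ~artery
        rgb[artery] = _ARTERY_RGB
        rgb[vein] = _VEIN_RGB
        meta_scale = None
    else:
        if scale is None:
            finite = [v for v in values if np.isfinite(v)]
            lo = min(finite) if finite else 0.0
            hi = max(finite) if finite else 1.0
            if hi <= lo:
                hi = lo + 1.0
        else:
            lo, hi = scale
            if hi <= lo:
                raise ValueError("scale must satisfy lo < hi")
        normed = np.clip((value_img - lo) / (hi - lo), 0.0, 1.0)
        colored = colormaps[cmap](np.nan_to_num(normed))[..., :3]
        rgb[on] = (colored[on] * 255).astype(np.uint8)
        meta_scale = (float(lo), float(hi))
    return FactorMap(
        values=value_img,
        rgb=rgb,
        metadata={
            "kind": kind,
            "scale": meta_scale,
            "cmap": None if kind == "av" else cmap,
            "segment_values": [float(v) for v in values],
        },
    )


def render_contribution_map(
    assessment: ImageAssessment,
    dilate_px: int = 1,
    scale: tuple[float, float] | None = None,
    cmap: str = "viridis",
) -> FactorMap:
    """Net contribution of each vessel to the global tortuosity score.

    Per-segment values are ``tau_vi * f_i / sum_j f_j`` and sum to the
    predicted ``tau_f``; the metadata records the weighting configuration
    and score so the map fully explains the prediction.
    """
    if not assessment.paths:
        raise ValueError("assessment carries no pixel paths to render")
    shape = None
    for p in assessment.paths:
        top = p.max(axis=0)
        shape = top if shape is None else np.maximum(shape, top)
    shape = (int(shape[0]) + 2, int(shape[1]) + 2)
    contributions = assessment.segments["contribution"].tolist()
    fmap = render_factor_map(
        shape,
        assessment.paths,
        contributions,
        kind="contribution",
        scale=scale,
        cmap=cmap,
        dilate_px=dilate_px,
    )
    w = assessment.weights
    fmap.metadata.update(
        {
            "tau_f": assessment.tau_f,
            "label": assessment.label,
            "weights": {
                "omega_av": w.omega_av,
                "omega_cal": w.omega_cal,
                "omega_dod": w.omega_dod,
                "omega_dfov": w.omega_dfov,
                "phi_tort": w.phi_tort,
            },
        }
    )
    return fmap


def save_map(fmap: FactorMap, path: str | Path) -> tuple[Path, Path]:
    """Write the rendered PNG and a JSON sidecar with its metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(fmap.rgb).save(path)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(fmap.metadata, indent=1))
    return path, sidecar
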