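"""Reading and writing anatomy bundles, and the landmark heatmap codec.

An :class:`AnatomyBundle` collects what a segmentation network would produce
for one fundus image: soft artery, vein, and whole-vessel probability maps
(values in [0, 1]) plus the pixel locations of the optic disc and the fovea.
Landmarks may be exchanged either as explicit ``(row, col)`` coordinates or
as regression heatmaps of the form ``y = 1 + tanh(-d * pi / beta)``, which
peak at 1 on the target and decay to 0 at distances well beyond ``beta``.
The internal canonical form is always coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "AnatomyBundle",
    "Heatmap",
    "ShapeMismatchError",
    "MissingMapError",
    "LandmarkOutOfBoundsError",
    "encode_heatmap",
    "decode_landmark",
    "read_bundle",
    "write_bundle",
]


class ShapeMismatchError(ValueError):
    """Probability maps of one bundle do not share a common shape."""


class MissingMapError(FileNotFoundError):
    """A required probability map file is absent."""


class LandmarkOutOfBoundsError(ValueError):
    """A landmark lies outside the image grid."""


def _check_landmark(name: str, loc, shape) -> tuple[int, int]:
    r, c = int(loc[0]), int(loc[1])
    if not (0 <= r < shape[0] and 0 <= c < shape[1]):
        raise LandmarkOutOfBoundsError(
            f"{name} landmark {loc!r} outside image of shape {shape}"
        )
    return (r, c)


@dataclass
class AnatomyBundle:
    """Soft anatomy maps and landmarks for a single retinal image.

    All maps share one shape and hold values in [0, 1]. Coordinates are
    0-based ``(row, col)`` with the origin at the top-left corner; all
    distances throughout the package are in pixel units.
    """

    artery_prob: np.ndarray
    vein_prob: np.ndarray
    vessel_prob: np.ndarray
    od_location: tuple[int, int]
    fovea_location: tuple[int, int]

    def __post_init__(self) -> None:
        self.artery_prob = np.asarray(self.artery_prob, dtype=float)
        self.vein_prob = np.asarray(self.vein_prob, dtype=float)
        self.vessel_prob = np.asarray(self.vessel_prob, dtype=float)
        shape = self.artery_prob.shape
        if self.vein_prob.shape != shape or self.vessel_prob.shape != shape:
            raise ShapeMismatchError(
                f"map shapes differ: artery {shape}, vein {self.vein_prob.shape}, "
                f"vessel {self.vessel_prob.shape}"
            )
        for m in (self.artery_prob, self.vein_prob, self.vessel_prob):
            if m.size and (m.min() < -1e-9 or m.max() > 1 + 1e-9):
                raise ValueError("probability maps must hold values in [0, 1]")
        self.od_location = _check_landmark("optic disc", self.od_location, shape)
        self.fovea_location = _check_landmark("fovea", self.fovea_location, shape)

    @property
    def shape(self) -> tuple[int, int]:
        return self.artery_prob.shape


@dataclass
class Heatmap:
    """Landmark-regression heatmap with its decay scale ``beta`` (px)."""

    values: np.ndarray
    beta: float = field(default=60.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def encode_heatmap(
    location: tuple[int, int], beta: float, shape: tuple[int, int]
) -> Heatmap:
    """Encode a landmark as ``y = 1 + tanh(-d * pi / beta)``.

    ``d`` is the Euclidean pixel distance to ``location``; the map equals 1
    at the target and decays towards 0, reaching ``1 + tanh(-pi)`` ≈ 3.7e-3
    at ``d = beta``.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    r0, c0 = _check_landmark("target", location, shape)
    rows = np.arange(shape[0])[:, None] - r0
    cols = np.arange(shape[1])[None, :] - c0
    d = np.hypot(rows, cols)
    return Heatmap(values=1.0 + np.tanh(-d * np.pi / beta), beta=float(beta))


def decode_landmark(h: Heatmap | np.ndarray) -> tuple[int, int]:
    """Locate a landmark as the heatmap argmax (first in row-major order)."""
    values = h.values if isinstance(h, Heatmap) else np.asarray(h)
    if values.size == 0:
        raise ValueError("cannot decode a landmark from an empty heatmap")
    r, c = np.unravel_index(int(np.argmax(values)), values.shape)
    return (int(r), int(c))


# ---------------------------------------------------------------------------
# file round-trip
# ---------------------------------------------------------------------------

_MAP_FILES = {"artery": "artery.png", "vein": "vein.png", "vessel": "vessel.png"}


def _read_gray(path: Path) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # collapse accidental RGB
        arr = arr[..., 0]
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return arr.astype(float) / 255.0


def write_bundle(bundle: AnatomyBundle, directory: str | Path) -> dict[str, Path]:
    """Write maps as 8-bit grayscale PNG and landmarks as JSON.

    Pixel values are stored as ``round(255 * p)``; re-reading therefore
    reproduces the maps within 1/255.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    maps = {
        "artery": bundle.artery_prob,
        "vein": bundle.vein_prob,
        "vessel": bundle.vessel_prob,
    }
    written: dict[str, Path] = {}
    for key, arr in maps.items():
        path = directory / _MAP_FILES[key]
        Image.fromarray(np.round(arr * 255).astype(np.uint8)).save(path)
        written[key] = path
    lm_path = directory / "landmarks.json"
    lm_path.write_text(
        json.dumps(
            {"od": list(bundle.od_location), "fovea": list(bundle.fovea_location)}
        )
    )
    written["landmarks"] = lm_path
    return written


def read_bundle(
    directory: str | Path,
    landmark_form: str = "coords",
    beta: float = 60.0,
) -> AnatomyBundle:
    """Read an :class:`AnatomyBundle` from a directory.

    Parameters
    ----------
    landmark_form
        ``"coords"`` reads ``landmarks.json``; ``"heatmap"`` reads
        ``od_heatmap.png`` / ``fovea_heatmap.png`` and decodes them by argmax.
    beta
        Decay scale attached to decoded heatmaps (metadata only).
    """
    directory = Path(directory)
    maps: dict[str, np.ndarray] = {}
    for key, fname in _MAP_FILES.items():
        path = directory / fname
        if not path.exists():
            raise MissingMapError(f"missing {key} map: {path}")
        maps[key] = _read_gray(path)
    shapes = {m.shape for m in maps.values()}
    if len(shapes) > 1:
        raise ShapeMismatchError(f"inconsistent map shapes: {shapes}")

    if landmark_form == "coords":
        lm = json.loads((directory / "landmarks.json").read_text())
        od, fovea = tuple(lm["od"]), tuple(lm["fovea"])
    elif landmark_form == "heatmap":
        od = decode_landmark(Heatmap(_read_gray(directory / "od_heatmap.png"), beta))
        fovea = decode_landmark(
            Heatmap(_read_gray(directory / "fovea_heatmap.png"), beta)
        )
    else:
        raise ValueError(f"unknown landmark_form {landmark_form!r}")

    return AnatomyBundle(
        artery_prob=maps["artery"],
        vein_prob=maps["vein"],
        vessel_prob=maps["vessel"],
        od_location=od,
        fovea_location=fovea,
    )
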