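"""End-to-end assessment of one image: maps -> segments -> factors -> score.

The arterial and venous trees are processed independently with identical
steps: binarize the class probability map, thin it to a skeleton, discard
the optic-disc region, split at junctions, rejoin matching segments, then
measure per-segment anatomical factors and tortuosity. Segments from both
trees are pooled into one image assessment. When only a whole-vessel map is
available the same procedure runs once on it (no-anatomical-factors mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .factors import (
    SegmentFactors,
    compute_av_probability,
    compute_caliber,
    compute_distance,
)
from .graph import detect_junctions, mask_optic_disc, rejoin_segments, skeletonize, split_segments
from .io import AnatomyBundle
from .score import ImageAssessment, WeightConfig
from .tortuosity import path_tortuosity

__all__ = ["PipelineConfig", "extract_segments", "assess_image"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the measurement pipeline (all in px/deg)."""

    binarize_threshold: float = 0.5
    od_radius: float = 60.0
    min_segment_len: int = 10
    dir_tol_deg: float = 30.0
    cal_ratio_tol: float = 0.25
    sg_window: int = 7
    sg_polyorder: int = 2
    gauss_sigma: float = 3.0
    eps_curvature: float = 1e-4
    mask_od: bool = True
    subpixel_refine: bool = True


def extract_segments(
    class_prob: np.ndarray,
    od_location: tuple[int, int],
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[np.ndarray], np.ndarray]:
    """Segment paths of one vascular tree plus its binary mask."""
    mask = np.asarray(class_prob, dtype=float) >= config.binarize_threshold
    skel = skeletonize(mask)
    if config.mask_od:
        skel = mask_optic_disc(skel, od_location, r=config.od_radius)
    junctions = detect_junctions(skel)
    paths = split_segments(skel, junctions, min_len=config.min_segment_len)
    if paths:
        calibers = [compute_caliber(mask, p) for p in paths]
        paths = rejoin_segments(
            paths,
            junctions,
            calibers,
            dir_tol_deg=config.dir_tol_deg,
            cal_ratio_tol=config.cal_ratio_tol,
        )
    return paths, mask


def assess_image(
    bundle: AnatomyBundle,
    weights: WeightConfig | None = None,
    config: PipelineConfig = PipelineConfig(),
    trees: tuple[str, ...] = ("artery", "vein"),
) -> ImageAssessment:
    """Score one image: per-segment tortuosity, weighting, global score.

    ``trees`` selects which maps are decomposed; pass ``("vessel",)`` to run
    on the whole-vessel map only (the standard length-weighted mode when no
    artery/vein distinction is available).
    """
    if weights is None:
        weights = WeightConfig.length_only()
    tree_maps = {
        "artery": bundle.artery_prob,
        "vein": bundle.vein_prob,
        "vessel": bundle.vessel_prob,
    }
    all_factors: list[SegmentFactors] = []
    tortuosities: list[float] = []
    all_paths: list[np.ndarray] = []
    tree_tags: list[str] = []
    for tree in trees:
        paths, mask = extract_segments(tree_maps[tree], bundle.od_location, config)
        for path in paths:
            f_av, assigned = compute_av_probability(
                bundle.artery_prob, bundle.vein_prob, path
            )
            factors = SegmentFactors(
                L_c=len(path),
                f_cal=compute_caliber(mask, path),
                f_av=f_av,
                f_dod=compute_distance(bundle.od_location, path),
                f_dfov=compute_distance(bundle.fovea_location, path),
                assigned_class=assigned,
            )
            tau = path_tortuosity(
                path,
                soft_map=tree_maps[tree] if config.subpixel_refine else None,
                window=config.sg_window,
                polyorder=config.sg_polyorder,
                sigma=config.gauss_sigma,
                eps_k=config.eps_curvature,
                profile_halfwidth=factors.f_cal / 2.0 + 3.0,
            )
            all_factors.append(factors)
            tortuosities.append(tau)
            all_paths.append(path)
            tree_tags.append(tree)
    return ImageAssessment.from_measurements(
        all_factors, tortuosities, weights, paths=all_paths, trees=tree_tags
    )
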