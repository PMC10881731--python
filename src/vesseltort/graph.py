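"""Decomposition of a binary vascular map into individual vessel segments.

The vascular tree is thinned to a 1-px skeleton (Zhang-Suen), pixels inside
the optic-disc region are discarded, junctions are located with a
hit-or-miss transform over all rotations of the T- and Y-shaped 3x3
patterns, the skeleton is split at the junctions, and finally pairs of
segments that meet at a junction with matching directions and calibers are
rejoined into a single vessel. Arterial and venous trees are processed
independently with the same procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

__all__ = [
    "Junction",
    "skeletonize",
    "mask_optic_disc",
    "detect_junctions",
    "split_segments",
    "rejoin_segments",
    "trace_path",
]

log = logging.getLogger(__name__)

_N8 = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
# ring order for angular adjacency: E, NE, N, NW, W, SW, S, SE
_RING = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class Junction:
    """A skeleton junction: cluster of hit-or-miss matches and arm count."""

    position: tuple[int, int]
    arms: int
    pixels: frozenset = field(default_factory=frozenset)


def skeletonize(vessel_mask: np.ndarray) -> np.ndarray:
    """1-px-wide skeleton of a binary vascular map (Zhang-Suen thinning)."""
    mask = np.asarray(vessel_mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    return _sk_skeletonize(mask, method="zhang")


def mask_optic_disc(
    skeleton: np.ndarray, od: tuple[int, int], r: float = 60.0
) -> np.ndarray:
    """Remove skeleton pixels within Euclidean distance ``r`` of the optic disc.

    Vessels naturally curve where they enter the retina at the optic disc, so
    this region is excluded from tortuosity analysis.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    skel = np.asarray(skeleton, dtype=bool)
    rows = np.arange(skel.shape[0])[:, None] - od[0]
    cols = np.arange(skel.shape[1])[None, :] - od[1]
    return skel & (np.hypot(rows, cols) > r)


def _junction_lut() -> np.ndarray:
    """256-entry lookup: does a neighbor bitmask match a T or Y pattern?

    All 45-degree rotations of the T pattern (three arms with ring gaps
    {2,2,4}) and of the Y pattern (gaps {2,3,3}) are, with don't-care misses,
    exactly the triples of 8-neighbors that are pairwise non-adjacent on the
    neighbor ring. A bitmask matches if it contains such a triple, so 4-way
    crossings match too.
    """
    lut = np.zeros(256, dtype=bool)
    for bits in range(256):
        on = [i for i in range(8) if bits >> i & 1]
        for tri in combinations(on, 3):
            if all(
                min((a - b) % 8, (b - a) % 8) >= 2 for a, b in combinations(tri, 2)
            ):
                lut[bits] = True
                break
    return lut


_JUNCTION_LUT = _junction_lut()


def _neighbor_bitmask(skel: np.ndarray) -> np.ndarray:
    """Per-pixel bitmask of which ring neighbors are on (ring order)."""
    padded = np.pad(skel.astype(np.uint8), 1)
    bits = np.zeros(skel.shape, dtype=np.uint8)
    for i, (dr, dc) in enumerate(_RING):
        bits |= (
            padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
            << i
        ).astype(np.uint8)
    return bits


def detect_junctions(skeleton: np.ndarray) -> list[Junction]:
    """Hit-or-miss junction detection on a 1-px skeleton.

    Matches of the T/Y foreground templates (background positions are
    don't-care) that fall within the same 8-neighborhood are merged into a
    single junction located at the rounded cluster centroid.
    """
    skel = np.asarray(skeleton, dtype=bool)
    if not skel.any():
        return []
    candidates = skel & _JUNCTION_LUT[_neighbor_bitmask(skel)]
    if not candidates.any():
        return []
    labels, n = ndimage.label(candidates, structure=np.ones((3, 3), dtype=int))
    junctions: list[Junction] = []
    for lab in range(1, n + 1):
        rr, cc = np.nonzero(labels == lab)
        pixels = frozenset(zip(rr.tolist(), cc.tolist()))
        # representative position: matched pixel nearest the cluster
        # centroid, ties broken in row-major order
        cr, cc_mean = rr.mean(), cc.mean()
        pos = min(
            sorted(pixels),
            key=lambda p: ((p[0] - cr) ** 2 + (p[1] - cc_mean) ** 2),
        )
        # arms = branches leaving the cluster = components of the skeleton
        # restricted to the cluster's immediate surroundings minus the cluster
        r0, r1 = max(rr.min() - 1, 0), min(rr.max() + 2, skel.shape[0])
        c0, c1 = max(cc.min() - 1, 0), min(cc.max() + 2, skel.shape[1])
        local = skel[r0:r1, c0:c1].copy()
        for r, c in pixels:
            local[r - r0, c - c0] = False
        _, arms = ndimage.label(local, structure=np.ones((3, 3), dtype=int))
        junctions.append(Junction(position=pos, arms=max(int(arms), 3), pixels=pixels))
    return junctions


def trace_path(component: set[tuple[int, int]]) -> list[tuple[int, int]]:
    """Order the pixels of a 1-px-wide connected curve endpoint to endpoint.

    Cyclic components without endpoints are traced from their lowest
    row-major pixel (a warning is logged).
    """
    if not component:
        return []

    def neighbors(p):
        return [(p[0] + dr, p[1] + dc) for dr, dc in _N8 if (p[0] + dr, p[1] + dc) in component]

    endpoints = sorted(p for p in component if len(neighbors(p)) <= 1)
    if endpoints:
        start = endpoints[0]
    else:
        start = min(component)
        log.warning("cyclic skeleton component traced from %s", start)
    path = [start]
    visited = {start}
    current = start
    while True:
        nxt = [p for p in neighbors(current) if p not in visited]
        if not nxt:
            break
        if len(nxt) > 1:
            # prefer 4-adjacent continuation so diagonal shortcuts do not
            # skip pixels of a staircase
            nxt.sort(key=lambda p: (abs(p[0] - current[0]) + abs(p[1] - current[1]), p))
        current = nxt[0]
        visited.add(current)
        path.append(current)
    if len(path) < len(component):
        log.warning(
            "trace covered %d of %d pixels of a component", len(path), len(component)
        )
    return path


def split_segments(
    skeleton: np.ndarray,
    junctions: list[Junction],
    min_len: int = 10,
) -> list[np.ndarray]:
    """Split the skeleton at junctions into ordered pixel paths.

    Junction pixels are removed, each remaining connected curve is traced
    into an ordered path, and paths shorter than ``min_len`` pixels are
    dropped (they are below the scale of the smoothing filter).
    """
    skel = np.asarray(skeleton, dtype=bool).copy()
    for j in junctions:
        for r, c in j.pixels:
            skel[r, c] = False
    labels, n = ndimage.label(skel, structure=np.ones((3, 3), dtype=int))
    paths: list[np.ndarray] = []
    for lab in range(1, n + 1):
        rr, cc = np.nonzero(labels == lab)
        comp = set(zip(rr.tolist(), cc.tolist()))
        # components are usually simple arcs, but degree-3 pixels whose arms
        # are not T/Y-shaped survive junction removal; trace repeatedly so
        # every pixel of a branched component is assigned to some path
        while comp:
            path = trace_path(comp)
            comp -= set(path)
            if len(path) >= max(min_len, 2):
                paths.append(np.asarray(path, dtype=int))
    return paths


def _end_direction(path: np.ndarray, end: str, window: int = 10) -> np.ndarray:
    """Unit tangent at a path end, oriented outward (towards the end).

    The direction is the principal axis of the last ``min(window, len)``
    pixels, fitted by least squares.
    """
    pts = path[-window:] if end == "tail" else path[:window][::-1]
    pts = np.asarray(pts, dtype=float)
    centered = pts - pts.mean(axis=0)
    # principal direction via SVD
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    u = vt[0]
    # orient from interior towards the terminal pixel
    if np.dot(pts[-1] - pts[0], u) < 0:
        u = -u
    n = np.hypot(*u)
    return u / n if n > 0 else u


def _order_connector(
    pixels: frozenset, start: tuple[int, int]
) -> list[tuple[int, int]]:
    remaining = set(pixels)
    ordered: list[tuple[int, int]] = []
    cur = np.asarray(start, dtype=float)
    while remaining:
        nxt = min(remaining, key=lambda p: float(np.hypot(p[0] - cur[0], p[1] - cur[1])))
        ordered.append(nxt)
        remaining.discard(nxt)
        cur = np.asarray(nxt, dtype=float)
    return ordered


def rejoin_segments(
    paths: list[np.ndarray],
    junctions: list[Junction],
    calibers: dict[int, float] | list[float],
    dir_tol_deg: float = 30.0,
    cal_ratio_tol: float = 0.25,
    tangent_window: int = 10,
) -> list[np.ndarray]:
    """Rejoin split segments whose directions and calibers match.

    At each junction, among the incident path ends, pairs whose end tangents
    are anti-parallel within ``dir_tol_deg`` and whose caliber ratio lies in
    ``[1 - cal_ratio_tol, 1 / (1 - cal_ratio_tol)]`` are merged through the
    junction (best-matching pairs first). Junction pixels are inserted as a
    connector and may be shared between merged paths, mirroring the
    multi-label convention at vessel crossings.
    """
    if isinstance(calibers, dict):
        cal = dict(calibers)
    else:
        cal = {i: float(c) for i, c in enumerate(calibers)}
    pool: dict[int, np.ndarray] = {i: np.asarray(p) for i, p in enumerate(paths)}
    cos_thresh = -np.cos(np.deg2rad(dir_tol_deg))
    lo, hi = 1.0 - cal_ratio_tol, 1.0 / (1.0 - cal_ratio_tol)
    next_id = len(paths)

    for junction in junctions:
        jpx = junction.pixels or frozenset({junction.position})
        # collect incident (path_id, which_end) whose terminal pixel touches
        # the junction cluster (chebyshev distance <= 1)
        incident: list[tuple[int, str]] = []
        for pid, p in pool.items():
            for end, term in (("head", p[0]), ("tail", p[-1])):
                if any(
                    max(abs(int(term[0]) - r), abs(int(term[1]) - c)) <= 1
                    for r, c in jpx
                ):
                    incident.append((pid, end))
        # score all candidate pairs
        candidates = []
        for (p1, e1), (p2, e2) in combinations(incident, 2):
            if p1 == p2:
                continue
            u1 = _end_direction(pool[p1] if e1 == "tail" else pool[p1][::-1], "tail", tangent_window)
            u2 = _end_direction(pool[p2] if e2 == "tail" else pool[p2][::-1], "tail", tangent_window)
            cosang = float(np.dot(u1, u2))
            if cosang > cos_thresh:
                continue  # not anti-parallel enough
            ratio = cal[p1] / cal[p2] if cal[p2] > 0 else np.inf
            if not (lo <= ratio <= hi):
                continue
            candidates.append((cosang, p1, e1, p2, e2))
        candidates.sort(key=lambda t: t[0])  # most anti-parallel first
        used: set[int] = set()
        for cosang, p1, e1, p2, e2 in candidates:
            if p1 in used or p2 in used or p1 not in pool or p2 not in pool:
                continue
            a = pool.pop(p1)
            b = pool.pop(p2)
            if e1 == "head":
                a = a[::-1]
            if e2 == "tail":
                b = b[::-1]
            connector = _order_connector(jpx, tuple(a[-1]))
            merged = np.vstack([a, np.asarray(connector, dtype=int), b])
            la, lb = len(a), len(b)
            cal[next_id] = (cal[p1] * la + cal[p2] * lb) / (la + lb)
            pool[next_id] = merged
            used.update((p1, p2))
            next_id += 1
    return list(pool.values())
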