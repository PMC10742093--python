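"""Prey visual perception without a full 3-D renderer.

The simulated world contains only uniform-colour cylinders on a flat floor, so
a mate's image is well approximated by an axis-aligned pixel rectangle: its
horizontal extent spans the azimuths ``bearing +/- asin(radius / d)`` mapped
linearly over the horizontal field of view, and its vertical extent spans the
elevation range of the cylinder's nearest surface line (at horizontal distance
``d - radius``) mapped linearly over the vertical field of view.  The percept
is the union of these rectangles, which makes per-step vision O(mates) rather
than O(pixels).  A brute-force per-pixel ray caster lives in the test suite as
the independent oracle for this approximation.

Pixel conventions: pixel ``(u, v)`` has its center at integer coordinates,
``u = 0`` the leftmost column (largest counterclockwise azimuth), ``v = 0``
the top row (largest elevation); the optical axis pierces the image center
``((width-1)/2, (height-1)/2)``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["CameraModel", "VisualPercept", "project_cylinder", "compose_percept"]


@dataclasses.dataclass(frozen=True)
class CameraModel:
    """Ideal pinhole-like camera with linear angle-to-pixel mapping.

    Mounted at ``eye_height`` above the floor (the top of the prey cylinder),
    optical axis horizontal along the agent heading.
    """

    hfov: float = 2.0 * math.pi / 3.0    # radians (120 degrees)
    vfov: float = math.pi / 2.0          # radians (90 degrees)
    width: int = 200
    height: int = 150
    eye_height: float = 5.0

    def __post_init__(self):
        if not 0.0 < self.hfov <= 2.0 * math.pi:
            raise ValueError("hfov must lie in (0, 2*pi]")
        if self.vfov <= 0 or self.width <= 0 or self.height <= 0:
            raise ValueError("vfov and image dimensions must be positive")


@dataclasses.dataclass
class VisualPercept:
    """What one prey sees in one step.

    ``matched_fraction``: proportion of image pixels covered by mates' bodies
    (the colour-matched binary image's non-zero fraction).
    ``largest_apparent``: vertical angular extent of the nearest visible mate
    divided by the vertical field of view, in [0, 1].
    ``nearest_bearing``: world-frame bearing of the nearest visible mate, or
    ``None`` when no mate is visible.
    """

    matched_fraction: float = 0.0
    largest_apparent: float = 0.0
    nearest_bearing: Optional[float] = None
    nearest_distance: Optional[float] = None


def _wrap_pi(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def project_cylinder(
    viewer_pos,
    viewer_heading: float,
    target_pos,
    radius: float,
    height: float,
    camera: CameraModel,
) -> Optional[Tuple[float, float, float, float]]:
    """Image-space rectangle ``(u0, u1, v0, v1)`` of a cylinder, or ``None``.

    ``None`` when the viewer stands on/inside the target (``d <= radius``) or
    when no part of the silhouette's azimuth range intersects the field of
    view.  The rectangle is in continuous pixel coordinates and may extend
    beyond the image; callers clip when rasterising.
    """
    dx = target_pos[0] - viewer_pos[0]
    dy = target_pos[1] - viewer_pos[1]
    d = math.hypot(dx, dy)
    if d <= radius:
        return None
    rel = _wrap_pi(math.atan2(dy, dx) - viewer_heading)
    half = math.asin(radius / d)
    if abs(rel) - half > camera.hfov / 2.0:
        return None
    ppr_h = camera.width / camera.hfov       # pixels per radian, horizontal
    ppr_v = camera.height / camera.vfov
    uc = (camera.width - 1) / 2.0 - rel * ppr_h
    u0 = uc - half * ppr_h
    u1 = uc + half * ppr_h
    x_near = d - radius                       # nearest surface line
    elev_top = math.atan2(height - camera.eye_height, x_near)
    elev_bot = math.atan2(-camera.eye_height, x_near)
    vc = (camera.height - 1) / 2.0
    v0 = vc - elev_top * ppr_v
    v1 = vc - elev_bot * ppr_v
    return (u0, u1, v0, v1)


def _clip_rect_to_pixels(
    rect: Tuple[float, float, float, float], camera: CameraModel
) -> Optional[Tuple[int, int, int, int]]:
    """Integer pixel index ranges (inclusive) whose centers fall in the rect."""
    u0, u1, v0, v1 = rect
    ju0 = max(int(math.ceil(u0)), 0)
    ju1 = min(int(math.floor(u1)), camera.width - 1)
    jv0 = max(int(math.ceil(v0)), 0)
    jv1 = min(int(math.floor(v1)), camera.height - 1)
    if ju0 > ju1 or jv0 > jv1:
        return None
    return (ju0, ju1, jv0, jv1)


def compose_percept(
    viewer_pos,
    viewer_heading: float,
    mate_positions: Sequence,
    radius: float,
    height: float,
    camera: CameraModel,
    _buffer: Optional[np.ndarray] = None,
) -> VisualPercept:
    """Percept of a viewer given its mates' positions (viewer excluded).

    Only mates (same body colour) contribute matched pixels; the predator is
    never passed here.  Occlusion needs no depth sorting for the matched
    fraction — all mates share one colour, so the count is the rectangle
    union — while ``largest_apparent``/``nearest_bearing`` come from the
    nearest visible mate.
    """
    if _buffer is None:
        _buffer = np.zeros((camera.height, camera.width), dtype=bool)
    else:
        _buffer[:] = False
    nearest_d = math.inf
    nearest: Optional[Tuple[float, float]] = None   # (bearing, apparent)
    any_visible = False
    for mp in mate_positions:
        rect = project_cylinder(viewer_pos, viewer_heading, mp, radius, height, camera)
        if rect is None:
            continue
        pix = _clip_rect_to_pixels(rect, camera)
        if pix is None:
            continue
        any_visible = True
        ju0, ju1, jv0, jv1 = pix
        _buffer[jv0 : jv1 + 1, ju0 : ju1 + 1] = True
        d = math.hypot(mp[0] - viewer_pos[0], mp[1] - viewer_pos[1])
        if d < nearest_d:
            nearest_d = d
            bearing = math.atan2(mp[1] - viewer_pos[1], mp[0] - viewer_pos[0])
            # (v1 - v0) pixels / (pixels per radian) / vfov == (v1 - v0) / height
            apparent = min((rect[3] - rect[2]) / camera.height, 1.0)
            nearest = (bearing, apparent)
    if not any_visible:
        return VisualPercept(0.0, 0.0, None, None)
    matched = float(_buffer.sum()) / float(camera.width * camera.height)
    bearing, apparent = nearest  # type: ignore[misc]
    return VisualPercept(matched, apparent, bearing, nearest_d)


def matched_mask(
    viewer_pos,
    viewer_heading: float,
    mate_positions: Sequence,
    radius: float,
    height: float,
    camera: CameraModel,
) -> np.ndarray:
    """Binary colour-matched image (bool, height x width) for inspection."""
    buffer = np.zeros((camera.height, camera.width), dtype=bool)
    compose_percept(
        viewer_pos, viewer_heading, mate_positions, radius, height, camera, _buffer=buffer
    )
    return buffer


def save_pgm(mask: np.ndarray, path) -> None:
    """Write a binary image as a plain-text portable graymap (P2)."""
    h, w = mask.shape
    rows = "\n".join(" ".join("255" if v else "0" for v in row) for row in mask)
    with open(path, "w") as fh:
        fh.write(f"P2\n{w} {h}\n255\n{rows}\n")
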