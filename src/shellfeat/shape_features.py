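"""Centroid Contour Distance (CCD) shape profile.

The shell outline is traced from the binary shell mask as an ordered
closed polyline of border-pixel centres; the area centroid of that
polygon is computed by the shoelace formula; and the distance from the
centroid to the outline is sampled by casting rays at a fixed angular
step (default 5 degrees, hence 72 distances per view).  For a sample the
profiles of both views are concatenated, 144 values in total.

Angles are measured from the +x axis (columns, rightwards), increasing
counter-clockwise in the shared (x, y) frame; distances are in pixels
and deliberately unnormalized — acquisition fixes the image scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon

from .imaging_core import ShellMask, ShellSample

DEFAULT_STEP_DEG = 5

# Moore neighbourhood in clockwise order starting west, as (dy, dx)
_MOORE = (
    (0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1),
)
_DIR_INDEX = {d: i for i, d in enumerate(_MOORE)}


@dataclass(frozen=True)
class Boundary:
    """Ordered closed polyline of (x, y) border-pixel centres."""

    points: np.ndarray  # (n, 2) float, columns (x, y); first point not repeated

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError(f"boundary needs >=3 (x, y) points, got shape {pts.shape}")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class CCDProfile:
    centroid: tuple[float, float]
    distances: np.ndarray  # (360/step,) pixels
    step_deg: float = DEFAULT_STEP_DEG

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(len(self.distances)) * self.step_deg


def extract_boundary(mask: ShellMask) -> Boundary:
    """Trace the outer contour of the mask (Moore-neighbour tracing).

    Expects the single-component, hole-filled mask produced by
    ``shell_mask``.  Returns border-pixel centres ordered counter-clockwise
    in the (x, y) frame (positive shoelace area).
    """
    fg = mask.foreground
    if not fg.any():
        raise ValueError("cannot trace boundary of an empty mask")

    padded = np.pad(fg, 1)
    rows, cols = np.nonzero(padded)
    # start at the topmost-leftmost foreground pixel, entered from the west,
    # so the backtrack direction of the initial state is west (index 0)
    start = (int(rows[0]), int(cols[0]))
    state: tuple[tuple[int, int], int] | None = (start, 0)
    visited = {state}
    contour = [start]
    while True:
        state = _moore_step(padded, *state)
        if state is None or state in visited:
            break
        visited.add(state)
        contour.append(state[0])

    if len(contour) < 3:
        raise ValueError(
            f"degenerate contour with {len(contour)} point(s); mask too small"
        )
    pts = np.array(contour, dtype=np.float64) - 1.0  # undo padding
    xy = pts[:, ::-1].copy()  # (row, col) -> (x, y)
    if _signed_area(xy) < 0:
        xy = xy[::-1].copy()
    return Boundary(xy)


def _moore_step(
    padded: np.ndarray, cur: tuple[int, int], backtrack: int
) -> tuple[tuple[int, int], int] | None:
    """One step of Moore-neighbour tracing.

    Scans the 8-neighbourhood of ``cur`` clockwise starting just after the
    backtrack direction; returns the next border pixel together with its
    backtrack direction (towards the background pixel examined immediately
    before the hit).  ``None`` for an isolated pixel.
    """
    for i in range(1, 9):
        d = (backtrack + i) % 8
        dy, dx = _MOORE[d]
        ny, nx = cur[0] + dy, cur[1] + dx
        if padded[ny, nx]:
            by, bx = _MOORE[(backtrack + i - 1) % 8]
            bg = (cur[0] + by, cur[1] + bx)  # last background pixel seen
            return (ny, nx), _DIR_INDEX[(bg[0] - ny, bg[1] - nx)]
    return None


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def polygon_centroid(boundary: Boundary) -> tuple[float, float]:
    """Area centroid of the closed boundary polygon (shoelace formula)."""
    pts = boundary.points
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if abs(area) < 1e-12:
        raise ValueError("zero-area polygon: centroid undefined")
    cx = float(((x + xn) * cross).sum() / (6.0 * area))
    cy = float(((y + yn) * cross).sum() / (6.0 * area))
    return cx, cy


def ccd_profile(
    boundary: Boundary,
    step: float = DEFAULT_STEP_DEG,
    centroid: tuple[float, float] | None = None,
) -> CCDProfile:
    """Centroid-to-boundary distances at fixed angular increments.

    For each angle a ray is cast from the centroid and the distance to the
    farthest intersection with the boundary polygon is recorded, which
    follows the outer silhouette for mildly concave outlines.  A ray that
    misses every segment numerically falls back to the boundary vertex
    nearest in angle; the profile never contains NaN.
    """
    if step <= 0 or 360 % step:
        raise ValueError(f"step must divide 360, got {step}")
    if centroid is None:
        centroid = polygon_centroid(boundary)
    cx, cy = centroid
    poly = Polygon(boundary.points)
    if not poly.contains(Point(cx, cy)):
        raise ValueError(
            f"centroid ({cx:.2f}, {cy:.2f}) lies outside the boundary polygon; "
            "the outline is too concave for a radial profile"
        )

    pts = boundary.points
    seg_a = pts
    seg_b = np.roll(pts, -1, axis=0)
    ax, ay = seg_a[:, 0] - cx, seg_a[:, 1] - cy
    ex, ey = seg_b[:, 0] - seg_a[:, 0], seg_b[:, 1] - seg_a[:, 1]

    n = int(round(360 / step))
    angles = np.deg2rad(np.arange(n) * step)
    dx, dy = np.cos(angles), np.sin(angles)

    vertex_angles = np.arctan2(ay, ax)
    vertex_dists = np.hypot(ax, ay)

    distances = np.empty(n)
    for i in range(n):
        # ray: t*(dx,dy), t>=0; segment: a + u*e, u in [0,1)
        denom = dx[i] * ey - dy[i] * ex
        with np.errstate(divide="ignore", invalid="ignore"):
            u = (ax * dy[i] - ay * dx[i]) / denom
            t = np.where(np.abs(dx[i]) > np.abs(dy[i]),
                         (ax + u * ex) / dx[i],
                         (ay + u * ey) / dy[i])
        valid = (np.abs(denom) > 1e-12) & (u >= 0.0) & (u <= 1.0) & (t >= 0.0)
        if valid.any():
            distances[i] = t[valid].max()
        else:
            # nearest-vertex fallback for numerical misses
            dang = np.abs(np.angle(np.exp(1j * (vertex_angles - angles[i]))))
            distances[i] = vertex_dists[np.argmin(dang)]
    return CCDProfile(centroid=(cx, cy), distances=distances, step_deg=step)


def ccd_from_mask(mask: ShellMask, step: float = DEFAULT_STEP_DEG) -> CCDProfile:
    """Boundary tracing, centroid and radial profile in one call."""
    return ccd_profile(extract_boundary(mask), step=step)


def shape_feature(
    sample: ShellSample, masks: dict[str, ShellMask], step: float = DEFAULT_STEP_DEG
) -> np.ndarray:
    """Concatenated CCD profile of both views: 72 + 72 = 144 values at
    the default 5-degree step."""
    prof_a = ccd_from_mask(masks["A"], step=step)
    prof_b = ccd_from_mask(masks["B"], step=step)
    return np.concatenate([prof_a.distances, prof_b.distances])


def feature_names(step: float = DEFAULT_STEP_DEG) -> tuple[str, ...]:
    """CSV column names d000A..d355A, d000B..d355B for the given step."""
    angles = [int(a) for a in np.arange(0, 360, step)]
    return tuple(f"d{a:03d}{v}" for v in ("A", "B") for a in angles)
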