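"""Wave-break polylines, signed cross-shore distances, and surveyed areas.

The wave break — the line where waves break, or the seaward edge of the surf
whitewash — is the zero reference for every cross-shore distance in the
analysis.  Distances are signed: negative for subjects between the break and
the beach (shoreward), positive seaward.  All coordinates here are planar
metric (x alongshore, y increasing seaward); geographic input is converted on
read by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "WaveBreakLine",
    "build_wavebreak_line",
    "signed_distance_to_break",
    "signed_distances_to_break",
    "surveyed_area_ha",
]


@dataclass
class WaveBreakLine:
    """Ordered georeferenced polyline separating surf wash from open water.

    ``shore_side`` records which side of the (directed) polyline the beach is
    on: +1 if the shore lies to the left of travel along the vertex order,
    -1 if to the right.  Storing orientation with the line makes the side
    test for an open polyline unambiguous.
    """

    beach: str
    vertices: np.ndarray  # (n, 2) local metric
    shore_side: int = -1  # with x alongshore and y seaward, shore (y small) is right of +x travel

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 2 or self.vertices.shape[1] != 2:
            raise ValueError("WaveBreakLine needs >= 2 (x, y) vertices")
        if self.shore_side not in (-1, 1):
            raise ValueError("shore_side must be +1 (left) or -1 (right)")
        ls = LineString(self.vertices)
        if not ls.is_simple:
            raise ValueError("wave-break polyline self-intersects")
        self._line = ls

    @property
    def line(self) -> LineString:
        return self._line


def build_wavebreak_line(
    traced_points: np.ndarray,
    beach: str = "",
    shore_side: int = -1,
    dedup_tol_m: float = 1.0,
    simplify_tol_m: float = 2.0,
) -> WaveBreakLine:
    """Assemble a wave-break line from points traced on sequential first-leg frames.

    Points are taken in along-track order, deduplicated within ``dedup_tol_m``
    and Douglas-Peucker simplified at ``simplify_tol_m`` (2 m is below the
    distance resolution of any reported measurement).  Raises if fewer than
    two points survive.
    """
    pts = np.asarray(traced_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("traced points must be (n, 2)")
    kept: list[np.ndarray] = []
    for p in pts:
        if not kept or np.hypot(*(p - kept[-1])) > dedup_tol_m:
            kept.append(p)
    if len(kept) < 2:
        raise ValueError("fewer than 2 traced points survive deduplication")
    simplified = LineString(np.array(kept)).simplify(simplify_tol_m, preserve_topology=False)
    verts = np.asarray(simplified.coords)
    return WaveBreakLine(beach=beach, vertices=verts, shore_side=shore_side)


def _side_of_line(break_line: WaveBreakLine, points: np.ndarray) -> np.ndarray:
    """+1 if the point is on the shore side of the line, -1 if seaward, 0 on the line.

    The side is evaluated against the local tangent at the nearest point of
    the polyline.  At a vertex the tangent from shapely's linear referencing
    is the chord across the vertex, equivalent to the angle-bisector
    tie-break.
    """
    line = break_line.line
    length = line.length
    out = np.empty(len(points))
    eps = min(1e-6 * length, 1e-3)
    for i, (px, py) in enumerate(points):
        s = line.project(Point(px, py))
        a = line.interpolate(max(s - eps, 0.0))
        b = line.interpolate(min(s + eps, length))
        tx, ty = b.x - a.x, b.y - a.y
        n = line.interpolate(s)
        cross = tx * (py - n.y) - ty * (px - n.x)
        if cross == 0.0:
            out[i] = 0.0
        else:
            # cross > 0 means the point is left of travel
            out[i] = break_line.shore_side * np.sign(cross)
    return out


def signed_distances_to_break(points: np.ndarray, break_line: WaveBreakLine) -> np.ndarray:
    """Signed nearest distances (m) from points to the wave-break polyline.

    Magnitude is the Euclidean nearest distance to the polyline; the sign is
    negative shoreward of the break, positive seaward.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    from shapely import distance as shp_distance
    from shapely import points as shp_points

    mags = shp_distance(break_line.line, shp_points(pts))
    sides = _side_of_line(break_line, pts)
    # shore side -> negative
    signs = np.where(sides > 0, -1.0, np.where(sides < 0, 1.0, 0.0))
    return signs * mags


def signed_distance_to_break(point, break_line: WaveBreakLine) -> float:
    """Signed distance of a single point; see :func:`signed_distances_to_break`."""
    return float(signed_distances_to_break(np.asarray(point)[None, :], break_line)[0])


def surveyed_area_ha(shoreline: np.ndarray, offshore_extent_m: float) -> float:
    """Area (hectares) of the strip between the shoreline and its seaward offset.

    The strip is bounded by the shoreline polyline and the parallel curve
    ``offshore_extent_m`` seaward of it (offset to the left of the vertex
    order, i.e. toward +y for a west-to-east shoreline).
    """
    verts = np.asarray(shoreline, dtype=float)
    if verts.ndim != 2 or len(verts) < 2:
        raise ValueError("shoreline must be a (n>=2, 2) polyline")
    line = LineString(verts)
    if line.length <= 0:
        raise ValueError("degenerate shoreline of zero length")
    if offshore_extent_m <= 0:
        raise ValueError("offshore extent must be positive")
    offset = line.offset_curve(offshore_extent_m, join_style="round")
    off = np.asarray(offset.coords)
    ring = np.vstack([verts, off[::-1]])
    poly = Polygon(ring)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.is_empty or poly.area <= 0:
        raise ValueError("degenerate survey strip polygon")
    return poly.area / 1e4
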