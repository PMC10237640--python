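"""2-D kernel density surfaces and highest-density-region overlap.

Beach-specific space use is summarised by kernel density estimates of
observation locations; the 50% and 95% highest-density regions (HDR) give
core and full use areas, and intersections of the 95% regions of two groups
quantify their spatial overlap.

The estimator is an axis-aligned Gaussian product kernel evaluated on a
regular grid, with per-axis normal-reference bandwidths
h = 1.06 * min(sd, IQR/1.34) * n^(-1/5).  HDR contour levels are found by
inverting the density-mass relationship on the grid (sort cells by density,
accumulate mass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KDESurface", "kde_surface", "kde_overlap", "reference_bandwidth"]


def reference_bandwidth(x: np.ndarray) -> float:
    """Normal-reference rule bandwidth for one axis."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("degenerate (zero-variance) axis for KDE")
    return 1.06 * spread * n ** (-0.2)


@dataclass
class KDESurface:
    """A gridded 2-D density with its HDR contour levels."""

    xs: np.ndarray          # (nx,) grid centres
    ys: np.ndarray          # (ny,)
    density: np.ndarray     # (ny, nx)
    bandwidths: tuple[float, float]
    levels: dict            # mass -> density level

    @property
    def cell_area(self) -> float:
        return float((self.xs[1] - self.xs[0]) * (self.ys[1] - self.ys[0]))

    def mass(self) -> float:
        return float(self.density.sum() * self.cell_area)

    def hdr_mask(self, mass: float) -> np.ndarray:
        return self.density >= self.levels[mass]

    def hdr_area(self, mass: float) -> float:
        """Area (m^2 in metric coordinates) of the HDR containing `mass`."""
        return float(self.hdr_mask(mass).sum()) * self.cell_area


def _hdr_levels(density: np.ndarray, cell_area: float, masses) -> dict:
    flat = np.sort(density.ravel())[::-1]
    cum = np.cumsum(flat) * cell_area
    total = cum[-1]
    levels = {}
    for m in masses:
        idx = int(np.searchsorted(cum, m * total))
        idx = min(idx, len(flat) - 1)
        levels[m] = float(flat[idx])
    return levels


def kde_surface(points: np.ndarray, grid_size: int = 128, pad_bandwidths: float = 3.0,
                bounds: tuple | None = None, masses=(0.5, 0.95)) -> KDESurface:
    """Evaluate the product-Gaussian KDE of 2-D points on a regular grid.

    The grid spans the data bounding box expanded by ``pad_bandwidths``
    bandwidths per side (or explicit ``bounds`` (xmin, xmax, ymin, ymax), so
    two surfaces can share a grid).  Needs >= 10 points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 10:
        raise ValueError("need at least 10 points for a KDE")
    hx = reference_bandwidth(pts[:, 0])
    hy = reference_bandwidth(pts[:, 1])
    if bounds is None:
        xmin, xmax = pts[:, 0].min() - pad_bandwidths * hx, pts[:, 0].max() + pad_bandwidths * hx
        ymin, ymax = pts[:, 1].min() - pad_bandwidths * hy, pts[:, 1].max() + pad_bandwidths * hy
    else:
        xmin, xmax, ymin, ymax = bounds
    xs = np.linspace(xmin, xmax, grid_size)
    ys = np.linspace(ymin, ymax, grid_size)
    # separable kernel: density = (Kx @ Ky^T terms) summed over points
    ux = (xs[None, :] - pts[:, 0][:, None]) / hx   # (n, nx)
    uy = (ys[None, :] - pts[:, 1][:, None]) / hy   # (n, ny)
    kx = np.exp(-0.5 * ux**2) / (hx * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * uy**2) / (hy * np.sqrt(2 * np.pi))
    density = ky.T @ kx / len(pts)                 # (ny, nx)
    cell = float((xs[1] - xs[0]) * (ys[1] - ys[0]))
    levels = _hdr_levels(density, cell, masses)
    return KDESurface(xs=xs, ys=ys, density=density, bandwidths=(hx, hy), levels=levels)


def kde_overlap(points_a: np.ndarray, points_b: np.ndarray, grid_size: int = 128,
                masses=(0.5, 0.95)) -> dict:
    """HDR areas of two point sets and their 95% spatial overlap.

    Both densities are evaluated on one shared grid covering the union
    bounding box.  Returns per-set 50%/95% HDR areas, the symmetric overlap
    area(A95 ∩ B95) / area(A95 ∪ B95), and the A-conditional overlap
    area(A95 ∩ B95) / area(A95) (with A the shark set, the fraction of
    shark space use shared with people).
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    ha = [reference_bandwidth(a[:, i]) for i in (0, 1)]
    hb = [reference_bandwidth(b[:, i]) for i in (0, 1)]
    pad = 3.0
    xmin = min(a[:, 0].min() - pad * ha[0], b[:, 0].min() - pad * hb[0])
    xmax = max(a[:, 0].max() + pad * ha[0], b[:, 0].max() + pad * hb[0])
    ymin = min(a[:, 1].min() - pad * ha[1], b[:, 1].min() - pad * hb[1])
    ymax = max(a[:, 1].max() + pad * ha[1], b[:, 1].max() + pad * hb[1])
    bounds = (xmin, xmax, ymin, ymax)
    surf_a = kde_surface(a, grid_size=grid_size, bounds=bounds, masses=masses)
    surf_b = kde_surface(b, grid_size=grid_size, bounds=bounds, masses=masses)
    m95a = surf_a.hdr_mask(0.95)
    m95b = surf_b.hdr_mask(0.95)
    cell = surf_a.cell_area
    inter = float((m95a & m95b).sum()) * cell
    union = float((m95a | m95b).sum()) * cell
    return {
        "surface_a": surf_a,
        "surface_b": surf_b,
        "area_a": {m: surf_a.hdr_area(m) for m in masses},
        "area_b": {m: surf_b.hdr_area(m) for m in masses},
        "overlap_fraction": inter / union if union > 0 else float("nan"),
        "conditional_overlap_a": inter / surf_a.hdr_area(0.95),
        "intersection_area": inter,
    }
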