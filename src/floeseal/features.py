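"""Per-floe covariates from rasters and points, plus the survey filters.

Works in planar scene coordinates: metres, origin at the raster's top-left
corner, y increasing downward; a pixel's value is attributed to its centre.
Sea-ice concentration (SIC) is the ice fraction in a metric buffer taken from
the floe's *boundary* (not its centroid), with the focal floe's own pixels
excluded so a large floe does not dominate its own covariate.  Bathymetric
terrain metrics use 3x3 focal windows — slope as the central-difference
gradient magnitude, TRI as the mean absolute difference from the centre cell,
roughness as the window max minus min — averaged over a metric circle.

Feature extraction has no randomness; the only seeded operation here is the
stratified size-bin subsample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import Point

__all__ = [
    "SceneRasters",
    "ColonySet",
    "sic_at_radius",
    "bathy_metrics",
    "colony_distance",
    "edge_filter",
    "stratified_sample",
    "build_feature_table",
    "SIC_RADII",
]

#: Buffer radii (m) at which sea-ice concentration is evaluated.
SIC_RADII = (150, 250, 500, 750, 1000)


@dataclass
class SceneRasters:
    """Co-registered ice mask and bathymetry grids for one scene."""

    ice_mask: np.ndarray
    bathymetry: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.ice_mask = np.asarray(self.ice_mask, dtype=bool)
        self.bathymetry = np.asarray(self.bathymetry, dtype=float)
        if self.ice_mask.shape != self.bathymetry.shape:
            raise ValueError("ice mask and bathymetry grids must share a shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        ox, oy = self.origin
        ny, nx = self.ice_mask.shape
        return (ox, oy, ox + nx * self.pixel_size, oy + ny * self.pixel_size)

    def pixel_centers(self, i0, i1, j0, j1):
        ox, oy = self.origin
        xs = ox + (np.arange(j0, j1) + 0.5) * self.pixel_size
        ys = oy + (np.arange(i0, i1) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    @property
    def focal_grids(self):
        """Cached (slope, tri, roughness) focal-metric grids."""
        if not hasattr(self, "_focal"):
            self._focal = _focal_metrics(self.bathymetry, self.pixel_size)
        return self._focal


@dataclass
class ColonySet:
    """Penguin colony point locations in scene coordinates."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size and self.points.shape[1] != 2:
            raise ValueError("colony points must be (n, 2)")


def _floe_geometry(floe):
    geom = None
    if isinstance(floe, pd.Series):
        geom = floe.get("geometry")
        if geom is None or (isinstance(geom, float) and np.isnan(geom)):
            r = np.sqrt(float(floe["area"]) / np.pi)
            geom = Point(float(floe["x"]), float(floe["y"])).buffer(r, quad_segs=32)
    elif isinstance(floe, shapely.Geometry):
        geom = floe
    if geom is None:
        raise TypeError("floe must be a record with geometry/x/y/area or a shapely geometry")
    return geom


def sic_at_radius(rasters: SceneRasters, floe, radius: float) -> float:
    """Sea-ice concentration in a buffer of ``radius`` around one floe.

    Fraction of pixels whose centres lie within ``radius`` of the floe
    boundary (outside the floe itself) that are ice.  Raises when the buffer
    would extend past the scene bounds — edge-filter first.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    geom = _floe_geometry(floe)
    minx, miny, maxx, maxy = geom.bounds
    bx0, by0, bx1, by1 = rasters.bounds
    if (minx - radius < bx0 or miny - radius < by0
            or maxx + radius > bx1 or maxy + radius > by1):
        raise ValueError(
            f"buffer of {radius} m around floe at "
            f"({geom.centroid.x:.0f}, {geom.centroid.y:.0f}) extends past the "
            "scene bounds; apply edge_filter first")
    px = rasters.pixel_size
    ox, oy = rasters.origin
    j0 = int((minx - radius - ox) / px)
    j1 = int(np.ceil((maxx + radius - ox) / px))
    i0 = int((miny - radius - oy) / px)
    i1 = int(np.ceil((maxy + radius - oy) / px))
    cx, cy = rasters.pixel_centers(i0, i1, j0, j1)
    pts = shapely.points(np.c_[cx.ravel(), cy.ravel()])
    dist = shapely.distance(geom, pts).reshape(cx.shape)
    sel = (dist > 0) & (dist <= radius)
    if not sel.any():
        raise ValueError("buffer contains no pixel centres; radius below pixel size?")
    return float(rasters.ice_mask[i0:i1, j0:j1][sel].mean())


def _sic_all_radii(rasters: SceneRasters, floe, radii) -> dict[int, float]:
    """SIC at several radii from a single distance field (max radius window)."""
    rmax = float(max(radii))
    geom = _floe_geometry(floe)
    minx, miny, maxx, maxy = geom.bounds
    bx0, by0, bx1, by1 = rasters.bounds
    if (minx - rmax < bx0 or miny - rmax < by0
            or maxx + rmax > bx1 or maxy + rmax > by1):
        raise ValueError(
            f"buffer of {rmax} m around floe at "
            f"({geom.centroid.x:.0f}, {geom.centroid.y:.0f}) extends past the "
            "scene bounds; apply edge_filter first")
    px = rasters.pixel_size
    ox, oy = rasters.origin
    j0 = int((minx - rmax - ox) / px)
    j1 = int(np.ceil((maxx + rmax - ox) / px))
    i0 = int((miny - rmax - oy) / px)
    i1 = int(np.ceil((maxy + rmax - oy) / px))
    cx, cy = rasters.pixel_centers(i0, i1, j0, j1)
    pts = shapely.points(np.c_[cx.ravel(), cy.ravel()])
    dist = shapely.distance(geom, pts).reshape(cx.shape)
    ice = rasters.ice_mask[i0:i1, j0:j1]
    out = {}
    for r in radii:
        sel = (dist > 0) & (dist <= float(r))
        if not sel.any():
            raise ValueError(f"no pixel centres in the {r} m buffer")
        out[int(r)] = float(ice[sel].mean())
    return out


def _focal_metrics(bathy: np.ndarray, px: float):
    """3x3 focal slope, TRI and roughness grids (edges are NaN)."""
    gy, gx = np.gradient(bathy, px)
    slope = np.hypot(gx, gy)
    tri = np.zeros_like(bathy)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            tri += np.abs(np.roll(np.roll(bathy, di, 0), dj, 1) - bathy)
    tri /= 8.0
    rough = (ndimage.maximum_filter(bathy, size=3)
             - ndimage.minimum_filter(bathy, size=3))
    for grid in (slope, tri, rough):
        grid[0, :] = grid[-1, :] = np.nan
        grid[:, 0] = grid[:, -1] = np.nan
    return slope, tri, rough


def bathy_metrics(rasters: SceneRasters, center, radius: float) -> dict[str, float]:
    """Mean bathymetric slope, TRI and roughness in a circle around a point.

    Per-pixel 3x3 focal metrics averaged over pixels whose centres fall
    within ``radius`` of ``center``; the circle (plus the one-pixel focal
    margin) must sit inside the raster extent.
    """
    px = rasters.pixel_size
    if radius < px:
        raise ValueError(f"radius {radius} m is below one pixel ({px} m)")
    x0, y0 = float(center[0]), float(center[1])
    bx0, by0, bx1, by1 = rasters.bounds
    if (x0 - radius < bx0 + px or y0 - radius < by0 + px
            or x0 + radius > bx1 - px or y0 + radius > by1 - px):
        raise ValueError("metric circle extends past the raster extent")
    slope, tri, rough = rasters.focal_grids
    ox, oy = rasters.origin
    j0 = int((x0 - radius - ox) / px)
    j1 = int(np.ceil((x0 + radius - ox) / px))
    i0 = int((y0 - radius - oy) / px)
    i1 = int(np.ceil((y0 + radius - oy) / px))
    cx, cy = rasters.pixel_centers(i0, i1, j0, j1)
    sel = (cx - x0) ** 2 + (cy - y0) ** 2 <= radius ** 2
    return {
        "slope": float(np.nanmean(slope[i0:i1, j0:j1][sel])),
        "tri": float(np.nanmean(tri[i0:i1, j0:j1][sel])),
        "roughness": float(np.nanmean(rough[i0:i1, j0:j1][sel])),
    }


def colony_distance(centroid, colonies: ColonySet) -> float:
    """Planar distance (m) from a floe centroid to the nearest colony."""
    if colonies.points.size == 0:
        raise ValueError("colony set is empty")
    d = np.hypot(colonies.points[:, 0] - centroid[0],
                 colonies.points[:, 1] - centroid[1])
    return float(d.min())


def edge_filter(floes: pd.DataFrame, bounds, buffer: float = 1000.0):
    """Drop floes within ``buffer`` metres of the scene edge.

    A floe is retained iff its whole polygon lies inside the rectangle inset
    by ``buffer`` from ``bounds = (minx, miny, maxx, maxy)``.  Returns
    ``(retained, report)`` where the report lists excluded floe ids and the
    total seal count removed (0 when counts are not yet assigned).
    """
    minx, miny, maxx, maxy = map(float, bounds)
    if buffer >= min(maxx - minx, maxy - miny) / 2.0:
        raise ValueError(
            f"edge buffer {buffer} m leaves no scene interior "
            f"({maxx - minx:.0f} x {maxy - miny:.0f} m)")
    keep = np.empty(len(floes), dtype=bool)
    for k, (_, row) in enumerate(floes.iterrows()):
        gminx, gminy, gmaxx, gmaxy = _floe_geometry(row).bounds
        keep[k] = (gminx >= minx + buffer and gminy >= miny + buffer
                   and gmaxx <= maxx - buffer and gmaxy <= maxy - buffer)
    retained = floes.loc[keep].reset_index(drop=True)
    excluded = floes.loc[~keep]
    report = {
        "n_excluded": int((~keep).sum()),
        "excluded_ids": excluded["floe_id"].tolist() if "floe_id" in floes else [],
        "excluded_seals": int(excluded["seal_count"].sum())
        if "seal_count" in floes else 0,
        "buffer_m": buffer,
    }
    return retained, report


def stratified_sample(floes: pd.DataFrame, n_bins: int = 20,
                      per_bin: int = 3000, seed: int = 0) -> pd.DataFrame:
    """Size-stratified subsample: up to ``per_bin`` floes per log-area bin.

    Areas are split into ``n_bins`` log-spaced bins over the observed range;
    within each bin floes are drawn uniformly without replacement (all are
    kept when a bin holds fewer than ``per_bin``).
    """
    if len(floes) == 0:
        raise ValueError("cannot sample from an empty floe table")
    if n_bins < 1 or per_bin < 1:
        raise ValueError("n_bins and per_bin must be >= 1")
    a = floes["area"].to_numpy(dtype=float)
    edges = np.geomspace(a.min(), a.max(), n_bins + 1)
    edges[-1] *= 1.0 + 1e-12
    which = np.clip(np.digitize(a, edges) - 1, 0, n_bins - 1)
    rng = np.random.default_rng(seed)
    chosen = []
    for b in range(n_bins):
        idx = np.flatnonzero(which == b)
        if idx.size == 0:
            continue
        if idx.size <= per_bin:
            chosen.append(idx)
        else:
            chosen.append(rng.choice(idx, size=per_bin, replace=False))
    take = np.sort(np.concatenate(chosen))
    return floes.iloc[take].reset_index(drop=True)


def build_feature_table(floes: pd.DataFrame, rasters: SceneRasters,
                        colonies: ColonySet, radii=SIC_RADII,
                        bathy_radius: float = 1000.0) -> pd.DataFrame:
    """Assemble the full per-floe covariate table.

    Expects edge-filtered floes; returns a copy with ``sic_<r>`` for each
    buffer radius, ``slope_1000``/``tri_1000``/``rough_1000``, ``colony_dist``
    and ``edge_dist`` columns filled.  Row order and count are preserved.
    """
    out = floes.copy()
    cols = [f"sic_{int(r)}" for r in radii] + [
        "slope_1000", "tri_1000", "rough_1000", "colony_dist", "edge_dist"]
    for c in cols:
        out[c] = np.nan
    if len(out) == 0:
        return out
    minx, miny, maxx, maxy = rasters.bounds
    for i, (_, row) in enumerate(floes.iterrows()):
        fid = row.get("floe_id", i)
        try:
            geom = _floe_geometry(row)
            cx, cy = geom.centroid.x, geom.centroid.y
            sic = _sic_all_radii(rasters, row, radii)
            for r in radii:
                out.iloc[i, out.columns.get_loc(f"sic_{int(r)}")] = sic[int(r)]
            m = bathy_metrics(rasters, (cx, cy), bathy_radius)
            out.iloc[i, out.columns.get_loc("slope_1000")] = m["slope"]
            out.iloc[i, out.columns.get_loc("tri_1000")] = m["tri"]
            out.iloc[i, out.columns.get_loc("rough_1000")] = m["roughness"]
            out.iloc[i, out.columns.get_loc("colony_dist")] = \
                colony_distance((cx, cy), colonies)
            gb = geom.bounds
            out.iloc[i, out.columns.get_loc("edge_dist")] = min(
                gb[0] - minx, gb[1] - miny, maxx - gb[2], maxy - gb[3])
        except ValueError as exc:
            raise ValueError(f"covariate extraction failed for floe {fid}: {exc}") from exc
    return out
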