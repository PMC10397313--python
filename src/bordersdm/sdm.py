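"""The scanning and digitization model (SDM) of the tumor border.

The border between tumor and paratumor liver is recovered from the spot
annotation alone: hepatocyte spots are rasterized into a binary mask, scatter
is removed by windowed thresholding and largest-component selection, the
mask boundary is traced and smoothed by a least-squares cubic spline, and the
smoothed border is digitized into six 250 µm offset layers (three per side,
tumor side negative) plus a 250 µm-wide "distant" reference band 2 mm from
the border on each side. Each layer is cut into ``n_tiles`` tiles of
approximately equal area along the border, and every spot is assigned a
(layer, tile) index by a cross-product point-in-polygon test.

Distances are in µm everywhere. The paratumor (hepatocyte) side carries
positive signed distance; layer +1 is the first paratumor layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.interpolate import LSQUnivariateSpline
from scipy.ndimage import binary_fill_holes, uniform_filter
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point, Polygon, box as shapely_box
from shapely.ops import split as shapely_split
from skimage import measure

from .config import (
    DISTANT_BAND_UM,
    DISTANT_LABEL,
    LAYER_HALF_WIDTHS_UM,
    N_TILES,
    NONE_LABEL,
    SPLINE_DF,
)

__all__ = [
    "BinaryMask",
    "BorderCurve",
    "LayerSet",
    "SdmError",
    "build_mask",
    "denoise_mask",
    "extract_contour",
    "smooth_border",
    "signed_distance",
    "build_layers",
    "tile_layer",
    "build_tiles",
    "assign_spots",
    "digitize_slide",
]

RESAMPLE_UM = 5.0  # maximum vertex spacing of border curves


class SdmError(RuntimeError):
    """Geometry failure in the scanning and digitization model."""


# ---------------------------------------------------------------------------
# Binary mask

@dataclass
class BinaryMask:
    """Raster of hepatocyte-positive pixels; pixel (iy, ix) covers
    [ix*pixel_um, (ix+1)*pixel_um) × [iy*pixel_um, (iy+1)*pixel_um)."""

    pixels: np.ndarray  # bool, shape (ny, nx)
    pixel_um: float

    @property
    def extent_um(self) -> tuple[float, float]:
        ny, nx = self.pixels.shape
        return (nx * self.pixel_um, ny * self.pixel_um)


def build_mask(
    annotation: pd.DataFrame,
    pixel_um: float = 25.0,
    extent_um: tuple[float, float] | None = None,
    hepatocyte_label: str = "hepatocyte",
) -> BinaryMask:
    """Rasterize hepatocyte spot centroids into a binary mask.

    A pixel is foreground iff at least one spot annotated as hepatocyte has
    its centroid inside it.
    """
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    hep = annotation[annotation["cell_type"] == hepatocyte_label]
    if hep.empty:
        raise SdmError("no hepatocyte spots: cannot build the border mask")
    x = hep["x_um"].to_numpy(dtype=float)
    y = hep["y_um"].to_numpy(dtype=float)
    if extent_um is None:
        extent_um = (
            float(annotation["x_um"].max()) + pixel_um,
            float(annotation["y_um"].max()) + pixel_um,
        )
    nx = int(np.ceil(extent_um[0] / pixel_um))
    ny = int(np.ceil(extent_um[1] / pixel_um))
    ix = np.clip((x // pixel_um).astype(int), 0, nx - 1)
    iy = np.clip((y // pixel_um).astype(int), 0, ny - 1)
    pixels = np.zeros((ny, nx), dtype=bool)
    pixels[iy, ix] = True
    return BinaryMask(pixels=pixels, pixel_um=float(pixel_um))


def denoise_mask(mask: BinaryMask, window: int = 5, keep_fraction: float = 0.4) -> BinaryMask:
    """Windowed-threshold scatter filtering, then largest-component selection.

    A foreground pixel is retained iff the foreground fraction in its
    ``window`` × ``window`` neighbourhood is at least ``keep_fraction``;
    afterwards only the largest connected foreground component survives.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    # "nearest" avoids eroding foreground along the slide frame, which would
    # bend the extracted border away from the edges it should meet
    frac = uniform_filter(mask.pixels.astype(float), size=window, mode="nearest")
    # threshold the local foreground fraction itself: removes isolated scatter
    # and fills speckle holes left by imperfect single-spot typing
    kept = frac >= keep_fraction - 1e-12
    kept = binary_fill_holes(kept)
    labels, n = measure.label(kept, connectivity=2, return_num=True)
    if n == 0:
        raise SdmError("denoising removed every foreground pixel")
    sizes = np.bincount(labels.ravel())[1:]
    keep_label = int(np.argmax(sizes)) + 1
    return BinaryMask(pixels=labels == keep_label, pixel_um=mask.pixel_um)


# ---------------------------------------------------------------------------
# Contour extraction and spline smoothing

def extract_contour(mask: BinaryMask) -> np.ndarray:
    """Trace the boundary of the (single-component) mask as an open polyline.

    Returns an (N, 2) array of (x, y) µm positions. The marching-squares
    boundary is clipped to the slide interior: vertices hugging the raster
    frame are dropped and the longest interior run is kept.
    """
    contours = measure.find_contours(mask.pixels.astype(float), 0.5)
    if not contours:
        raise SdmError(
            "mask has no interior boundary (fully foreground or fully background)"
        )

    def _arclen(c: np.ndarray) -> float:
        return float(np.sum(np.hypot(*np.diff(c, axis=0).T)))

    contour = max(contours, key=_arclen)  # (row=y_px, col=x_px)
    xy = np.column_stack([(contour[:, 1] + 0.5), (contour[:, 0] + 0.5)]) * mask.pixel_um
    # drop vertices within half a pixel of the raster frame (slide-edge runs)
    w, h = mask.extent_um
    tol = 0.5 * mask.pixel_um + 1e-9
    interior = (
        (xy[:, 0] > tol) & (xy[:, 0] < w - tol) & (xy[:, 1] > tol) & (xy[:, 1] < h - tol)
    )
    if not interior.any():
        raise SdmError("mask boundary lies entirely on the slide edge")
    # longest contiguous interior run
    runs = np.split(np.arange(len(xy)), np.flatnonzero(np.diff(interior.astype(int)) != 0) + 1)
    runs = [r for r in runs if interior[r[0]]]
    best = max(runs, key=lambda r: _arclen(xy[r]) if len(r) > 1 else 0.0)
    poly = xy[best]
    if len(poly) < 2:
        raise SdmError("degenerate border: interior boundary shorter than one pixel")
    return poly


@dataclass
class BorderCurve:
    """Smoothed border polyline with arc-length parameterization.

    ``vertices`` are (N, 2) µm positions with spacing ≤ 5 µm; ``s`` is the
    cumulative arc length. The curve is oriented so that the paratumor
    (hepatocyte-mask) side is to the left of the direction of travel, i.e.
    signed-positive.
    """

    vertices: np.ndarray
    s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        seg = np.hypot(*np.diff(self.vertices, axis=0).T)
        self.s = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.s[-1])

    @property
    def tangents(self) -> np.ndarray:
        t = np.gradient(self.vertices, self.s, axis=0)
        norm = np.hypot(t[:, 0], t[:, 1])
        return t / norm[:, None]

    @property
    def normals(self) -> np.ndarray:
        """Left-hand unit normals (point to the paratumor side)."""
        t = self.tangents
        return np.column_stack([-t[:, 1], t[:, 0]])

    def reversed(self) -> "BorderCurve":
        return BorderCurve(self.vertices[::-1].copy())

    def as_linestring(self) -> LineString:
        return LineString(self.vertices)

    def curvature(self) -> np.ndarray:
        t = self.tangents
        dtds = np.gradient(t, self.s, axis=0)
        return np.hypot(dtds[:, 0], dtds[:, 1])


def _resample_polyline(xy: np.ndarray, spacing: float = RESAMPLE_UM) -> np.ndarray:
    seg = np.hypot(*np.diff(xy, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(np.ceil(s[-1] / spacing)), 1)
    s_new = np.linspace(0.0, s[-1], n + 1)
    return np.column_stack([np.interp(s_new, s, xy[:, 0]), np.interp(s_new, s, xy[:, 1])])


def smooth_border(
    polyline: np.ndarray,
    df: int = SPLINE_DF,
    orient_mask: BinaryMask | None = None,
) -> BorderCurve:
    """Smooth a raw boundary polyline by least-squares cubic splines.

    x(s) and y(s) are each fit on the arc-length parameter with a cubic
    spline basis of ``df`` degrees of freedom (df − 4 equally spaced interior
    knots), then resampled at ≤ 5 µm spacing. If ``orient_mask`` is given,
    the curve is oriented so the mask (paratumor) side lies on its left.
    """
    polyline = np.asarray(polyline, dtype=float)
    if df < 4:
        raise ValueError("spline df must be >= 4")
    if len(polyline) < df + 4:
        raise ValueError(f"polyline has {len(polyline)} vertices; need >= df + 4 = {df + 4}")
    seg = np.hypot(*np.diff(polyline, axis=0).T)
    keep = np.concatenate([[True], seg > 0])
    polyline = polyline[keep]
    seg = np.hypot(*np.diff(polyline, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_interior = df - 4
    knots = np.linspace(s[0], s[-1], n_interior + 2)[1:-1]
    fx = LSQUnivariateSpline(s, polyline[:, 0], knots, k=3)
    fy = LSQUnivariateSpline(s, polyline[:, 1], knots, k=3)
    n = max(int(np.ceil(s[-1] / RESAMPLE_UM)), 8)
    s_new = np.linspace(0.0, s[-1], n + 1)
    curve = BorderCurve(np.column_stack([fx(s_new), fy(s_new)]))
    if not curve.as_linestring().is_simple:
        raise SdmError(
            "smoothed border self-intersects; split the section and digitize "
            "the border locally (local segmentation/rotation)"
        )
    if orient_mask is not None and not _mask_on_left(curve, orient_mask):
        curve = curve.reversed()
    return curve


def _mask_on_left(curve: BorderCurve, mask: BinaryMask, probe_um: float | None = None) -> bool:
    """True if mask foreground dominates on the curve's left side."""
    if probe_um is None:
        probe_um = 2.0 * mask.pixel_um
    idx = np.linspace(0, len(curve.vertices) - 1, 25).astype(int)
    p = curve.vertices[idx]
    nrm = curve.normals[idx]
    votes = 0.0
    ny, nx = mask.pixels.shape
    for sign in (+1, -1):
        q = p + sign * probe_um * nrm
        ix = (q[:, 0] // mask.pixel_um).astype(int)
        iy = (q[:, 1] // mask.pixel_um).astype(int)
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        hits = mask.pixels[iy[ok], ix[ok]].sum()
        votes += sign * hits
    return votes >= 0


# ---------------------------------------------------------------------------
# Signed distance

def signed_distance(curve: BorderCurve, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed Euclidean distance and arc position of the nearest curve point.

    Positive on the paratumor side (left of travel). Returns (d, s) arrays,
    one entry per point.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    V = curve.vertices
    tree = cKDTree(V)
    _, nearest = tree.query(pts)
    best_d2 = np.full(len(pts), np.inf)
    best_s = np.zeros(len(pts))
    best_cross = np.zeros(len(pts))
    for offset in (-1, 0):
        j = np.clip(nearest + offset, 0, len(V) - 2)
        a, b = V[j], V[j + 1]
        ab = b - a
        L2 = np.einsum("ij,ij->i", ab, ab)
        t = np.clip(np.einsum("ij,ij->i", pts - a, ab) / np.maximum(L2, 1e-30), 0.0, 1.0)
        foot = a + t[:, None] * ab
        vec = pts - foot
        d2 = np.einsum("ij,ij->i", vec, vec)
        cross = ab[:, 0] * vec[:, 1] - ab[:, 1] * vec[:, 0]
        better = d2 < best_d2 - 1e-12
        best_d2 = np.where(better, d2, best_d2)
        best_s = np.where(better, curve.s[j] + t * (curve.s[j + 1] - curve.s[j]), best_s)
        best_cross = np.where(better, cross, best_cross)
    sign = np.where(best_cross >= 0, 1.0, -1.0)
    d = sign * np.sqrt(best_d2)
    d[best_d2 < 1e-18] = 0.0
    if np.isscalar(points[0]) and np.ndim(points) == 1:
        return d[0], best_s[0]
    return d, best_s


# ---------------------------------------------------------------------------
# Layers

@dataclass
class LayerSet:
    """Six offset-band polygons plus the two distant reference bands.

    ``bands`` maps layer labels ("-3".."+3", "distant+", "distant-") to
    polygons; ``curve_ext`` is the border extended to the slide frame, used
    for banding, tiling and distance queries; ``boundary_offsets`` holds the
    displaced polylines keyed by signed offset in µm.
    """

    curve: BorderCurve
    curve_ext: BorderCurve
    bands: dict[str, Polygon]
    boundary_offsets: dict[float, np.ndarray]
    half_widths: tuple[float, ...]
    distant: tuple[float, float]
    slide_extent_um: tuple[float, float]

    @property
    def layer_labels(self) -> list[str]:
        k = len(self.half_widths)
        return [f"-{i}" for i in range(k, 0, -1)] + [f"+{i}" for i in range(1, k + 1)]


def _extend_to_box(curve: BorderCurve, extent_um: tuple[float, float]) -> BorderCurve:
    """Extend the curve along its end tangents until it exits the slide, then
    clip to the slide rectangle and resample."""
    V = curve.vertices
    t = curve.tangents
    reach = float(np.hypot(*extent_um)) * 2.0
    ext = np.vstack([V[0] - reach * t[0], V, V[-1] + reach * t[-1]])
    line = LineString(ext)
    box = shapely_box(0.0, 0.0, extent_um[0], extent_um[1])
    clipped = line.intersection(box)
    if clipped.is_empty:
        raise SdmError("border lies outside the slide rectangle")
    if clipped.geom_type == "MultiLineString":
        clipped = max(clipped.geoms, key=lambda g: g.length)
    xy = np.asarray(clipped.coords)
    # preserve orientation of the original curve
    if np.dot(xy[-1] - xy[0], V[-1] - V[0]) < 0:
        xy = xy[::-1]
    return BorderCurve(_resample_polyline(xy))


def _offset_polyline(curve: BorderCurve, d: float, prune: bool = False) -> np.ndarray:
    """Normal displacement of the curve by ``d`` µm.

    With ``prune=True``, vertices whose displaced segment runs against the
    base tangent (inverted loops where the local curvature radius dips below
    |d|) are dropped.
    """
    out = curve.vertices + d * curve.normals
    if prune and abs(d) > 0:
        t = curve.tangents
        seg = np.diff(out, axis=0)
        forward = np.einsum("ij,ij->i", seg, t[:-1]) > 0
        keep = np.concatenate([[True], forward])
        keep[-1] = True
        out = out[keep]
    return out


def _sliver_decomposition(
    curve: BorderCurve, d_in: float, d_out: float, box: Polygon
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Decompose the band between two offsets into normal-bounded slivers.

    Returns (A, B, polys, areas): the two displaced polylines, one valid
    clipped polygon per ≤5 µm arc step, and its area. Bands and tiles are
    both assembled from these slivers, so tiles partition their band by
    construction even where sub-offset wiggles locally fold the displaced
    polyline (folded quads are resolved by make_valid).
    """
    A = _offset_polyline(curve, d_in)
    B = _offset_polyline(curve, d_out)
    quads = shapely.polygons(
        shapely.linearrings(np.stack([A[:-1], A[1:], B[1:], B[:-1]], axis=1))
    )
    polys = shapely.make_valid(quads)
    polys = shapely.intersection(polys, box)
    # where the displaced polyline folds back on itself, consecutive slivers
    # overlap; dedupe in arc order so the decomposition is an exact partition
    tree = shapely.STRtree(polys)
    q_from, q_to = tree.query(polys, predicate="intersects")
    overlap = q_from < q_to  # earlier sliver claims the shared area
    by_later: dict[int, list[int]] = {}
    for j, k in zip(q_from[overlap], q_to[overlap]):
        if k - j > 1 or shapely.area(shapely.intersection(polys[j], polys[k])) > 1e-9:
            by_later.setdefault(int(k), []).append(int(j))
    for k in sorted(by_later):
        earlier = by_later[k]
        polys[k] = polys[k].difference(shapely.unary_union([polys[j] for j in earlier]))
    areas = shapely.area(polys)
    return A, B, polys, areas


def build_layers(
    curve: BorderCurve,
    slide_extent_um: tuple[float, float],
    half_widths: tuple[float, ...] = LAYER_HALF_WIDTHS_UM,
    distant: tuple[float, float] = DISTANT_BAND_UM,
    max_curvature_violation: float = 0.15,
) -> LayerSet:
    """Construct the offset-band layers on both sides of the border.

    Layer boundaries are the border displaced along its local normals by
    0, ±250, ±500, ±750 µm (defaults); bands are closed against the slide
    rectangle. The distant reference bands (2.00–2.25 mm from the border)
    are built by buffering, which prunes offset self-intersections where the
    border curvature radius is below 2 mm.
    """
    curve_ext = _extend_to_box(curve, slide_extent_um)
    # curvature measured at the layer-width scale: sub-offset wiggles only
    # create micro-loops the sliver dedup resolves, macroscopic bends do not
    coarse = BorderCurve(_resample_polyline(curve_ext.vertices, spacing=250.0))
    kappa = coarse.curvature()
    max_off = max(half_widths)
    violation = float(np.mean(kappa[2:-2] > 1.0 / max_off))
    if violation > max_curvature_violation:
        raise SdmError(
            f"border curvature radius < {max_off:.0f} µm along "
            f"{violation:.0%} of the arc; offsets would self-intersect — "
            "digitize the border in local segments"
        )
    box = shapely_box(0.0, 0.0, slide_extent_um[0], slide_extent_um[1])
    offsets = [0.0] + [w for hw in half_widths for w in (hw, -hw)]
    boundary_offsets: dict[float, np.ndarray] = {}
    for d in sorted(set(offsets)):
        boundary_offsets[d] = _offset_polyline(curve_ext, d, prune=True)

    bands: dict[str, Polygon] = {}
    widths = (0.0,) + tuple(half_widths)
    for i in range(len(half_widths)):
        lo, hi = widths[i], widths[i + 1]
        for label, (da, db) in ((f"+{i + 1}", (lo, hi)), (f"-{i + 1}", (-hi, -lo))):
            _, _, polys, _ = _sliver_decomposition(curve_ext, da, db, box)
            bands[label] = shapely.unary_union(polys)

    # distant bands: two-sided buffer rings split by side
    ext_line = LineString(curve_ext.vertices)
    ring = ext_line.buffer(distant[1]).difference(ext_line.buffer(distant[0]))
    mid = len(curve_ext.vertices) // 2
    para_probe = Point(curve_ext.vertices[mid] + 50.0 * curve_ext.normals[mid])
    try:
        pieces = shapely_split(box, ext_line)
        para_side = next(g for g in pieces.geoms if g.contains(para_probe))
        tumor_side = box.difference(para_side)
    except (StopIteration, ValueError):
        para_side = tumor_side = box  # degenerate split: fall back to unsplit
    bands["distant+"] = ring.intersection(para_side).intersection(box)
    bands["distant-"] = ring.intersection(tumor_side).intersection(box)
    return LayerSet(
        curve=curve,
        curve_ext=curve_ext,
        bands=bands,
        boundary_offsets=boundary_offsets,
        half_widths=tuple(half_widths),
        distant=tuple(distant),
        slide_extent_um=tuple(slide_extent_um),
    )


# ---------------------------------------------------------------------------
# Tiles

def _layer_offsets(label: str, half_widths: tuple[float, ...]) -> tuple[float, float]:
    widths = (0.0,) + tuple(half_widths)
    k = int(label[1:])
    sign = 1.0 if label[0] == "+" else -1.0
    lo, hi = widths[k - 1], widths[k]
    return sign * lo, sign * hi


def tile_layer(
    layers: LayerSet,
    label: str,
    n_tiles: int = N_TILES,
) -> pd.DataFrame:
    """Cut one layer band into ``n_tiles`` equal-area tiles along the border.

    Cumulative band area is accumulated along the arc in ≤ 5 µm slivers
    bounded by local normals; the n_tiles − 1 cut normals sit at equal
    cumulative-area quantiles (interpolated within slivers). Returns a frame
    with columns layer, tile, polygon, area_um2, s_start, s_end ordered along
    the border.
    """
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    curve = layers.curve_ext
    d_in, d_out = _layer_offsets(label, layers.half_widths)
    box = shapely_box(0.0, 0.0, layers.slide_extent_um[0], layers.slide_extent_um[1])
    A, B, polys, areas = _sliver_decomposition(curve, d_in, d_out, box)
    m = len(A) - 1
    total = float(areas.sum())
    if total <= 0:
        raise SdmError(f"layer {label} has zero area inside the slide")
    cum = np.concatenate([[0.0], np.cumsum(areas)])

    def _cut(target: float) -> tuple[int, float]:
        j = int(np.searchsorted(cum, target, side="left") - 1)
        j = min(max(j, 0), m - 1)
        f = (target - cum[j]) / areas[j] if areas[j] > 0 else 0.0
        return j, float(np.clip(f, 0.0, 1.0))

    def _partial_quad(j: int, f0: float, f1: float):
        """The [f0, f1] arc portion of (deduped, clipped) sliver j."""
        a0 = A[j] * (1 - f0) + A[j + 1] * f0
        b0 = B[j] * (1 - f0) + B[j + 1] * f0
        a1 = A[j] * (1 - f1) + A[j + 1] * f1
        b1 = B[j] * (1 - f1) + B[j + 1] * f1
        quad = Polygon([a0, a1, b1, b0])
        if not quad.is_valid:
            quad = shapely.make_valid(quad)
        return quad.intersection(polys[j])

    cuts = [(0, 0.0)] + [_cut(total * t / n_tiles) for t in range(1, n_tiles)] + [(m - 1, 1.0)]
    rows = []
    s = curve.s
    for t in range(n_tiles):
        (j0, f0), (j1, f1) = cuts[t], cuts[t + 1]
        pieces = []
        if j0 == j1:
            pieces.append(_partial_quad(j0, f0, f1))
        else:
            if f0 < 1.0:
                pieces.append(_partial_quad(j0, f0, 1.0))
            pieces.extend(polys[j0 + 1: j1])
            pieces.append(_partial_quad(j1, 0.0, f1))
        poly = shapely.unary_union([p for p in pieces if not p.is_empty])
        if poly.is_empty:
            raise SdmError(f"tile {t + 1} of layer {label} fell outside the slide")
        rows.append(
            {
                "layer": label,
                "tile": t + 1,
                "polygon": poly,
                "area_um2": float(poly.area),
                "s_start": float(s[j0] + f0 * (s[j0 + 1] - s[j0])),
                "s_end": float(s[j1] + f1 * (s[j1 + 1] - s[j1])),
            }
        )
    # where sub-offset folds make neighbouring tiles overlap, the overlap
    # belongs to the lower tile index (the assignment tie rule); subtracting
    # it keeps the tiles an exact partition of the band
    for t in range(1, n_tiles):
        poly = rows[t]["polygon"]
        for prev in rows[max(0, t - 2): t]:
            if poly.intersects(prev["polygon"]):
                poly = poly.difference(prev["polygon"])
        rows[t]["polygon"] = poly
        rows[t]["area_um2"] = float(poly.area)
    return pd.DataFrame(rows)


def build_tiles(layers: LayerSet, n_tiles: int = N_TILES, labels: list[str] | None = None) -> pd.DataFrame:
    """Tile every (or the requested) layer; rows ordered by (layer, tile)."""
    labels = labels if labels is not None else layers.layer_labels
    frames = [tile_layer(layers, lab, n_tiles) for lab in labels]
    if not frames:
        return pd.DataFrame(
            columns=["layer", "tile", "polygon", "area_um2", "s_start", "s_end"]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Spot assignment

def _triangles_of(poly: Polygon) -> np.ndarray:
    """Fan/Delaunay decomposition into triangles, (n_tri, 3, 2)."""
    tris = []
    for geom in shapely.get_parts(shapely.delaunay_triangles(poly)):
        if poly.buffer(1e-6).contains(geom.centroid):
            coords = np.asarray(geom.exterior.coords)[:3]
            tris.append(coords)
    if not tris:  # fallback: fan from first vertex (convex polygons)
        ring = np.asarray(poly.exterior.coords)[:-1]
        tris = [np.array([ring[0], ring[i], ring[i + 1]]) for i in range(1, len(ring) - 1)]
    return np.stack(tris)


def _points_in_triangles(pts: np.ndarray, tris: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Edge-wise cross-product containment test (boundary counts inside)."""
    inside = np.zeros(len(pts), dtype=bool)
    for tri in tris:
        a, b, c = tri
        # ensure counter-clockwise winding
        if (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]) < 0:
            b, c = c, b
        ok = np.ones(len(pts), dtype=bool)
        for p0, p1 in ((a, b), (b, c), (c, a)):
            edge = p1 - p0
            cross = edge[0] * (pts[:, 1] - p0[1]) - edge[1] * (pts[:, 0] - p0[0])
            ok &= cross >= -tol
        inside |= ok
    return inside


def assign_spots(
    spots: pd.DataFrame,
    tiles: pd.DataFrame,
    layers: LayerSet,
) -> pd.DataFrame:
    """Assign every spot a (layer, tile) index.

    A spot belongs to a tile iff the cross products of each tile edge with
    the spot centroid share a sign over a convex (triangle) piece of the
    tile; spots on shared edges go to the lowest (layer, tile) index. Spots
    in no tile are labelled "distant" (2.00–2.25 mm from the border) or
    "none" according to their signed distance.

    ``spots`` needs columns spot_id, x_um, y_um; extra columns (cell type,
    subtype, ...) are carried through. The output adds layer, tile, d_um and
    s_um columns.
    """
    out = spots.reset_index(drop=True).copy()
    pts = out[["x_um", "y_um"]].to_numpy(dtype=float)
    d, s_arc = signed_distance(layers.curve_ext, pts)
    out["d_um"] = d
    out["s_um"] = s_arc
    layer_out = np.full(len(out), NONE_LABEL, dtype=object)
    tile_out = np.full(len(out), NONE_LABEL, dtype=object)
    assigned = np.zeros(len(out), dtype=bool)
    if len(tiles):
        layer_rank = {lab: i for i, lab in enumerate(layers.layer_labels)}
        order = tiles.assign(_rank=[layer_rank[la] for la in tiles["layer"]]).sort_values(
            ["_rank", "tile"]
        )
        tree = shapely.STRtree(list(order["polygon"]))
        pt_geoms = shapely.points(pts)
        cand_pt, cand_tile = tree.query(pt_geoms)
        tile_rows = order.reset_index(drop=True)
    else:
        cand_pt = cand_tile = np.array([], dtype=int)
        tile_rows = tiles
    for tile_idx in range(len(tile_rows)):
        sel = cand_pt[cand_tile == tile_idx]
        sel = sel[~assigned[sel]]
        if sel.size == 0:
            continue
        row = tile_rows.iloc[tile_idx]
        polys = (
            list(row["polygon"].geoms)
            if row["polygon"].geom_type in ("MultiPolygon", "GeometryCollection")
            else [row["polygon"]]
        )
        hit = np.zeros(sel.size, dtype=bool)
        for poly in polys:
            if poly.geom_type != "Polygon" or poly.is_empty:
                continue
            hit |= _points_in_triangles(pts[sel], _triangles_of(poly))
        got = sel[hit]
        layer_out[got] = row["layer"]
        tile_out[got] = int(row["tile"])
        assigned[got] = True
    # spots outside all tiles: distant band or none, by signed distance
    lo, hi = layers.distant
    outside = ~assigned
    dist_mask = outside & (np.abs(d) >= lo) & (np.abs(d) <= hi)
    layer_out[dist_mask] = DISTANT_LABEL
    out["layer"] = layer_out
    out["tile"] = tile_out
    return out


# ---------------------------------------------------------------------------
# One-call digitization

def digitize_slide(
    annotation: pd.DataFrame,
    slide_extent_um: tuple[float, float],
    pixel_um: float = 25.0,
    window: int = 5,
    keep_fraction: float = 0.4,
    df: int = SPLINE_DF,
    half_widths: tuple[float, ...] = LAYER_HALF_WIDTHS_UM,
    distant: tuple[float, float] = DISTANT_BAND_UM,
    n_tiles: int = N_TILES,
    tile_labels: list[str] | None = None,
):
    """Run the full SDM on an annotated slide.

    Returns (mask, curve, layers, tiles, assignment).
    """
    mask = denoise_mask(
        build_mask(annotation, pixel_um=pixel_um, extent_um=slide_extent_um),
        window=window,
        keep_fraction=keep_fraction,
    )
    raw = extract_contour(mask)
    curve = smooth_border(raw, df=df, orient_mask=mask)
    layers = build_layers(curve, slide_extent_um, half_widths=half_widths, distant=distant)
    tiles = build_tiles(layers, n_tiles=n_tiles, labels=tile_labels)
    assignment = assign_spots(annotation, tiles, layers)
    return mask, curve, layers, tiles, assignment
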