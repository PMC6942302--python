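"""Trait catalogue for slices, zones, layers and vascular bundles.

Five trait categories are computed from the uniform contour
representation:

* intensity — mean grey level (AI) over the filled region;
* geometry, dimensional (mm / mm²) — width W, height H, main axis length
  MAL and width MAW (minimum-area rotated rectangle), circumcircle
  radius CR, inscribed circle radius ICR, area A, perimeter P, convex
  hull area CHA;
* geometry, dimensionless — RA = A/(MAL·MAW), AR = MAW/MAL,
  CIR = 4πA/P², ECC = sqrt(MAL² − MAW²)/MAL, SPH = ICR/CR, CV = A/CHA;
* distribution — distance to the stem center DC, plus the exponential
  size–distance law y = a − b·e^{c·x} fitted across candidates;
* layer and growth — equal-distance / equal-area concentric ring
  partitions, Voronoi growth space, per-zone populations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage, optimize
from shapely.affinity import scale as shapely_scale
from shapely.geometry import MultiPoint, Point, Polygon
from sklearn.cluster import KMeans

from .calibration import SliceImage
from .contours import ContourShape, mask_from_contour


@dataclass(frozen=True)
class TraitRecord:
    """Per-object trait values (lengths mm, areas mm², AI grey level)."""

    AI: float
    W: float
    H: float
    MAL: float
    MAW: float
    CR: float
    ICR: float
    A: float
    P: float
    CHA: float
    RA: float
    AR: float
    CIR: float
    ECC: float
    SPH: float
    CV: float
    DC: float


@dataclass(frozen=True)
class DistanceModel:
    """Fitted exponential trend y = a − b·e^{c·x} of a trait against DC."""

    trait: str
    a: float
    b: float
    c: float
    residual_sigma: float      #: 1.4826 · MAD of the fit residuals

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.a - self.b * np.exp(self.c * np.asarray(x, dtype=float))


def contour_traits(contour: ContourShape, img: SliceImage,
                   stem_center: tuple[float, float]) -> TraitRecord:
    """All intensity/geometry/distribution traits of one contour."""
    ps = img.pixel_size_mm
    poly = contour.to_polygon()
    if poly.area <= 0:
        raise ValueError("degenerate (collinear) contour")

    mask = mask_from_contour(contour, img.shape)
    if not mask.any():
        raise ValueError("contour rasterizes to an empty region")

    minx, miny, maxx, maxy = poly.bounds
    w, h = (maxx - minx) * ps, (maxy - miny) * ps

    rect = poly.minimum_rotated_rectangle
    if rect.geom_type != "Polygon":
        raise ValueError("degenerate (collinear) contour")
    coords = np.asarray(rect.exterior.coords)[:4]
    side1 = float(np.hypot(*(coords[1] - coords[0])))
    side2 = float(np.hypot(*(coords[2] - coords[1])))
    mal, maw = max(side1, side2) * ps, min(side1, side2) * ps
    if maw <= 0:
        raise ValueError("degenerate (collinear) contour")

    cr = float(shapely.minimum_bounding_radius(poly)) * ps
    # EDT measures center-to-center distance; −0.5 px refers it to the
    # half-pixel object boundary the polygon uses
    edt_max = float(ndimage.distance_transform_edt(mask).max())
    icr = max(edt_max - 0.5, 0.5) * ps

    area = contour.area_px * ps ** 2
    # Crofton estimator: unbiased on digitized curved outlines, where the
    # raw marching-squares arc length overestimates by several percent
    from skimage import measure as _measure
    from skimage import morphology as _morph
    perim = float(_measure.perimeter_crofton(mask, directions=4)) * ps
    cha = int(_morph.convex_hull_image(mask).sum()) * ps ** 2

    ai = float(img.pixels[mask].mean())
    dc = math.hypot(contour.centroid[0] - stem_center[0],
                    contour.centroid[1] - stem_center[1]) * ps

    return TraitRecord(
        AI=ai, W=w, H=h, MAL=mal, MAW=maw, CR=cr, ICR=icr, A=area, P=perim,
        CHA=cha,
        RA=area / (mal * maw),
        AR=maw / mal,
        CIR=4 * math.pi * area / perim ** 2,
        ECC=math.sqrt(max(mal ** 2 - maw ** 2, 0.0)) / mal,
        SPH=min(icr / cr, 1.0),
        CV=area / cha,
        DC=dc,
    )


def zone_histogram(img: SliceImage, mask: np.ndarray) -> np.ndarray:
    """255-bin grey histogram over the mask, background level 0 excluded."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    counts = np.bincount(img.pixels[mask].ravel(), minlength=256)
    return counts[1:256]


def fit_distance_model(samples, trait: str) -> DistanceModel:
    """Nonlinear least-squares fit of y = a − b·e^{c·x}.

    Initialization: a₀ = max(y); b₀ = max(a₀ − min(y), 1e−6); c₀ from a
    log-linear fit of log(a₀ − y) against x over the strictly positive
    residues (0.1 when fewer than two are available).  The residual
    scale is the normalized median absolute deviation.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 10:
        raise ValueError("need at least 10 (distance, value) samples")
    x, y = arr[:, 0], arr[:, 1]
    if x.max() - x.min() < 3.0:
        raise ValueError("samples must span at least 3 mm of distance")

    a0 = float(y.max())
    b0 = max(a0 - float(y.min()), 1e-6)
    resid = a0 - y
    pos = resid > 0
    if pos.sum() >= 2:
        slope, inter = np.polyfit(x[pos], np.log(resid[pos]), 1)
        c0 = float(slope)
        b0 = max(float(np.exp(inter)), 1e-9)
    else:
        c0 = 0.1

    def model(xv, a, b, c):
        return a - b * np.exp(c * xv)

    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=(a0, b0, c0),
                                     maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise RuntimeError(
            f"exponential fit did not converge from p0=({a0:.4g}, {b0:.4g}, "
            f"{c0:.4g}): {exc}") from exc
    res = y - model(x, *popt)
    sigma = 1.4826 * float(np.median(np.abs(res - np.median(res))))
    return DistanceModel(trait=trait, a=float(popt[0]), b=float(popt[1]),
                         c=float(popt[2]), residual_sigma=sigma)


@dataclass
class LayerScheme:
    """Concentric ring partition of the region inside the rind.

    Ring boundaries are the epidermis inner boundary (Contour3) scaled
    about the stem center by k/n (equal-distance) or sqrt(k/n)
    (equal-area, exact by the similarity scaling law).
    """

    mode: str                       #: 'ED' or 'EA'
    n_layers: int
    ring_polygons: list[Polygon]    #: outward, k = 1..n (shapely, x=col y=row)
    ring_contours: list[ContourShape]
    stem_center: tuple[float, float]
    table: object | None = None     #: per-layer stats DataFrame when computed

    def layer_of(self, center: tuple[float, float]) -> int | None:
        """1-based layer index of a (row, col) point, None if outside."""
        pt = Point(center[1], center[0])
        for k, ring in enumerate(self.ring_polygons, start=1):
            if ring.covers(pt):
                return k
        return None


def layer_partition(zones, n: int = 5, mode: str = "EA") -> LayerScheme:
    """Build the ED/EA ring partition from the zone hierarchy."""
    if n < 2:
        raise ValueError("need at least 2 layers")
    if mode not in ("ED", "EA"):
        raise ValueError("mode must be 'ED' or 'EA'")
    poly3 = zones.contour3.to_polygon()
    cy, cx = zones.stem_center
    if not poly3.covers(Point(cx, cy)):
        raise ValueError("stem center lies outside Contour3")
    polys, contours = [], []
    for k in range(1, n + 1):
        s = k / n if mode == "ED" else math.sqrt(k / n)
        ring = shapely_scale(poly3, xfact=s, yfact=s, origin=(cx, cy))
        polys.append(ring)
        pts = np.asarray(ring.exterior.coords)[:, ::-1]
        contours.append(ContourShape(points=pts,
                                     area_px=max(int(ring.area), 1),
                                     centroid=(cy, cx)))
    return LayerScheme(mode=mode, n_layers=n, ring_polygons=polys,
                       ring_contours=contours, stem_center=(cy, cx))


def layer_stats(scheme: LayerScheme, zones, bundles, img: SliceImage,
                voronoi_mm2: dict[int, float] | None = None):
    """Per-layer AEL / NVBEL / AVBEL / VAVBEL / AI table (pandas)."""
    import pandas as pd

    ps = img.pixel_size_mm
    n = scheme.n_layers
    # rasterized bands tile region(contour3) exactly: outermost band uses
    # the contour3 region mask itself
    region3 = zones.inner_mask | zones.periphery_mask
    prev = np.zeros(img.shape, dtype=bool)
    rows = []
    areas_poly = [p.area for p in scheme.ring_polygons]
    for k in range(1, n + 1):
        band_outer = region3 if k == n else mask_from_contour(
            scheme.ring_contours[k - 1], img.shape) & region3
        band = band_outer & ~prev
        prev = prev | band_outer
        members = [i for i, b in enumerate(bundles)
                   if scheme.layer_of(b.contour.centroid) == k]
        b_areas = [bundles[i].contour.area_px * ps ** 2 for i in members]
        v_areas = ([voronoi_mm2[i] for i in members if i in voronoi_mm2]
                   if voronoi_mm2 else [])
        grey = img.pixels[band]
        grey = grey[grey > 0]
        ael = (areas_poly[k - 1] - (areas_poly[k - 2] if k > 1 else 0.0))
        rows.append({
            "layer": k,
            "AEL": ael * ps ** 2,
            "NVBEL": len(members),
            "AVBEL": float(np.mean(b_areas)) if b_areas else np.nan,
            "VAVBEL": float(np.mean(v_areas)) if v_areas else np.nan,
            "AI": float(grey.mean()) if grey.size else np.nan,
        })
    scheme.table = pd.DataFrame(rows)
    return scheme.table


def voronoi_growth_space(centers, boundary: ContourShape,
                         pixel_size_mm: float = 1.0) -> list[float]:
    """Exclusive growth space of each bundle: Voronoi cell clipped to the
    stem interior (inner boundary of the epidermis as constraint).

    Returns one patch area (mm², or px² when pixel_size_mm is 1) per
    center, in input order; the patches partition the boundary region.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 2 or centers.shape[0] < 1:
        raise ValueError("need at least one center")
    bpoly = boundary.to_polygon()
    pts_xy = centers[:, ::-1].copy()
    # shapely's Voronoi drops duplicate sites; perturb them
    seen: dict[tuple[float, float], int] = {}
    for i, (px, py) in enumerate(pts_xy):
        key = (px, py)
        if key in seen:
            warnings.warn("duplicate Voronoi centers perturbed by 1e-6 px")
            pts_xy[i] += (seen[key] + 1) * 1e-6
            seen[key] += 1
        else:
            seen[key] = 0

    if len(pts_xy) == 1:
        return [float(bpoly.area) * pixel_size_mm ** 2]

    env = shapely.box(*bpoly.buffer(10.0).bounds)
    cells = shapely.voronoi_polygons(MultiPoint(pts_xy.tolist()),
                                     extend_to=env, ordered=True)
    areas = []
    for i, cell in enumerate(cells.geoms):
        clipped = cell.intersection(bpoly)
        areas.append(float(clipped.area) * pixel_size_mm ** 2)
    return areas


def kmeans_area_classes(areas, k: int, seed: int = 0) -> np.ndarray:
    """1-D k-means labels of bundle areas, deterministic quantile init.

    Labels are reindexed by ascending cluster mean, so label 0 is always
    the smallest-area class.
    """
    areas = np.asarray(areas, dtype=float).reshape(-1, 1)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > np.unique(areas).size:
        raise ValueError("k exceeds the number of distinct areas")
    init = np.quantile(areas, [(i + 0.5) / k for i in range(k)]).reshape(-1, 1)
    km = KMeans(n_clusters=k, init=init, n_init=1, random_state=seed)
    labels = km.fit_predict(areas)
    order = np.argsort(km.cluster_centers_.ravel())
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[labels]


@dataclass(frozen=True)
class ZoneTraits:
    """Slice- and zone-level growth traits."""

    aefz_mm2: dict[str, float]              #: area per zone
    nvbpz: int
    nvbiz: int
    avbpz_mm2: float | None                 #: mean bundle area, periphery
    avbiz_mm2: float | None
    vavpz_mm2: float | None                 #: mean Voronoi patch, periphery
    vaviz_mm2: float | None
    bundle_area_ratio: dict[str, float | None]  #: Σ bundle area / zone area
    slice_ai: float
    substance_ratio: float
    epidermis_thickness_mm: float
    histograms: dict[str, np.ndarray]


def _epidermis_thickness(zones, n_rays: int = 360) -> float:
    """Mean radial distance between Contour3 and Contour1 crossings."""
    from shapely.geometry import LineString

    cy, cx = zones.stem_center
    p1, p3 = zones.contour1.to_polygon(), zones.contour3.to_polygon()
    reach = 2.0 * math.sqrt(p1.area / math.pi) + 10.0
    vals = []
    for t in np.linspace(0, 2 * math.pi, n_rays, endpoint=False):
        ray = LineString([(cx, cy),
                          (cx + reach * math.cos(t), cy + reach * math.sin(t))])
        d1 = ray.intersection(p1.exterior)
        d3 = ray.intersection(p3.exterior)
        if d1.is_empty or d3.is_empty:
            continue
        r1 = max(pt.distance(Point(cx, cy)) for pt in _points_of(d1))
        r3 = max(pt.distance(Point(cx, cy)) for pt in _points_of(d3))
        if r1 > r3:
            vals.append(r1 - r3)
    if not vals:
        raise ValueError("no epidermis crossings found")
    return float(np.mean(vals))


def _points_of(geom):
    if geom.geom_type == "Point":
        return [geom]
    return [g for g in getattr(geom, "geoms", []) if g.geom_type == "Point"]


def zone_growth_traits(zones, bundles, img: SliceImage) -> ZoneTraits:
    """Growth-based traits of Table-style zone rows.

    Bundle membership is by center point; Voronoi patches are
    constrained by Contour3; slice AI and the substance ratio exclude
    grey level 0; epidermis thickness is the 360-ray radial mean.
    """
    ps = img.pixel_size_mm
    aefz = {
        "epidermis": int(zones.epidermis_mask.sum()) * ps ** 2,
        "periphery": int(zones.periphery_mask.sum()) * ps ** 2,
        "inner": int(zones.inner_mask.sum()) * ps ** 2,
    }
    peri = [b for b in bundles if b.zone == "periphery"]
    inner = [b for b in bundles if b.zone == "inner"]

    def mean_area(group):
        return (float(np.mean([b.contour.area_px for b in group])) * ps ** 2
                if group else None)

    vor_p = vor_i = None
    if bundles:
        centers = [b.contour.centroid for b in bundles]
        patches = voronoi_growth_space(centers, zones.contour3, ps)
        vp = [a for b, a in zip(bundles, patches) if b.zone == "periphery"]
        vi = [a for b, a in zip(bundles, patches) if b.zone == "inner"]
        vor_p = float(np.mean(vp)) if vp else None
        vor_i = float(np.mean(vi)) if vi else None

    slice_mask = zones.slice_mask
    grey = img.pixels[slice_mask]
    nonzero = grey[grey > 0]
    histograms = {}
    for name, m in (("slice", slice_mask), ("epidermis", zones.epidermis_mask),
                    ("periphery", zones.periphery_mask),
                    ("inner", zones.inner_mask)):
        if m.any():
            histograms[name] = zone_histogram(img, m)

    ratio = {
        "periphery": (sum(b.contour.area_px for b in peri) * ps ** 2
                      / aefz["periphery"] if aefz["periphery"] else None),
        "inner": (sum(b.contour.area_px for b in inner) * ps ** 2
                  / aefz["inner"] if aefz["inner"] else None),
    }
    return ZoneTraits(
        aefz_mm2=aefz,
        nvbpz=len(peri),
        nvbiz=len(inner),
        avbpz_mm2=mean_area(peri),
        avbiz_mm2=mean_area(inner),
        vavpz_mm2=vor_p,
        vaviz_mm2=vor_i,
        bundle_area_ratio=ratio,
        slice_ai=float(nonzero.mean()) if nonzero.size else 0.0,
        substance_ratio=float(nonzero.size / grey.size) if grey.size else 0.0,
        epidermis_thickness_mm=_epidermis_thickness(zones) * ps,
        histograms=histograms,
    )
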