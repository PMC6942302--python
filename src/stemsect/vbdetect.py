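"""Vascular-bundle detection, refinement and splitting.

The two zones need different treatment.  Inner-zone bundles are
isolated but faint-edged: a permissive fixed threshold (grey >= 1)
yields one redundant candidate per bundle, whose boundary is then
refined by a region-based active contour.  Periphery bundles are bright
but densely packed and often fused with their neighbours: the adaptive
segmentation of the zone pipeline yields the candidates, oversized ones
(relative to the exponential size-distance law) are flagged as merged
and decomposed into lobes by greedy maximum-inscribed-circle
extraction, and lobes are grown back into individual bundles by
geodesic label propagation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology, segmentation

from .calibration import SliceImage
from .contours import ContourShape, contour_from_filled
from .zones import FunctionZones, ZoneParams, adaptive_mean_segment


class LevelSetError(RuntimeError):
    """Active-contour refinement collapsed or exploded."""


@dataclass(frozen=True)
class DetectParams:
    min_size: int = 5          #: smallest candidate, px (noise guard)
    ls_iters: int = 50         #: active-contour iterations
    ls_smoothing: int = 1      #: curvature-smoothing passes per iteration
    min_circle_radius: float = 3.0  #: inscribed-circle stop threshold, px
    despeckle_size: int = 5    #: opening disk cleaning the periphery mask
    flag_k: float = 3.0        #: merged-candidate residual multiplier
    fit_min_samples: int = 10  #: samples required to fit the size law
    fit_min_span_mm: float = 3.0


@dataclass(frozen=True)
class InscribedCircle:
    """One maximal circle extracted from a candidate region."""

    center: tuple[int, int]    #: (row, col) of the distance-transform argmax
    radius_px: float


@dataclass
class CandidateObject:
    """A connected segmented object, potential vascular bundle."""

    contour: ContourShape
    zone: str                  #: 'inner' or 'periphery'
    mask: np.ndarray           #: filled region raster (full-frame)
    convex_hull: ContourShape | None = None
    distance_to_center_mm: float = 0.0
    merged_flag: bool = False


@dataclass
class VascularBundle:
    """A verified bundle; traits are attached by the traits module."""

    contour: ContourShape
    zone: str
    mask: np.ndarray
    merged_flag: bool = False
    traits: object | None = None


def _candidates_from_mask(mask: np.ndarray, zone: str, zones: FunctionZones,
                          pixel_size_mm: float, min_size: int
                          ) -> list[CandidateObject]:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    out: list[CandidateObject] = []
    if n == 0:
        return out
    slices = ndimage.find_objects(labels)
    cy, cx = zones.stem_center
    for i, sl in enumerate(slices, start=1):
        comp_local = labels[sl] == i
        if comp_local.sum() < min_size:
            continue
        comp = np.zeros(mask.shape, dtype=bool)
        comp[sl] = ndimage.binary_fill_holes(comp_local)
        contour = contour_from_filled(comp)
        hull = contour_from_filled(_hull_mask(comp, sl))
        dc = math.hypot(contour.centroid[0] - cy, contour.centroid[1] - cx)
        out.append(CandidateObject(contour=contour, zone=zone, mask=comp,
                                   convex_hull=hull,
                                   distance_to_center_mm=dc * pixel_size_mm))
    return out


def _hull_mask(comp: np.ndarray, sl: tuple[slice, slice]) -> np.ndarray:
    rs = slice(max(sl[0].start - 1, 0), sl[0].stop + 1)
    cs = slice(max(sl[1].start - 1, 0), sl[1].stop + 1)
    out = np.zeros_like(comp)
    out[rs, cs] = morphology.convex_hull_image(comp[rs, cs])
    return out


def inner_candidates(img: SliceImage, zones: FunctionZones,
                     min_size: int = 5) -> list[CandidateObject]:
    """Redundant inner-zone candidates: grey >= 1 inside the inner mask."""
    mask = (img.pixels >= 1) & zones.inner_mask
    return _candidates_from_mask(mask, "inner", zones, img.pixel_size_mm,
                                 min_size)


def periphery_candidates(seg: np.ndarray, zones: FunctionZones,
                         pixel_size_mm: float, min_size: int = 5,
                         despeckle_size: int = 5) -> list[CandidateObject]:
    """Connected bright objects of the adaptive mask inside the periphery.

    The zero-offset local-mean mask marks about half the pixels of any
    noisy homogeneous stretch of ground tissue; an opening with a small
    disk (below the smallest bundle) removes that speckle before
    component extraction, keeping only compact bright objects.
    """
    mask = np.asarray(seg, bool) & zones.periphery_mask
    if despeckle_size > 1:
        mask = morphology.opening(
            mask, morphology.disk(max(despeckle_size // 2, 1)))
        mask &= zones.periphery_mask
    return _candidates_from_mask(mask, "periphery", zones, pixel_size_mm,
                                 min_size)


def level_set_refine(img: SliceImage, init: ContourShape | np.ndarray,
                     iters: int = 50, smoothing: int = 1,
                     shape: tuple[int, int] | None = None) -> ContourShape:
    """Refine a candidate boundary with a two-phase piecewise-constant
    active contour (morphological Chan–Vese) run in a local window.

    The evolution window is the candidate's bounding box expanded by half
    its size on each side, so the contour can never grow beyond twice the
    initial bounding box.  A vanished contour returns the initial one
    with a warning; collapse below 0.2x or growth above 5x the initial
    area is treated as an error.
    """
    from .contours import mask_from_contour

    if isinstance(init, ContourShape):
        init_mask = mask_from_contour(init, shape or img.shape)
    else:
        init_mask = np.asarray(init, bool)
    if not (init_mask & (img.pixels > 0)).any():
        raise ValueError("init must enclose at least one foreground pixel")

    rr, cc = np.nonzero(init_mask)
    h, w = rr.max() - rr.min() + 1, cc.max() - cc.min() + 1
    r0 = max(rr.min() - h // 2 - 1, 0)
    r1 = min(rr.max() + h // 2 + 2, img.shape[0])
    c0 = max(cc.min() - w // 2 - 1, 0)
    c1 = min(cc.max() + w // 2 + 2, img.shape[1])

    window = img.pixels[r0:r1, c0:c1].astype(float)
    evolved = segmentation.morphological_chan_vese(
        window, num_iter=iters, init_level_set=init_mask[r0:r1, c0:c1],
        smoothing=smoothing).astype(bool)
    if not evolved.any():
        warnings.warn("active contour vanished; keeping the initial boundary")
        return contour_from_filled(init_mask)
    labels, _ = ndimage.label(evolved, structure=np.ones((3, 3), int))
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    comp = ndimage.binary_fill_holes(labels == counts.argmax())
    ratio = comp.sum() / init_mask.sum()
    if not 0.2 <= ratio <= 5.0:
        raise LevelSetError(
            f"refined area is {ratio:.2f}x the initial area (allowed 0.2-5)")
    full = np.zeros(img.shape, dtype=bool)
    full[r0:r1, c0:c1] = comp
    return contour_from_filled(full)


def inscribed_circle_decomposition(region: np.ndarray,
                                   min_radius: float = 3.0
                                   ) -> list[InscribedCircle]:
    """Greedy maximal-inscribed-circle shape decomposition.

    Repeatedly take the Euclidean-distance-transform maximum of the
    remaining region as the next circle (argmax ties broken toward the
    smallest (row, col)), delete its pixels, and stop once the radius
    falls below ``min_radius``.  Radii are non-increasing.
    """
    if min_radius < 1:
        raise ValueError("min_radius must be >= 1")
    remaining = np.asarray(region, bool).copy()
    if not remaining.any():
        raise ValueError("empty region")
    yy, xx = np.indices(remaining.shape)
    circles: list[InscribedCircle] = []
    while remaining.any():
        edt = ndimage.distance_transform_edt(remaining)
        flat = int(edt.argmax())          # first max in C order = lexicographic
        r = float(edt.ravel()[flat])
        if r < min_radius:
            break
        cy, cx = np.unravel_index(flat, edt.shape)
        circles.append(InscribedCircle(center=(int(cy), int(cx)), radius_px=r))
        remaining &= (yy - cy) ** 2 + (xx - cx) ** 2 > r ** 2
    return circles


def split_candidate(region: np.ndarray, circles: list[InscribedCircle]
                    ) -> list[ContourShape]:
    """Split a merged candidate into lobes seeded by its inscribed circles.

    Circles whose centers lie within the sum of their radii are merged
    into one seed group (union-find); region pixels are then assigned to
    the geodesically nearest group by constrained label growth, so the
    split conserves every pixel of the candidate.
    """
    region = np.asarray(region, bool)
    if not circles:
        warnings.warn("no inscribed circles: candidate returned whole")
        return [contour_from_filled(region)]

    parent = list(range(len(circles)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, ci in enumerate(circles):
        for j in range(i + 1, len(circles)):
            cj = circles[j]
            d = math.hypot(ci.center[0] - cj.center[0],
                           ci.center[1] - cj.center[1])
            if d < ci.radius_px + cj.radius_px:
                parent[find(i)] = find(j)

    groups: dict[int, int] = {}
    markers = np.zeros(region.shape, dtype=np.int32)
    yy, xx = np.indices(region.shape)
    for i, c in enumerate(circles):
        g = groups.setdefault(find(i), len(groups) + 1)
        disk = (yy - c.center[0]) ** 2 + (xx - c.center[1]) ** 2 <= c.radius_px ** 2
        markers[disk & region] = g
    if len(groups) == 1:
        return [contour_from_filled(region)]

    labels = segmentation.watershed(np.zeros(region.shape), markers=markers,
                                    mask=region)
    out = []
    for g in range(1, len(groups) + 1):
        part = labels == g
        if part.any():
            out.append(contour_from_filled(part))
    return out


def flag_merged_candidates(cands: list[CandidateObject], model,
                           pixel_size_mm: float,
                           k: float = 3.0) -> list[CandidateObject]:
    """Flag candidates whose area exceeds the size-distance law.

    A candidate is merged-flagged iff its area is more than ``k`` robust
    residual SDs above the model prediction at its center distance.
    With no fitted model every candidate stays unflagged (warning).
    """
    if model is None:
        warnings.warn("no fitted distance model: candidates left unflagged")
        return cands
    for c in cands:
        area_mm2 = c.contour.area_px * pixel_size_mm ** 2
        pred = model.predict(c.distance_to_center_mm)
        c.merged_flag = area_mm2 > pred + k * model.residual_sigma
    return cands


def detect_vascular_bundles(img: SliceImage, zones: FunctionZones,
                            params: DetectParams | None = None,
                            zone_params: ZoneParams | None = None
                            ) -> list[VascularBundle]:
    """Detect all bundles of a slice: inner track + periphery track.

    Inner candidates are refined by the active contour (falling back to
    the raw candidate if the refinement errors).  Periphery candidates
    are flagged against the fitted area-distance law and flagged ones are
    decomposed by inscribed circles and split.
    """
    from .contours import mask_from_contour
    from .traits import fit_distance_model

    p = params or DetectParams()
    out: list[VascularBundle] = []

    for cand in inner_candidates(img, zones, p.min_size):
        try:
            contour = level_set_refine(img, cand.mask, iters=p.ls_iters,
                                       smoothing=p.ls_smoothing)
            mask = mask_from_contour(contour, img.shape)
        except (LevelSetError, ValueError) as exc:
            warnings.warn(f"inner candidate kept unrefined: {exc}")
            contour, mask = cand.contour, cand.mask
        out.append(VascularBundle(contour=contour, zone="inner", mask=mask))

    seg = zones.adaptive_mask
    if seg is None:
        zp = zone_params or ZoneParams()
        roi = zones.periphery_mask | zones.epidermis_mask
        seg = adaptive_mean_segment(img, roi, zp.block)
    cands = periphery_candidates(seg, zones, img.pixel_size_mm, p.min_size,
                                 p.despeckle_size)

    model = None
    samples = [(c.distance_to_center_mm,
                c.contour.area_px * img.pixel_size_mm ** 2) for c in cands]
    if len(samples) >= p.fit_min_samples:
        xs = [s[0] for s in samples]
        if max(xs) - min(xs) >= p.fit_min_span_mm:
            try:
                model = fit_distance_model(samples, "area")
            except RuntimeError as exc:
                warnings.warn(f"size-distance fit failed: {exc}")

    cands = flag_merged_candidates(cands, model, img.pixel_size_mm, p.flag_k)
    for cand in cands:
        if cand.merged_flag:
            circles = inscribed_circle_decomposition(cand.mask,
                                                     p.min_circle_radius)
            parts = split_candidate(cand.mask, circles)
            was_split = len(parts) > 1
            for part in parts:
                if part.area_px < p.min_size:
                    continue
                out.append(VascularBundle(
                    contour=part, zone="periphery",
                    mask=mask_from_contour(part, img.shape),
                    merged_flag=was_split))
        else:
            out.append(VascularBundle(contour=cand.contour, zone="periphery",
                                      mask=cand.mask))
    return out
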