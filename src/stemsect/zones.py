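"""Function-zone detection for a maize stem cross-section.

A dried stem slice has three concentric function zones: the dense,
bright epidermis rind; the periphery annulus where small vascular
bundles sit in lignified ground tissue; and the dark inner pith with
sparse, larger, isolated bundles.  The zones are recovered as a
hierarchy of three closed contours:

* Contour1 — outer epidermis boundary (the slice outline),
* Contour2 — periphery/inner boundary (the pith outline),
* Contour3 — epidermis/periphery boundary (inner edge of the rind).

The procedure: threshold the substance at the air level; validate (and
if cracked, morphologically repair) the outer boundary; find the pith as
the largest interior background component; adaptively threshold the
epidermis+periphery annulus so bright objects (rind, bundles) separate
from the darker ground tissue; the reversed mask's cavity network,
closed with a bundle-sized disk, is the region inside the rind and its
outer boundary is Contour3.

Zone masks are computed by set algebra on the region masks, so the three
zones partition the slice region exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .calibration import SliceImage
from .contours import (ContourShape, NoObjectError, contour_from_filled,
                       largest_component, mask_from_contour)


class NoInnerZoneError(ValueError):
    """No interior background component: the slice has no detectable pith."""


class UnrepairableBoundaryError(ValueError):
    """The outer boundary never became valid within the iteration budget."""


@dataclass(frozen=True)
class ZoneParams:
    """Tunables of the zone pipeline (defaults are the working values)."""

    substance_threshold: int = 0    #: grey level of air
    area_ratio: float = 0.95        #: convexity ratio validating Contour1
    block: int = 31                 #: adaptive-mean window (odd, px)
    close_size: int = 15            #: closing disk diameter ~ largest bundle
    repair_max_iter: int = 50       #: dilation budget of the boundary repair
    despeckle_size: int = 3         #: opening disk cleaning the cavity mask


@dataclass(frozen=True)
class FunctionZones:
    """The three boundary contours plus derived zone masks."""

    contour1: ContourShape
    contour2: ContourShape
    contour3: ContourShape
    epidermis_mask: np.ndarray
    periphery_mask: np.ndarray
    inner_mask: np.ndarray
    stem_center: tuple[float, float]
    adaptive_mask: np.ndarray | None = None  #: Step-5 segmentation, reused downstream

    @property
    def slice_mask(self) -> np.ndarray:
        """Region enclosed by Contour1 = union of the three zones."""
        return self.epidermis_mask | self.periphery_mask | self.inner_mask


def threshold_substance(img: SliceImage, t: int = 0) -> np.ndarray:
    """Substance mask: grey strictly above the air level ``t``."""
    if not 0 <= t <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return img.pixels > t


def _filled_region(mask: np.ndarray) -> np.ndarray:
    """Hole-filled region of the component with the largest filled area.

    Filled area per component is the component's pixel count plus the
    holes it encloses; holes (interior background regions) are assigned
    to their surrounding component without filling each component
    separately, so speckle-heavy masks stay cheap.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    if n == 0:
        raise NoObjectError("empty mask: no object")
    areas = np.bincount(labels.ravel())[1:].astype(np.int64)
    filled_all = ndimage.binary_fill_holes(mask)
    holes, nh = ndimage.label(filled_all & ~mask)
    if nh:
        slices = ndimage.find_objects(holes)
        for i, sl in enumerate(slices, start=1):
            rs = slice(max(sl[0].start - 1, 0), sl[0].stop + 1)
            cs = slice(max(sl[1].start - 1, 0), sl[1].stop + 1)
            ring = ndimage.binary_dilation(holes[rs, cs] == i,
                                           np.ones((3, 3), bool))
            owner = labels[rs, cs][ring & (labels[rs, cs] > 0)]
            if owner.size:
                areas[owner[0] - 1] += int((holes[rs, cs] == i).sum())
    best = int(areas.argmax()) + 1
    sl = ndimage.find_objects(labels, max_label=best)[best - 1]
    out = np.zeros_like(mask)
    out[sl] = ndimage.binary_fill_holes(labels[sl] == best)
    return out


def outermost_contour(mask: np.ndarray) -> ContourShape:
    """Outer boundary of the connected component with largest filled area."""
    return contour_from_filled(_filled_region(mask))


def validate_epidermis(mask: np.ndarray, ratio: float = 0.95
                       ) -> tuple[bool, ContourShape]:
    """Convexity check of the outer boundary.

    The stem outline is close to convex, so the convex hull of the whole
    substance mask bounds the attainable area; the filled outer contour
    must cover more than ``ratio`` of it.  A cracked rind, whose outline
    collapses to a fragment, fails the check.
    """
    if not 0 < ratio <= 1:
        raise ValueError("ratio must lie in (0, 1]")
    contour = outermost_contour(mask)
    filled = _filled_region(mask)
    hull = morphology.convex_hull_image(np.asarray(mask, bool))
    actual = int(filled.sum())
    return actual / int(hull.sum()) > ratio, contour


def repair_boundary(mask: np.ndarray, ratio: float = 0.95, max_iter: int = 50
                    ) -> tuple[ContourShape, np.ndarray]:
    """Close a cracked outer boundary by iterative dilation.

    Dilate with a 3×3 element until the outer contour passes the
    convexity check, then erode the *filled* contour region by the same
    number of steps, so the repaired region sits where the intact
    boundary would.  Valid input is returned unchanged.
    """
    valid, contour = validate_epidermis(mask, ratio)
    if valid:
        return contour, _filled_region(mask)
    se = np.ones((3, 3), bool)
    work = np.asarray(mask, dtype=bool)
    for k in range(1, max_iter + 1):
        work = ndimage.binary_dilation(work, se)
        valid, _ = validate_epidermis(work, ratio)
        if valid:
            filled = _filled_region(work)
            eroded = ndimage.binary_erosion(filled, se, iterations=k)
            if not eroded.any():
                break
            return contour_from_filled(eroded), eroded
    raise UnrepairableBoundaryError(
        f"boundary still invalid after {max_iter} dilation steps"
    )


def inner_boundary(substance: np.ndarray, region1: np.ndarray | ContourShape
                   ) -> tuple[ContourShape, np.ndarray]:
    """Contour2: boundary between the inner (pith) and periphery zones.

    The pith is the largest connected non-substance region strictly
    inside Contour1 (4-connected, not touching the region border); its
    holes — the isolated inner bundles — are filled.
    Returns the contour and the filled pith mask.
    """
    substance = np.asarray(substance, dtype=bool)
    if isinstance(region1, ContourShape):
        region1 = mask_from_contour(region1, substance.shape)
    background = region1 & ~substance
    if not background.any():
        raise NoInnerZoneError("no interior background: no inner zone")
    labels, n = ndimage.label(background)  # 4-connectivity for background
    # components adjacent (4-conn) to the outside of region1 touch Contour1
    border = region1 & ~ndimage.binary_erosion(
        region1, structure=ndimage.generate_binary_structure(2, 1))
    touching = np.unique(labels[border & background])
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    counts[touching] = 0
    if counts.max() == 0:
        raise NoInnerZoneError("every interior background region touches "
                               "Contour1: no inner zone")
    region2 = ndimage.binary_fill_holes(labels == counts.argmax())
    return contour_from_filled(region2), region2


def adaptive_mean_segment(img: SliceImage, roi: np.ndarray, block: int = 31
                          ) -> np.ndarray:
    """Local mean thresholding: foreground where grey > block-mean.

    The threshold of each pixel is the mean of the in-ROI pixels of the
    ``block``×``block`` window centered on it, so grey levels of a
    neighbouring zone never leak into the local threshold; ties go to
    background, so uniform regions produce an empty mask.  Window sums
    use edge replication at the raster border.
    """
    if block < 3 or block % 2 == 0:
        raise ValueError("block must be odd and >= 3")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    win_sum = ndimage.uniform_filter(img.pixels.astype(float) * roi,
                                     size=block, mode="nearest")
    win_n = ndimage.uniform_filter(roi.astype(float), size=block,
                                   mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        local_mean = np.where(win_n > 0, win_sum / win_n, 255.0)
    # ties go to background; the epsilon absorbs the accumulation error of
    # the separable window sums so uniform regions stay empty
    return (img.pixels - local_mean > 1e-6) & roi


def close_cavities(mask: np.ndarray, se_size: int = 15) -> np.ndarray:
    """Morphological closing with a disk of diameter ``se_size``.

    Input: the reversed adaptive mask with the exterior cleared, i.e.
    pith + periphery cavity regions as foreground.  Closing with a disk
    sized to the largest bundle fills the bundle vacancies and merges
    the cavity network into one region inside the rind.
    """
    if se_size < 1:
        raise ValueError("se_size must be >= 1")
    footprint = morphology.disk(max(se_size // 2, 1))
    return morphology.closing(np.asarray(mask, bool), footprint)


def detect_function_zones(img: SliceImage, params: ZoneParams | None = None
                          ) -> FunctionZones:
    """Full zone hierarchy of one slice.

    Orchestrates substance thresholding, boundary validation/repair,
    pith detection, adaptive segmentation of the annulus, cavity closing
    and the final zone partition:
    epidermis = region1 − region3, periphery = region3 − region2,
    inner = region2.
    """
    p = params or ZoneParams()
    substance = threshold_substance(img, p.substance_threshold)
    contour1, region1 = repair_boundary(substance, p.area_ratio,
                                        p.repair_max_iter)
    contour2, region2 = inner_boundary(substance, region1)

    annulus = region1 & ~region2  # epidermis + periphery ROI
    seg = adaptive_mean_segment(img, annulus, p.block)

    cavities = annulus & ~seg
    if p.despeckle_size > 1:
        cavities = morphology.opening(
            cavities, morphology.disk(max(p.despeckle_size // 2, 1)))
    cavities |= region2  # pith counts as interior cavity (Step 7)
    closed = close_cavities(cavities, p.close_size) & region1
    closed |= region2
    region3 = ndimage.binary_fill_holes(
        largest_component(closed, connectivity=2))
    region3 |= region2
    region3 &= region1
    contour3 = contour_from_filled(region3)

    rr, cc = np.nonzero(region1)
    center = (float(rr.mean()), float(cc.mean()))
    return FunctionZones(
        contour1=contour1,
        contour2=contour2,
        contour3=contour3,
        epidermis_mask=region1 & ~region3,
        periphery_mask=region3 & ~region2,
        inner_mask=region2,
        stem_center=center,
        adaptive_mask=seg,
    )
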