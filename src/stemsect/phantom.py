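"""Synthetic stem cross-section phantoms with full ground truth.

The generator renders the concentric anatomy of a dried maize stem
slice: a bright closed epidermis ring, a periphery annulus of dense
small bundles embedded in mid-grey lignified ground tissue (a fraction
of the bundles fused into touching clumps, and a fraction in contact
with the rind), and a dark pith carrying sparse, larger, isolated
bundles over a near-zero parenchyma background with isolated cell-wall
speckle.  Bundle size decays with distance from the stem center
following the exponential law ``A(x) = a − b·e^{c·x}`` (mm² against mm)
observed on real slices, with multiplicative lognormal jitter.

Per-tissue Gaussian noise is applied to substance pixels only (air is
clamped to grey 0 by calibration), as per-tissue multiples of a global
``noise_sd``; ``noise_sd = 0`` therefore yields piecewise-constant
tissue intensities.  Rendering is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from skimage import draw

from .calibration import SliceImage
from .contours import ContourShape, contour_from_filled


class PackingError(RuntimeError):
    """Bundle placement failed: too many bundles for the available zone."""


#: printed area–distance law of real slices, the default size law (mm² vs mm)
AREA_LAW = (0.129, 5.594e-4, 0.475)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, population and intensity parameters of one phantom."""

    image_size: int = 768
    pixel_size_mm: float = 0.0271      #: 2×2-binned 13.55 µm acquisition
    outer_radius: int = 370            #: slice outline radius, px
    epidermis_width: int = 12          #: rind thickness, px (~0.33 mm)
    inner_radius: int = 215            #: pith radius (Contour2 analogue), px
    n_periphery: int = 200
    n_inner: int = 30
    size_law: tuple[float, float, float] = AREA_LAW
    size_jitter_sd: float = 0.08       #: lognormal sigma on bundle areas
    mean_epidermis: float = 200.0
    mean_matrix: float = 90.0          #: periphery ground tissue
    mean_bundle: float = 160.0
    mean_parenchyma: float = 20.0      #: pith cell-wall speckle value
    mean_background: float = 0.0
    tissue_rel_sd: float = 1.0         #: per-tissue SD = rel_sd × noise_sd
    speckle_fraction: float = 0.04     #: pith area fraction carrying speckle
    fusion_fraction: float = 0.05      #: periphery bundles placed in clumps
    epidermis_contact_fraction: float = 0.0  #: bundles touching the rind (stress mode)
    noise_sd: float = 10.0
    boundary_break: int = 0            #: arc length (px) of a rind crack
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.inner_radius < self.outer_radius - self.epidermis_width:
            raise ValueError("inner_radius must be below the rind inner edge")
        for m in (self.mean_epidermis, self.mean_matrix, self.mean_bundle,
                  self.mean_parenchyma, self.mean_background):
            if not 0 <= m <= 255:
                raise ValueError("intensity means must lie in [0, 255]")
        if min(self.n_periphery, self.n_inner) < 0:
            raise ValueError("bundle counts must be non-negative")


@dataclass(frozen=True)
class PhantomBundle:
    """Ground-truth record of one rendered bundle."""

    center: tuple[float, float]        #: (row, col), px
    area_px: int                       #: rendered pixel count
    zone: str                          #: 'periphery' or 'inner'
    clump_id: int | None               #: shared by deliberately fused bundles
    dc_mm: float                       #: distance to the stem center


@dataclass(frozen=True)
class PhantomTruth:
    """Rendered image plus the full annotation."""

    image: SliceImage
    epidermis_mask: np.ndarray
    periphery_mask: np.ndarray
    inner_mask: np.ndarray
    contour1: ContourShape
    contour2: ContourShape
    contour3: ContourShape
    bundles: tuple[PhantomBundle, ...]
    clumps: tuple[tuple[int, ...], ...]  #: bundle indices per fused clump
    substance_px: int                  #: nonzero pixels in the clean render
    spec: PhantomSpec

    @property
    def stem_center(self) -> tuple[float, float]:
        c = (self.image.shape[0] - 1) / 2.0
        return (c, c)

    def counts(self) -> dict[str, int]:
        n_p = sum(1 for b in self.bundles if b.zone == "periphery")
        return {"periphery": n_p, "inner": len(self.bundles) - n_p,
                "total": len(self.bundles)}


def _law_area_mm2(law: tuple[float, float, float], x_mm: float) -> float:
    a, b, c = law
    return a - b * math.exp(c * x_mm)


def _sample_ellipse(rng: np.random.Generator, spec: PhantomSpec,
                    dc_mm: float) -> tuple[float, float, float]:
    """(semi-major, semi-minor, orientation) in px from the size law."""
    area_mm2 = _law_area_mm2(spec.size_law, dc_mm)
    area_mm2 = max(area_mm2, 0.01) * rng.lognormal(0.0, spec.size_jitter_sd)
    area_px = area_mm2 / spec.pixel_size_mm ** 2
    q = rng.uniform(0.6, 1.0)  # axis ratio of near-round bundles
    a = math.sqrt(area_px / (math.pi * q))
    return a, q * a, rng.uniform(0, math.pi)


def _place(rng: np.random.Generator, r_lo: float, r_hi: float,
           center: float) -> tuple[float, float, float]:
    """Uniform-in-annulus position; returns (row, col, radius)."""
    r = math.sqrt(rng.uniform(r_lo ** 2, r_hi ** 2))
    t = rng.uniform(0, 2 * math.pi)
    return center + r * math.sin(t), center + r * math.cos(t), r


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomTruth:
    """Render one phantom slice and its annotation."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    center = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    rad = np.hypot(yy - center, xx - center)

    r1 = spec.outer_radius
    r3 = r1 - spec.epidermis_width           # rind inner edge
    r2 = spec.inner_radius
    epidermis = (rad <= r1) & (rad > r3)
    periphery = (rad <= r3) & (rad > r2)
    inner = rad <= r2

    base = np.zeros((n, n), dtype=float)
    base[epidermis] = spec.mean_epidermis
    base[periphery] = spec.mean_matrix

    tissue = np.zeros((n, n), dtype=np.uint8)  # 1=epi 2=matrix 3=bundle 4=speckle
    tissue[epidermis] = 1
    tissue[periphery] = 2

    bundles: list[PhantomBundle] = []
    clumps: list[tuple[int, ...]] = []
    placed: list[tuple[float, float, float]] = []  # (row, col, max semi-axis)

    def fits(row: float, col: float, s: float, pad: float) -> bool:
        if not placed:
            return True
        arr = np.asarray(placed)
        d = np.hypot(arr[:, 0] - row, arr[:, 1] - col)
        return bool((d >= arr[:, 2] + s + pad).all())

    def render_bundle(row: float, col: float, a: float, b: float,
                      phi: float, zone: str, clump: int | None) -> int:
        rr, cc = draw.ellipse(row, col, a, b, shape=(n, n), rotation=phi)
        base[rr, cc] = spec.mean_bundle
        tissue[rr, cc] = 3
        dc = math.hypot(row - center, col - center) * spec.pixel_size_mm
        bundles.append(PhantomBundle(center=(row, col), area_px=len(rr),
                                     zone=zone, clump_id=clump, dc_mm=dc))
        placed.append((row, col, max(a, b)))
        return len(bundles) - 1

    # --- periphery bundles ------------------------------------------------
    n_fused = int(round(spec.fusion_fraction * spec.n_periphery))
    n_contact = int(round(spec.epidermis_contact_fraction
                          * (spec.n_periphery - n_fused)))
    n_single = spec.n_periphery - n_fused - n_contact
    margin = 3.0
    budget = 2000 * max(spec.n_periphery + spec.n_inner, 1)
    attempts = 0

    def try_place(zone_lo: float, zone_hi: float, dc_hint: float | None,
                  pad: float, zone: str, clump: int | None,
                  contact: bool = False) -> int | None:
        nonlocal attempts
        if zone_lo >= zone_hi:
            return None  # annulus too thin for this placement mode
        while attempts < budget:
            attempts += 1
            row, col, r = _place(rng, zone_lo, zone_hi, center)
            dc = r * spec.pixel_size_mm
            a, b, phi = _sample_ellipse(rng, spec, dc)
            if contact:
                # re-center so the ellipse pokes into the rind
                r = r3 - 0.4 * b
                t = math.atan2(row - center, col - center)
                row = center + r * math.sin(t)
                col = center + r * math.cos(t)
            elif r + max(a, b) > zone_hi or r - max(a, b) < zone_lo:
                continue
            if not fits(row, col, max(a, b), pad):
                continue
            return render_bundle(row, col, a, b, phi, zone, clump)
        return None

    # fused clumps first (they need the most room): 2–4 bundles at center
    # spacing just below the sum of semi-axes
    remaining = n_fused
    clump_id = 0
    while remaining > 0:
        k = int(rng.integers(2, 5))
        k = min(k, remaining)
        if k < 2:
            break
        idx: list[int] = []
        first = try_place(r2 + 10 + margin, r3 - 10 - margin, None, 5.0,
                          "periphery", clump_id)
        if first is None:
            raise PackingError("clump seed placement failed")
        idx.append(first)
        for _ in range(k - 1):
            ar, ac, asz = placed[-1][0], placed[-1][1], placed[-1][2]
            ok = False
            for _ in range(200):
                dc = math.hypot(ar - center, ac - center) * spec.pixel_size_mm
                a, b, phi = _sample_ellipse(rng, spec, dc)
                t = rng.uniform(0, 2 * math.pi)
                d = 0.92 * (asz + max(a, b))  # touching, shallow overlap
                row, col = ar + d * math.sin(t), ac + d * math.cos(t)
                r = math.hypot(row - center, col - center)
                if r + max(a, b) > r3 - margin or r - max(a, b) < r2 + margin:
                    continue
                # must overlap clump-mate but keep clear of foreign bundles
                others = [p for j, p in enumerate(placed) if j not in idx]
                if any(math.hypot(row - pr, col - pc) < max(a, b) + ps + 2.0
                       for pr, pc, ps in others):
                    continue
                idx.append(render_bundle(row, col, a, b, phi, "periphery",
                                         clump_id))
                ok = True
                break
            if not ok:
                break
        if len(idx) >= 2:
            clumps.append(tuple(idx))
            remaining -= len(idx)
            clump_id += 1
        else:
            # lone clump seed degrades to a single bundle
            bundles[idx[0]] = replace(bundles[idx[0]], clump_id=None)
            remaining -= 1

    for _ in range(n_single):
        if try_place(r2 + margin, r3 - margin, None, 2.0, "periphery",
                     None) is None:
            raise PackingError("periphery bundle placement failed")
    for _ in range(n_contact):
        if try_place(r3 - 12.0, r3 - 4.0, None, 2.0, "periphery", None,
                     contact=True) is None:
            raise PackingError("epidermis-contact bundle placement failed")

    # --- inner bundles ----------------------------------------------------
    for _ in range(spec.n_inner):
        if try_place(0.0, r2 - 4.0, None, 4.0, "inner", None) is None:
            raise PackingError("inner bundle placement failed")

    # --- pith cell-wall speckle: isolated pixels on a jittered grid -------
    if spec.speckle_fraction > 0:
        cell = 4
        keep_p = spec.speckle_fraction * cell * cell
        bundle_halo = tissue == 3
        from scipy import ndimage as _ndi
        bundle_halo = _ndi.binary_dilation(bundle_halo, iterations=2)
        for gy in range(0, n - cell, cell):
            for gx in range(0, n - cell, cell):
                if rng.random() >= keep_p:
                    continue
                row = gy + int(rng.integers(0, 3))
                col = gx + int(rng.integers(0, 3))
                if rad[row, col] <= r2 - 3 and not bundle_halo[row, col]:
                    base[row, col] = spec.mean_parenchyma
                    tissue[row, col] = 4

    # --- rind crack -------------------------------------------------------
    if spec.boundary_break > 0:
        half_arc = 0.5 * spec.boundary_break / r1
        theta = np.arctan2(yy - center, xx - center)
        wedge = (np.abs(theta) < half_arc) & (rad > r2 + 2)
        base[wedge] = 0.0
        tissue[wedge] = 0

    substance_px = int((base > 0).sum())

    # --- noise ------------------------------------------------------------
    img = base.copy()
    if spec.noise_sd > 0:
        sub = base > 0
        noise = rng.normal(0.0, spec.tissue_rel_sd * spec.noise_sd,
                           size=base.shape)
        img[sub] = np.clip(base[sub] + noise[sub], 1, 255)
    img = np.floor(img + 0.5).astype(np.uint8)

    return PhantomTruth(
        image=SliceImage(img, pixel_size_mm=spec.pixel_size_mm,
                         source_id=f"phantom(seed={spec.seed})"),
        epidermis_mask=epidermis,
        periphery_mask=periphery,
        inner_mask=inner,
        contour1=contour_from_filled(rad <= r1),
        contour2=contour_from_filled(inner),
        contour3=contour_from_filled(rad <= r3),
        bundles=tuple(bundles),
        clumps=tuple(clumps),
        substance_px=substance_px,
        spec=spec,
    )


def phantom_batch(base_spec: PhantomSpec | None = None, n_slices: int = 20,
                  vary: dict[str, tuple[float, float]] | None = None,
                  seed: int = 0) -> list[PhantomTruth]:
    """Seeded batch of phantoms with parameters drawn from ranges.

    ``vary`` maps spec field names to (low, high) ranges; the special key
    ``n_total`` draws a total bundle count split ~85/15 between the
    periphery and inner zones, mirroring real slices.
    """
    base_spec = base_spec or PhantomSpec()
    vary = dict(vary or {})
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_slices):
        fields: dict[str, object] = {"seed": int(rng.integers(0, 2 ** 31))}
        if "n_total" in vary:
            lo, hi = vary["n_total"]
            total = int(rng.integers(int(lo), int(hi) + 1))
            fields["n_periphery"] = int(round(0.85 * total))
            fields["n_inner"] = total - fields["n_periphery"]
        for name, (lo, hi) in vary.items():
            if name == "n_total":
                continue
            val = rng.uniform(lo, hi)
            if isinstance(getattr(base_spec, name), int):
                val = int(round(val))
            fields[name] = val
        out.append(generate_phantom(replace(base_spec, **fields)))
    return out
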