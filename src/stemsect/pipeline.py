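"""Single-slice orchestration: zones → bundles → traits → tables."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationRange, SliceImage
from .traits import (contour_traits, layer_partition, layer_stats,
                     voronoi_growth_space, zone_growth_traits)
from .vbdetect import DetectParams, detect_vascular_bundles
from .zones import ZoneParams, detect_function_zones


@dataclass(frozen=True)
class PipelineParams:
    """Everything the full pipeline needs, with the working defaults."""

    zone: ZoneParams = field(default_factory=ZoneParams)
    detect: DetectParams = field(default_factory=DetectParams)
    pixel_size_mm: float = 0.01355
    calibration: CalibrationRange | None = None
    n_layers: int = 5
    layer_mode: str = "EA"
    kmeans_k: int = 3
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.calibration is None:
            d.pop("calibration")
        return d


@dataclass
class SliceResult:
    zones: object
    bundles: list
    zone_traits: object
    layers: object
    voronoi_mm2: dict[int, float]
    bundle_table: pd.DataFrame

    def summary_row(self) -> dict:
        zt = self.zone_traits
        return {
            "NVBPZ": zt.nvbpz, "NVBIZ": zt.nvbiz,
            "AEFZ_epidermis": zt.aefz_mm2["epidermis"],
            "AEFZ_periphery": zt.aefz_mm2["periphery"],
            "AEFZ_inner": zt.aefz_mm2["inner"],
            "AVBPZ": zt.avbpz_mm2, "AVBIZ": zt.avbiz_mm2,
            "VAVPZ": zt.vavpz_mm2, "VAVIZ": zt.vaviz_mm2,
            "slice_AI": zt.slice_ai,
            "substance_ratio": zt.substance_ratio,
            "epidermis_thickness": zt.epidermis_thickness_mm,
        }


def process_slice(img: SliceImage, params: PipelineParams | None = None
                  ) -> SliceResult:
    """Run the full pipeline on one calibrated slice."""
    from .traits import kmeans_area_classes

    p = params or PipelineParams()
    zones = detect_function_zones(img, p.zone)
    bundles = detect_vascular_bundles(img, zones, p.detect, p.zone)

    for b in bundles:
        b.traits = contour_traits(b.contour, img, zones.stem_center)

    voronoi: dict[int, float] = {}
    if bundles:
        centers = [b.contour.centroid for b in bundles]
        for i, a in enumerate(voronoi_growth_space(centers, zones.contour3,
                                                   img.pixel_size_mm)):
            voronoi[i] = a

    layers = layer_partition(zones, p.n_layers, p.layer_mode)
    layer_stats(layers, zones, bundles, img, voronoi)
    zt = zone_growth_traits(zones, bundles, img)

    rows = []
    areas = [b.traits.A for b in bundles]
    klabels = None
    if bundles and p.kmeans_k <= len(set(areas)):
        klabels = kmeans_area_classes(areas, p.kmeans_k, p.seed)
    for i, b in enumerate(bundles):
        row = dataclasses.asdict(b.traits)
        row.update({
            "zone": b.zone,
            "layer": layers.layer_of(b.contour.centroid),
            "voronoi_area": voronoi.get(i, np.nan),
            "merged_flag": b.merged_flag,
            "area_class": int(klabels[i]) if klabels is not None else -1,
        })
        rows.append(row)
    table = pd.DataFrame(rows)
    return SliceResult(zones=zones, bundles=bundles, zone_traits=zt,
                       layers=layers, voronoi_mm2=voronoi,
                       bundle_table=table)
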