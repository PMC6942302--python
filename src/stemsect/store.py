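"""VBF-JSON serialization, counting validation and batch orchestration.

Every object the pipeline produces is a contour, so a whole slice —
calibration, zone hierarchy, layer scheme, bundles with traits, and the
parameters that produced them — serializes to a single inspectable JSON
document (the VBF file).  Contour vertices are stored as exact decimal
numbers; deserialization reproduces every point and trait value
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calibration import CalibrationRange, SliceImage
from .contours import ContourShape

SCHEMA_VERSION = "1.0"

logger = logging.getLogger("stemsect")


class VbfFormatError(ValueError):
    """Malformed or wrong-schema VBF file."""


def _version() -> str:
    from . import __version__
    return __version__


@dataclass
class VbfDocument:
    """In-memory form of one VBF file."""

    pixel_size_mm: float
    zones: dict                      #: contour1/2/3 points + stem_center
    bundles: list[dict] = field(default_factory=list)
    layers: dict | None = None
    calibration: dict | None = None
    provenance: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION


def _contour_to_json(c: ContourShape) -> dict:
    return {"points": c.points.tolist(), "area_px": int(c.area_px),
            "centroid": [float(c.centroid[0]), float(c.centroid[1])]}


def _contour_from_json(d: dict) -> ContourShape:
    return ContourShape(points=np.asarray(d["points"], dtype=float),
                        area_px=int(d["area_px"]),
                        centroid=tuple(d["centroid"]))


def document_from_results(img: SliceImage, zones, bundles,
                          layers=None, params: dict | None = None,
                          cal: CalibrationRange | None = None) -> VbfDocument:
    """Assemble a VbfDocument from pipeline outputs."""
    zdict = {
        "contour1": _contour_to_json(zones.contour1),
        "contour2": _contour_to_json(zones.contour2),
        "contour3": _contour_to_json(zones.contour3),
        "stem_center": [float(zones.stem_center[0]),
                        float(zones.stem_center[1])],
    }
    bl = []
    for b in bundles:
        rec = {"contour": _contour_to_json(b.contour), "zone": b.zone,
               "merged_flag": bool(b.merged_flag)}
        if b.traits is not None:
            rec["traits"] = dataclasses.asdict(b.traits)
        bl.append(rec)
    layer_dict = None
    if layers is not None:
        layer_dict = {"mode": layers.mode, "n_layers": layers.n_layers}
        if layers.table is not None:
            layer_dict["table"] = layers.table.to_dict(orient="records")
    return VbfDocument(
        pixel_size_mm=img.pixel_size_mm, zones=zdict, bundles=bl,
        layers=layer_dict,
        calibration=(dataclasses.asdict(cal) if cal else None),
        provenance={"source_id": img.source_id, "params": params or {},
                    "tool": "stemsect", "tool_version": _version()},
    )


def serialize_vbf(doc: VbfDocument, path: str | Path) -> None:
    """Write the document as JSON text."""
    payload = dataclasses.asdict(doc)
    Path(path).write_text(json.dumps(payload, indent=1))


def deserialize_vbf(path: str | Path) -> VbfDocument:
    """Load and validate a VBF-JSON file."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise VbfFormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise VbfFormatError(f"{path}: missing schema_version")
    if payload["schema_version"] != SCHEMA_VERSION:
        raise VbfFormatError(
            f"{path}: schema {payload['schema_version']!r} unsupported "
            f"(expected {SCHEMA_VERSION!r})")
    try:
        return VbfDocument(**payload)
    except TypeError as exc:
        raise VbfFormatError(f"{path}: malformed document ({exc})") from exc


def zones_from_document(doc: VbfDocument) -> dict:
    """Contours and stem center reconstructed from a document."""
    z = doc.zones
    return {
        "contour1": _contour_from_json(z["contour1"]),
        "contour2": _contour_from_json(z["contour2"]),
        "contour3": _contour_from_json(z["contour3"]),
        "stem_center": tuple(z["stem_center"]),
    }


def counting_r2(observed, computed) -> float:
    """Coefficient of determination of computed counts against observed.

    Ordinary least squares with free intercept; R² = r² of the two
    vectors.  Zero variance in the observed counts is undefined and
    raises; zero variance in the computed counts gives 0 (no linear
    relation recovered).
    """
    obs = np.asarray(observed, dtype=float)
    comp = np.asarray(computed, dtype=float)
    if obs.shape != comp.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.var(obs) == 0:
        raise ValueError("observed counts have zero variance: R² undefined")
    if np.var(comp) == 0:
        return 0.0
    r = np.corrcoef(obs, comp)[0, 1]
    return float(r ** 2)


def run_batch(inputs, out_dir: str | Path, params=None,
              layer_mode: str = "EA", n_layers: int = 5):
    """Process a list of image paths or phantoms; write VBF + CSV outputs.

    Per-slice failures are logged and skipped.  Returns the aggregate
    per-slice summary DataFrame (also written as ``summary.csv``).
    """
    import pandas as pd

    from .pipeline import PipelineParams, process_slice
    from .calibration import load_slice
    from .phantom import PhantomTruth

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise RuntimeError(f"output directory {out_dir} is not writable") from exc

    params = params or PipelineParams(layer_mode=layer_mode,
                                      n_layers=n_layers)
    rows = []
    for i, item in enumerate(inputs):
        name = f"slice_{i:03d}"
        t0 = time.perf_counter()
        try:
            if isinstance(item, PhantomTruth):
                img = item.image
            elif isinstance(item, SliceImage):
                img = item
            else:
                name = Path(item).stem
                img = load_slice(item, params.pixel_size_mm, params.calibration)
            result = process_slice(img, params)
        except Exception as exc:  # error isolation: one bad slice never aborts
            logger.warning("slice %s failed: %s", name, exc)
            continue
        doc = document_from_results(img, result.zones, result.bundles,
                                    result.layers, params.to_dict())
        serialize_vbf(doc, out_dir / f"{name}.vbf.json")
        result.bundle_table.to_csv(out_dir / f"{name}_bundles.csv",
                                   index=False)
        row = {"slice": name, "n_bundles": len(result.bundles),
               "elapsed_s": round(time.perf_counter() - t0, 3)}
        row.update(result.summary_row())
        rows.append(row)
        logger.info("slice %s: %d bundles in %.1fs", name,
                    len(result.bundles), row["elapsed_s"])
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "summary.csv", index=False)
    return table
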