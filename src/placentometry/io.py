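"""Readers/writers for the package's on-disk interfaces.

Slides are 8-bit RGB TIFF or PNG; label masks are single-channel PNG using
the integer codes of :mod:`placentometry.config` plus a JSON sidecar with
pixel size and provenance; vessel instances are a 16-bit label TIFF plus a
per-instance CSV; exclusion polygons are GeoJSON in pixel coordinates
(x = column, y = row).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import ValidationError
from .imaging import LabelMask, QCReport, SlideImage, VesselInstances


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_slide(image: SlideImage, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.rgb)
    else:
        Image.fromarray(image.rgb).save(path)
    _sidecar(path).write_text(
        json.dumps({"pixel_size_um": image.pixel_size_um, "id": image.id})
    )


def load_slide(path, pixel_size_um: float | None = None) -> SlideImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        rgb = tifffile.imread(path)
    else:
        rgb = np.asarray(Image.open(path).convert("RGB"))
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValidationError(f"no pixel size for {path}; pass pixel_size_um")
    return SlideImage(rgb.astype(np.uint8), float(px), meta.get("id", path.stem))


def save_label_mask(mask: LabelMask, path, extra_meta: dict | None = None) -> None:
    path = Path(path)
    Image.fromarray(mask.labels.astype(np.uint8), mode="L").save(path)
    meta = {"pixel_size_um": mask.pixel_size_um,
            "codes": {"0": "background", "1": "villi", "2": "fibrin",
                      "3": "artifact", "4": "excluded"}}
    if mask.artifact_fraction_raw is not None:
        meta["artifact_fraction_raw"] = mask.artifact_fraction_raw
    meta.update(extra_meta or {})
    _sidecar(path).write_text(json.dumps(meta))


def load_label_mask(path) -> LabelMask:
    path = Path(path)
    labels = np.asarray(Image.open(path))
    meta = json.loads(_sidecar(path).read_text())
    return LabelMask(labels, float(meta["pixel_size_um"]),
                     meta.get("artifact_fraction_raw"))


def save_vessels(vessels: VesselInstances, stem) -> None:
    """Write ``<stem>.tif`` (16-bit instance labels) and ``<stem>.csv``."""
    stem = Path(stem)
    tifffile.imwrite(stem.with_suffix(".tif"),
                     vessels.instance_labels.astype(np.uint16))
    vessels.records.to_csv(stem.with_suffix(".csv"), index=False)


def load_vessels(stem, pixel_size_um: float) -> VesselInstances:
    stem = Path(stem)
    labels = tifffile.imread(stem.with_suffix(".tif")).astype(np.int32)
    records = pd.read_csv(stem.with_suffix(".csv"))
    return VesselInstances(labels, records, pixel_size_um)


def save_qc(report: QCReport, path) -> None:
    Path(path).write_text(json.dumps(vars(report), indent=2))


def read_exclusion_polygons(path) -> list[np.ndarray]:
    """Read polygons from GeoJSON; coordinates are (x=col, y=row) pixels."""
    gj = json.loads(Path(path).read_text())
    feats = gj.get("features", [gj]) if gj.get("type") == "FeatureCollection" else [gj]
    polys = []
    for f in feats:
        geom = f.get("geometry", f)
        if geom.get("type") != "Polygon":
            raise ValidationError("only Polygon geometries are supported")
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        polys.append(ring[:, ::-1])  # (x, y) -> (row, col)
    return polys
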