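"""On-disk formats: float32 TIFF arrays with JSON geometry sidecars.

Every image or sinogram is stored as a single-page 32-bit float TIFF
next to a ``<name>.json`` sidecar that carries the full acquisition
geometry (and, for sinograms, the explicit angle list), so a file pair
is self-describing.  Iteration traces are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .mar import IterationTrace
from .tomo import Geometry, ImageGrid, Sinogram

__all__ = [
    "geometry_to_dict",
    "geometry_from_dict",
    "save_image",
    "load_image",
    "save_sinogram",
    "load_sinogram",
    "save_trace",
    "load_trace",
    "save_manifest",
]


def geometry_to_dict(geometry: Geometry) -> dict:
    return {
        "n_views": geometry.n_views,
        "n_channels": geometry.n_channels,
        "image_size": geometry.image_size,
        "angular_range_deg": geometry.angular_range_deg,
        "pixel_spacing": geometry.pixel_spacing,
        "channel_spacing": geometry.channel_spacing,
        "fov": geometry.fov,
    }


def geometry_from_dict(d: dict) -> Geometry:
    return Geometry(
        n_views=int(d["n_views"]),
        n_channels=int(d["n_channels"]),
        image_size=int(d["image_size"]),
        angular_range_deg=float(d.get("angular_range_deg", 180.0)),
        pixel_spacing=float(d.get("pixel_spacing", 1.0)),
        channel_spacing=float(d["channel_spacing"]) if d.get("channel_spacing") else None,
        fov=d.get("fov", "circle"),
    )


def _sidecar(path) -> Path:
    return Path(path).with_suffix(".json")


def save_image(path, image: ImageGrid, geometry: Geometry | None = None) -> None:
    """Write an image as float32 TIFF + JSON sidecar."""
    tifffile.imwrite(str(path), image.values.astype(np.float32))
    meta: dict = {"kind": "image", "spacing": image.spacing}
    if geometry is not None:
        meta["geometry"] = geometry_to_dict(geometry)
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_image(path) -> ImageGrid:
    vals = tifffile.imread(str(path)).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return ImageGrid(vals, spacing=float(meta.get("spacing", 1.0)))


def save_sinogram(path, sinogram: Sinogram) -> None:
    """Write a sinogram as float32 TIFF + sidecar with geometry and angles."""
    tifffile.imwrite(str(path), sinogram.values.astype(np.float32))
    meta = {
        "kind": "sinogram",
        "geometry": geometry_to_dict(sinogram.geometry),
        "angles_deg": [float(a) for a in sinogram.angles_deg],
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_sinogram(path, geometry_path=None) -> Sinogram:
    """Read a sinogram TIFF; geometry comes from its sidecar by default."""
    vals = tifffile.imread(str(path)).astype(float)
    side = Path(geometry_path) if geometry_path else _sidecar(path)
    meta = json.loads(side.read_text())
    gdict = meta["geometry"] if "geometry" in meta else meta
    geometry = geometry_from_dict(gdict)
    angles = meta.get("angles_deg")
    return Sinogram(
        vals, geometry, np.asarray(angles, float) if angles is not None else None
    )


def save_trace(path, trace: IterationTrace) -> None:
    pd.DataFrame(
        {"iteration": np.arange(len(trace.tv_values)), "tv_norm": trace.tv_values}
    ).to_csv(path, index=False)


def load_trace(path) -> IterationTrace:
    df = pd.read_csv(path)
    return IterationTrace(df["tv_norm"].to_numpy())


def save_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
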