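"""Figure of merit and three-method comparison harness.

Metal streaks manifest as dark undershoots next to the bright metal; the
figure of merit is the minimum pixel value inside a square region of
interest placed on such an undershoot (40x40 by default).  A smaller
(more negative) minimum means a more severe artifact, so between methods
a *larger* ROI minimum is better.  Within one scene the three methods —
conventional FBP, image-domain TV descent, and projection-domain TV
restoration — are compared on the same ROI; values are never compared
across scenes, which contain different objects.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .mar import MARConfig, MetalImage, run_mar
from .tomo import Geometry, ImageGrid, Sinogram, ValidationError, fbp
from .tv import image_domain_tv_reconstruct, tv_norm

__all__ = [
    "ROISpec",
    "ComparisonReport",
    "roi_min",
    "auto_roi",
    "compare_methods",
    "display_window",
    "json_log",
]

logger = logging.getLogger(__name__)

METHODS = ("fbp", "tv_image_domain", "tv_projection_domain")


def json_log(event: str, **fields) -> None:
    """Structured JSON-lines run log entry."""
    logger.info(json.dumps({"event": event, "time": time.time(), **fields}))


@dataclass(frozen=True)
class ROISpec:
    """Square region of interest: top-left corner plus height/width."""

    row: int
    col: int
    height: int = 40
    width: int = 40

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValidationError("ROI height/width must be >= 1")
        if self.row < 0 or self.col < 0:
            raise ValidationError("ROI top-left indices must be >= 0")

    def check_inside(self, image: ImageGrid) -> None:
        n = image.size
        if self.row + self.height > n or self.col + self.width > n:
            raise ValidationError(
                f"ROI {self} does not fit inside a {n}x{n} image"
            )


@dataclass
class ComparisonReport:
    """Per-method ROI minima and TV norms for one scene."""

    roi: ROISpec
    roi_min: dict = field(default_factory=dict)
    tv_norm: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)


def roi_min(image: ImageGrid, roi: ROISpec) -> float:
    """Minimum pixel value in the ROI (the artifact-severity score)."""
    roi.check_inside(image)
    block = image.values[roi.row : roi.row + roi.height, roi.col : roi.col + roi.width]
    return float(block.min())


def auto_roi(metal: MetalImage, image_size: int, size: int = 40) -> ROISpec:
    """Place the ROI next to the largest metal blob, deterministically.

    The ROI is centered 10 px beyond the right edge of the largest
    connected metal component, at its centroid row (the undershoot hugs
    the metal), then shifted as needed to fit inside the image.  With no
    metal, the ROI sits at the image center.
    """
    labels = cc_label(metal.indicator, connectivity=2)
    if labels.max() == 0:
        cr = cc = image_size // 2
    else:
        biggest = max(regionprops(labels), key=lambda r: r.area)
        cr = int(round(biggest.centroid[0]))
        cc = int(biggest.bbox[3] - 1 + 10)  # 10 px right of the blob edge
    row = int(np.clip(cr - size // 2, 0, image_size - size))
    col = int(np.clip(cc - size // 2, 0, image_size - size))
    return ROISpec(row=row, col=col, height=size, width=size)


def display_window(image: ImageGrid) -> tuple[float, float]:
    """Grayscale window for figure export: (min, 0.3 * max)."""
    lo = float(image.values.min())
    hi = 0.3 * float(image.values.max())
    if hi <= lo:
        logger.warning("degenerate display window (%g, %g)", lo, hi)
    return lo, hi


def compare_methods(
    sinogram: Sinogram,
    geometry: Geometry,
    roi: ROISpec | None = None,
    mar_config: MARConfig | None = None,
    baseline_lambda_fid: float = 0.001,
    baseline_lambda_tv: float = 0.0005,
    baseline_n_iter: int | None = None,
) -> ComparisonReport:
    """Run the three methods on one sinogram and score them on one ROI.

    The raw FBP is computed once and shared: it is the first method's
    output, the baseline's initial image, and the image the MAR pipeline
    segments.  The baseline iteration count defaults to the MAR count so
    the comparison is iteration-matched.
    """
    if mar_config is None:
        mar_config = MARConfig()
    if baseline_n_iter is None:
        baseline_n_iter = mar_config.n_iter

    json_log(
        "compare_methods.start",
        n_iter=mar_config.n_iter,
        lambda_step=mar_config.lambda_step,
        threshold_fraction=mar_config.threshold_fraction,
    )
    mar = run_mar(sinogram, geometry, mar_config)
    raw = mar.raw_fbp
    baseline = image_domain_tv_reconstruct(
        sinogram,
        geometry,
        lambda_fid=baseline_lambda_fid,
        lambda_tv=baseline_lambda_tv,
        n_iter=baseline_n_iter,
    )
    if roi is None:
        roi = auto_roi(mar.metal, geometry.image_size)

    images = {
        "fbp": raw,
        "tv_image_domain": baseline,
        "tv_projection_domain": mar.final_image,
    }
    report = ComparisonReport(
        roi=roi,
        roi_min={name: roi_min(img, roi) for name, img in images.items()},
        tv_norm={name: tv_norm(img) for name, img in images.items()},
        artifacts={"mar": mar, "images": images},
    )
    json_log("compare_methods.done", roi_min=report.roi_min, tv_norm=report.tv_norm)
    return report
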