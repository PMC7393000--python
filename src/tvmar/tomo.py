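"""Parallel-beam Radon transform and filtered backprojection.

The discrete forward operator ``radon_forward`` and the ramp-filtered
inverse ``fbp`` are the two building blocks used throughout the package:
the metal-artifact-reduction loop alternates between them, and the
beam-hardening simulator uses ``radon_forward`` to compute per-material
path lengths.

Conventions (frozen; the iterative methods compose the two operators on
the same grid, so the discretization must not drift):

* Images are square ``N x N`` arrays; row index increases downward,
  column index rightward.
* View angles are evenly spaced over ``[0, angular_range_deg)`` and are
  measured from the image x-axis.
* The detector coordinate ``t`` is zero at the detector center.
* The reconstruction is restricted to the inscribed circle of the grid;
  pixels outside it are set to zero by both operators.
* ``radon_forward`` returns physical line integrals: the discrete sums
  are scaled by ``pixel_spacing``, so a disc of radius ``r`` and value
  ``mu`` projects to ``2*r*mu`` on the central channel.
* ``fbp(radon_forward(f)) ~= f`` — the standard ``pi / (2 n_views)``
  normalization lives inside the operators, so step sizes quoted against
  "normalized" operators keep their meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import iradon, radon

__all__ = [
    "GeometryError",
    "ValidationError",
    "ConfigurationError",
    "Geometry",
    "ImageGrid",
    "Sinogram",
    "radon_forward",
    "fbp",
    "backproject",
    "SUPPORTED_FILTERS",
]


class GeometryError(ValueError):
    """Shape or geometry metadata does not match the data it describes."""


class ValidationError(ValueError):
    """Input data violates a precondition (non-finite values, bad weights...)."""


class ConfigurationError(ValueError):
    """A configuration value is outside its admissible range."""


#: Apodization windows accepted by :func:`fbp` (pure ramp is the default).
SUPPORTED_FILTERS = ("ramp", "hann", "hamming", "cosine", "shepp-logan")


def _diagonal_channels(image_size: int) -> int:
    # skimage pads to ceil(sqrt(2) * N) before projecting with circle=False
    return int(np.ceil(np.sqrt(2) * image_size))


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam acquisition geometry.

    Parameters
    ----------
    n_views:
        Number of projection angles, evenly spaced on
        ``[0, angular_range_deg)``.
    n_channels:
        Detector bins per view.  For ``fov="circle"`` this must equal
        ``image_size`` (the detector covers the inscribed circle); for
        ``fov="diagonal"`` it must equal ``ceil(sqrt(2) * image_size)``
        (the detector covers the image diagonal).
    image_size:
        Side length N of the square reconstruction grid.
    pixel_spacing:
        Physical size of one pixel (e.g. cm); line integrals are in
        units of image values times this length.
    channel_spacing:
        Detector bin width; the discretization ties it to
        ``pixel_spacing``, so it defaults to that value and must match.
    """

    n_views: int
    n_channels: int
    image_size: int
    angular_range_deg: float = 180.0
    pixel_spacing: float = 1.0
    channel_spacing: float | None = None
    fov: str = "circle"

    def __post_init__(self) -> None:
        for name in ("n_views", "n_channels", "image_size"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise GeometryError(f"{name} must be a positive integer, got {v!r}")
        if self.angular_range_deg <= 0:
            raise GeometryError("angular_range_deg must be positive")
        if self.pixel_spacing <= 0:
            raise GeometryError("pixel_spacing must be positive")
        if self.channel_spacing is None:
            object.__setattr__(self, "channel_spacing", self.pixel_spacing)
        elif not np.isclose(self.channel_spacing, self.pixel_spacing):
            raise GeometryError(
                "channel_spacing must equal pixel_spacing for this discretization"
            )
        if self.fov not in ("circle", "diagonal"):
            raise GeometryError(f"fov must be 'circle' or 'diagonal', got {self.fov!r}")
        expected = (
            self.image_size if self.fov == "circle" else _diagonal_channels(self.image_size)
        )
        if self.n_channels != expected:
            raise GeometryError(
                f"n_channels={self.n_channels} inconsistent with image_size="
                f"{self.image_size} and fov={self.fov!r} (expected {expected})"
            )

    @classmethod
    def for_image(
        cls,
        image_size: int,
        n_views: int,
        *,
        angular_range_deg: float = 180.0,
        pixel_spacing: float = 1.0,
        fov: str = "circle",
    ) -> "Geometry":
        """Build a geometry whose detector matches the grid and field of view."""
        n_channels = image_size if fov == "circle" else _diagonal_channels(image_size)
        return cls(
            n_views=n_views,
            n_channels=n_channels,
            image_size=image_size,
            angular_range_deg=angular_range_deg,
            pixel_spacing=pixel_spacing,
            fov=fov,
        )

    @property
    def angles_deg(self) -> np.ndarray:
        """View angles in degrees, evenly spaced on [0, angular_range_deg)."""
        return np.linspace(
            0.0, self.angular_range_deg, self.n_views, endpoint=False
        )

    def circle_mask(self) -> np.ndarray:
        """Boolean mask of the inscribed reconstruction circle."""
        n = self.image_size
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[0:n, 0:n]
        return (xx - c) ** 2 + (yy - c) ** 2 <= (n / 2.0) ** 2


def _check_finite(values: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{what} contains non-finite values")


@dataclass
class ImageGrid:
    """Square 2-D grid of attenuation values with its pixel spacing."""

    values: np.ndarray
    spacing: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise GeometryError(
                f"image must be square 2-D, got shape {self.values.shape}"
            )
        _check_finite(self.values, "image")

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass
class Sinogram:
    """views x channels grid of line integrals with its view angles."""

    values: np.ndarray
    geometry: Geometry
    angles_deg: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.geometry.n_views, self.geometry.n_channels):
            raise GeometryError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"({self.geometry.n_views}, {self.geometry.n_channels})"
            )
        _check_finite(self.values, "sinogram")
        if self.angles_deg is None:
            self.angles_deg = self.geometry.angles_deg
        else:
            self.angles_deg = np.asarray(self.angles_deg, dtype=float)
            if self.angles_deg.shape != (self.geometry.n_views,):
                raise GeometryError("angles_deg length must equal n_views")


def _check_image(image: ImageGrid, geometry: Geometry) -> None:
    if image.size != geometry.image_size:
        raise GeometryError(
            f"image size {image.size} does not match geometry image_size "
            f"{geometry.image_size}"
        )


def radon_forward(image: ImageGrid, geometry: Geometry) -> Sinogram:
    """Discrete parallel-beam Radon transform (line integrals of *image*).

    The operator is linear, and an everywhere-nonnegative image projects
    to values no smaller than a tiny interpolation undershoot
    (``-1e-6 * max``).  For ``fov="circle"`` the image is zeroed outside
    the inscribed circle first — the operator is defined on that support.
    """
    _check_image(image, geometry)
    vals = image.values
    if geometry.fov == "circle":
        vals = vals * geometry.circle_mask()
        circle = True
    else:
        circle = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        sino = radon(vals, theta=geometry.angles_deg, circle=circle)
    # skimage returns (channels, views) in pixel units; we store
    # (views, channels) in physical units.
    return Sinogram(sino.T * geometry.pixel_spacing, geometry)


def _check_sino(sinogram: Sinogram, geometry: Geometry) -> None:
    if sinogram.values.shape != (geometry.n_views, geometry.n_channels):
        raise GeometryError(
            f"sinogram shape {sinogram.values.shape} does not match geometry "
            f"({geometry.n_views}, {geometry.n_channels})"
        )


def fbp(sinogram: Sinogram, geometry: Geometry, filter_name: str = "ramp") -> ImageGrid:
    """Ramp-filtered backprojection of *sinogram* onto the image grid.

    Linear in the sinogram; ``fbp(radon_forward(f)) ~= f`` for smooth
    images supported on the reconstruction circle.
    """
    _check_sino(sinogram, geometry)
    if filter_name not in SUPPORTED_FILTERS:
        raise ConfigurationError(
            f"unsupported filter {filter_name!r}; choose one of {SUPPORTED_FILTERS}"
        )
    rec = iradon(
        sinogram.values.T / geometry.pixel_spacing,
        theta=sinogram.angles_deg,
        circle=(geometry.fov == "circle"),
        filter_name=filter_name,
        output_size=geometry.image_size,
    )
    return ImageGrid(rec, spacing=geometry.pixel_spacing)


def backproject(sinogram: Sinogram, geometry: Geometry) -> ImageGrid:
    """Unfiltered backprojection (smearing of the sinogram over the grid).

    This is the Radon adjoint up to a single global scale constant
    (``2 * n_views / pi``, from the backprojection normalization); the
    image-domain baseline uses it as the gradient direction of its
    data-fidelity term, for which a fixed positive rescaling of the true
    adjoint is equally valid and much better conditioned.
    """
    _check_sino(sinogram, geometry)
    rec = iradon(
        sinogram.values.T / geometry.pixel_spacing,
        theta=sinogram.angles_deg,
        circle=(geometry.fov == "circle"),
        filter_name=None,
        output_size=geometry.image_size,
    )
    return ImageGrid(rec, spacing=geometry.pixel_spacing)
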