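"""Synthetic bag phantoms and polychromatic (beam-hardened) sinograms.

Real metal-corrupted scans pair an unknown object with an unknown X-ray
spectrum; this module builds the controlled counterpart: a
piecewise-constant ellipse phantom with known material maps, a discrete
source spectrum, and two sinograms —

* ``sino_mono``: ideal monochromatic line integrals at a reference
  energy (the ground truth the restoration is judged against), and
* ``sino_poly``: polychromatic Beer-Lambert measurements,

      p_poly = -ln( sum_k w_k * exp(-sum_m mu_m(E_k) * L_m) )

  where ``L_m`` is the per-material path length of the ray and ``w_k``
  the spectral weights.

Because the metal attenuation falls steeply with energy while soft
material is nearly flat, rays through metal come out *smaller* than
their true line integrals — the exact corruption the projection-domain
restoration targets — while metal-free rays are essentially accurate.
Everything is deterministic given the seed; optional Poisson
transmission noise is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .mar import MetalImage
from .tomo import (
    ConfigurationError,
    Geometry,
    ImageGrid,
    Sinogram,
    ValidationError,
    radon_forward,
)

__all__ = [
    "MaterialModel",
    "SpectrumModel",
    "PhantomSpec",
    "SimulationOutput",
    "default_materials",
    "default_spectrum",
    "make_phantom",
    "polychromatic_project",
    "make_reference_scenario",
    "DEFAULT_SEED",
]

#: Seed of the stock desk-scale scenario.
DEFAULT_SEED = 20200721


@dataclass(frozen=True)
class MaterialModel:
    """Tabulated linear attenuation mu(E) for one material label."""

    label: str
    energies_kev: tuple
    mu_per_cm: tuple

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_kev, float)
        mu = np.asarray(self.mu_per_cm, float)
        if e.ndim != 1 or e.shape != mu.shape or e.size < 1:
            raise ConfigurationError("energies and mu tables must match, length >= 1")
        if e.size > 1 and not np.all(np.diff(e) > 0):
            raise ConfigurationError("energy grid must be strictly increasing")
        if not np.all(mu > 0):
            raise ConfigurationError("attenuation values must be positive")

    def mu_at(self, energy_kev) -> np.ndarray:
        """Linear interpolation of mu on the energy grid (clamped ends)."""
        return np.interp(
            np.asarray(energy_kev, float),
            np.asarray(self.energies_kev, float),
            np.asarray(self.mu_per_cm, float),
        )


@dataclass(frozen=True)
class SpectrumModel:
    """Discrete source spectrum and the monochromatic reference energy."""

    energies_kev: tuple
    weights: tuple
    reference_energy_kev: float

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_kev, float)
        w = np.asarray(self.weights, float)
        if e.shape != w.shape or e.ndim != 1 or e.size < 1:
            raise ConfigurationError("energies and weights must match, length >= 1")
        if e.size > 1 and not np.all(np.diff(e) > 0):
            raise ConfigurationError("spectrum energies must be strictly increasing")
        if np.any(w < 0):
            raise ValidationError("spectrum weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValidationError(
                f"spectrum weights must sum to 1 (got {w.sum()!r})"
            )


# Invented but qualitatively shaped tables: water-like soft material is
# nearly flat over the diagnostic range; the metal decays steeply
# (~50x soft at 40 keV), which is what depresses its line integrals.
_SOFT = MaterialModel(
    label="soft",
    energies_kev=(20.0, 40.0, 60.0, 80.0, 100.0, 120.0, 140.0),
    mu_per_cm=(0.81, 0.27, 0.21, 0.18, 0.17, 0.16, 0.15),
)
_METAL = MaterialModel(
    label="metal",
    energies_kev=(20.0, 40.0, 60.0, 80.0, 100.0, 120.0, 140.0),
    mu_per_cm=(60.0, 15.0, 6.0, 3.2, 2.1, 1.6, 1.3),
)

#: Labels treated as metal when building the true metal map.
METAL_LABELS = frozenset({"metal"})


def default_materials() -> dict[str, MaterialModel]:
    """The two stock materials: water-like ``soft`` and ``metal``."""
    return {"soft": _SOFT, "metal": _METAL}


def default_spectrum() -> SpectrumModel:
    """Five-point 120 kVp-like spectrum.

    The monochromatic reference sits at the beam's effective energy
    (60 keV): there mu(E_ref) is at least the spectrum-weighted mean
    attenuation of both stock materials, so by Jensen's inequality the
    polychromatic line integral never exceeds the monochromatic one —
    metal corruption is a pure depression, the regime the restoration
    method assumes.
    """
    return SpectrumModel(
        energies_kev=(40.0, 60.0, 80.0, 100.0, 120.0),
        weights=(0.15, 0.30, 0.25, 0.20, 0.10),
        reference_energy_kev=60.0,
    )


@dataclass(frozen=True)
class Ellipse:
    """One ellipse of a phantom: center/axes in pixels, rotation in deg."""

    cx: float
    cy: float
    a: float
    b: float
    rotation_deg: float
    label: str


@dataclass
class PhantomSpec:
    """Ellipse-stack phantom description (later ellipses overwrite earlier)."""

    ellipses: list
    size: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ConfigurationError("size must be >= 1")
        c = (self.size - 1) / 2.0
        r_fov = self.size / 2.0
        for e in self.ellipses:
            reach = np.hypot(e.cx - c, e.cy - c) + max(e.a, e.b)
            if reach > r_fov:
                raise ConfigurationError(
                    f"ellipse {e} extends outside the inscribed circle"
                )


@dataclass
class SimulationOutput:
    """Ground truth and measurements of one simulated scan."""

    truth_image: ImageGrid
    true_metal: MetalImage
    sino_mono: Sinogram
    sino_poly: Sinogram
    geometry: Geometry
    manifest: dict = field(default_factory=dict)


def _ellipse_mask(e: Ellipse, size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    phi = np.deg2rad(e.rotation_deg)
    dx = xx - e.cx
    dy = yy - e.cy
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    # pixel-center membership, no anti-aliasing: counts are exactly testable
    return (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0


def make_phantom(
    spec: PhantomSpec,
    materials: dict[str, MaterialModel] | None = None,
    reference_energy_kev: float = 70.0,
    pixel_spacing: float = 0.1,
) -> tuple[ImageGrid, dict[str, np.ndarray], MetalImage]:
    """Rasterize *spec* into a truth image and per-label indicator maps.

    Returns the attenuation image at the reference energy, one binary
    indicator grid per material label, and the union of metal-labelled
    indicators as the true metal map.
    """
    if materials is None:
        materials = default_materials()
    for e in spec.ellipses:
        if e.label not in materials:
            raise ConfigurationError(f"unknown material label {e.label!r}")

    label_map = np.full((spec.size, spec.size), "", dtype=object)
    for e in spec.ellipses:
        label_map[_ellipse_mask(e, spec.size)] = e.label

    material_maps = {
        lab: (label_map == lab).astype(np.uint8) for lab in materials
    }
    truth = np.zeros((spec.size, spec.size), dtype=float)
    for lab, ind in material_maps.items():
        truth += float(materials[lab].mu_at(reference_energy_kev)) * ind
    metal_ind = np.zeros((spec.size, spec.size), dtype=np.uint8)
    for lab in METAL_LABELS:
        if lab in material_maps:
            metal_ind |= material_maps[lab]
    return (
        ImageGrid(truth, spacing=pixel_spacing),
        material_maps,
        MetalImage(metal_ind, threshold_used=float("nan")),
    )


def polychromatic_project(
    material_maps: dict[str, np.ndarray],
    materials: dict[str, MaterialModel],
    spectrum: SpectrumModel,
    geometry: Geometry,
    noise_photons: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Sinogram, Sinogram]:
    """Polychromatic and monochromatic sinograms of a material phantom.

    Per ray: path lengths ``L_m`` from the Radon transform of each
    material indicator, then

        p_mono = sum_m mu_m(E_ref) * L_m
        p_poly = -ln( sum_k w_k * exp(-sum_m mu_m(E_k) * L_m) )

    ``noise_photons``, if given, applies Poisson noise to the
    transmitted intensity at that incident photon count per ray
    (seeded via *rng*); default is noise-free.
    """
    labels = sorted(material_maps)
    paths = np.stack(
        [
            radon_forward(
                ImageGrid(
                    material_maps[lab].astype(float), geometry.pixel_spacing
                ),
                geometry,
            ).values
            for lab in labels
        ]
    )  # (n_materials, n_views, n_channels), cm
    paths = np.clip(paths, 0.0, None)  # interpolation undershoot

    energies = np.asarray(spectrum.energies_kev, float)
    weights = np.asarray(spectrum.weights, float)
    mu_ref = np.array(
        [materials[lab].mu_at(spectrum.reference_energy_kev) for lab in labels]
    )
    mu_tab = np.array(
        [materials[lab].mu_at(energies) for lab in labels]
    )  # (n_materials, n_energies)

    mono = np.einsum("m,mvc->vc", mu_ref, paths)
    # attenuation A[k] = sum_m mu_m(E_k) L_m per ray; logsumexp for stability
    atten = np.einsum("mk,mvc->kvc", mu_tab, paths)
    log_w = np.log(np.where(weights > 0, weights, 1.0))
    log_w[weights == 0] = -np.inf
    poly = -logsumexp(-atten + log_w[:, None, None], axis=0)

    if noise_photons is not None:
        if rng is None:
            rng = np.random.default_rng()
        trans = np.exp(-poly)
        counts = rng.poisson(noise_photons * trans)
        poly = -np.log(np.maximum(counts, 1) / noise_photons)

    return (
        Sinogram(poly, geometry),
        Sinogram(mono, geometry),
    )


def make_reference_scenario(
    seed: int = DEFAULT_SEED,
    size: int = 128,
    n_views: int = 90,
    n_metal: int | None = None,
    noise_photons: float | None = None,
) -> SimulationOutput:
    """Deterministic bag-like scene with metal inserts at desk scale.

    A soft-material bag (large random ellipse plus a few internal soft
    ellipses) with 1-3 small metal inserts, projected through the stock
    five-point spectrum.  ``n_metal=0`` gives the metal-free control.
    Identical seeds give bit-identical outputs.
    """
    if size < 64:
        raise ConfigurationError("size must be >= 64")
    rng = np.random.default_rng(seed)
    geometry = Geometry.for_image(size, n_views, pixel_spacing=0.1)
    c = (size - 1) / 2.0

    ellipses = [
        Ellipse(
            cx=c + rng.uniform(-0.02, 0.02) * size,
            cy=c + rng.uniform(-0.02, 0.02) * size,
            a=0.40 * size * rng.uniform(0.95, 1.05),
            b=0.33 * size * rng.uniform(0.95, 1.05),
            rotation_deg=rng.uniform(0, 180),
            label="soft",
        )
    ]
    for _ in range(rng.integers(2, 5)):
        ellipses.append(
            Ellipse(
                cx=c + rng.uniform(-0.18, 0.18) * size,
                cy=c + rng.uniform(-0.15, 0.15) * size,
                a=rng.uniform(0.06, 0.14) * size,
                b=rng.uniform(0.06, 0.14) * size,
                rotation_deg=rng.uniform(0, 180),
                label="soft",
            )
        )
    # 2-3 cm-scale metal objects: undershoot streaks develop *between*
    # metals, where the view-dependent depression is most inconsistent
    if n_metal is None:
        n_metal = int(rng.integers(2, 4))
    for _ in range(n_metal):
        ellipses.append(
            Ellipse(
                cx=c + rng.uniform(-0.15, 0.15) * size,
                cy=c + rng.uniform(-0.12, 0.12) * size,
                a=rng.uniform(0.030, 0.070) * size,
                b=rng.uniform(0.030, 0.070) * size,
                rotation_deg=rng.uniform(0, 180),
                label="metal",
            )
        )

    spec = PhantomSpec(ellipses=ellipses, size=size, seed=seed)
    materials = default_materials()
    spectrum = default_spectrum()
    truth, maps, true_metal = make_phantom(
        spec,
        materials,
        reference_energy_kev=spectrum.reference_energy_kev,
        pixel_spacing=geometry.pixel_spacing,
    )
    sino_poly, sino_mono = polychromatic_project(
        maps,
        materials,
        spectrum,
        geometry,
        noise_photons=noise_photons,
        rng=np.random.default_rng(seed + 1) if noise_photons else None,
    )
    manifest = {
        "seed": int(seed),
        "size": int(size),
        "n_views": int(n_views),
        "n_metal_inserts": int(n_metal),
        "pixel_spacing_cm": geometry.pixel_spacing,
        "spectrum_energies_kev": list(spectrum.energies_kev),
        "spectrum_weights": list(spectrum.weights),
        "reference_energy_kev": spectrum.reference_energy_kev,
        "noise_photons": noise_photons,
        "ellipses": [
            {
                "cx": e.cx,
                "cy": e.cy,
                "a": e.a,
                "b": e.b,
                "rotation_deg": e.rotation_deg,
                "label": e.label,
            }
            for e in ellipses
        ],
    }
    return SimulationOutput(
        truth_image=truth,
        true_metal=true_metal,
        sino_mono=sino_mono,
        sino_poly=sino_poly,
        geometry=geometry,
        manifest=manifest,
    )
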