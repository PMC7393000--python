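"""Phantom rasterization and polychromatic beam-hardening physics."""

import numpy as np
import pytest

from tvmar import (
    ConfigurationError,
    ImageGrid,
    Ellipse,
    Geometry,
    MaterialModel,
    PhantomSpec,
    SpectrumModel,
    ValidationError,
    fbp,
    make_phantom,
    make_reference_scenario,
    polychromatic_project,
    radon_forward,
    segment_metal,
)
from tvmar.simulate import default_materials, default_spectrum


def in_ellipse(x, y, e):
    phi = np.deg2rad(e.rotation_deg)
    u = (x - e.cx) * np.cos(phi) + (y - e.cy) * np.sin(phi)
    v = -(x - e.cx) * np.sin(phi) + (y - e.cy) * np.cos(phi)
    return (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0


class TestMakePhantom:
    def test_empty_spec_gives_zero_image(self):
        truth, maps, metal = make_phantom(PhantomSpec([], 32))
        assert np.all(truth.values == 0)
        assert metal.is_empty

    def test_single_soft_disc_is_two_valued(self):
        mats = default_materials()
        mu = float(mats["soft"].mu_at(70.0))
        spec = PhantomSpec([Ellipse(15.5, 15.5, 8, 8, 0, "soft")], 32)
        truth, _, metal = make_phantom(spec, mats, 70.0)
        assert set(np.unique(truth.values)) == {0.0, mu}
        assert metal.is_empty

    def test_overlap_counts_match_pixel_membership_oracle(self):
        # later ellipses overwrite earlier: metal wins where they overlap
        soft = Ellipse(30, 32, 18, 12, 25.0, "soft")
        met = Ellipse(36, 30, 6, 4, 70.0, "metal")
        spec = PhantomSpec([soft, met], 64)
        _, maps, metal = make_phantom(spec)
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        in_soft = in_ellipse(xx, yy, soft)
        in_met = in_ellipse(xx, yy, met)
        assert maps["metal"].sum() == in_met.sum()
        assert maps["soft"].sum() == (in_soft & ~in_met).sum()
        np.testing.assert_array_equal(metal.indicator, in_met.astype(np.uint8))

    def test_unknown_label_raises(self):
        spec = PhantomSpec([Ellipse(16, 16, 4, 4, 0, "kryptonite")], 32)
        with pytest.raises(ConfigurationError):
            make_phantom(spec)

    def test_ellipse_outside_circle_raises(self):
        with pytest.raises(ConfigurationError):
            PhantomSpec([Ellipse(2, 2, 8, 8, 0, "soft")], 32)


@pytest.fixture(scope="module")
def column_setup():
    """20 stacked pixels x 0.1 cm = exactly 2 cm along the 0-degree ray."""
    n = 64
    geom = Geometry.for_image(n, 60, pixel_spacing=0.1)
    m = np.zeros((n, n))
    m[22:42, n // 2] = 1.0
    return geom, {"mat": m}


class TestPolychromaticProject:
    def test_two_energy_closed_form(self, column_setup):
        geom, maps = column_setup
        mats = {"mat": MaterialModel("mat", (40.0, 80.0), (1.0, 0.5))}
        spec = SpectrumModel((40.0, 80.0), (0.5, 0.5), 60.0)
        poly, mono = polychromatic_project(maps, mats, spec, geom)
        # L = 2 cm, mu = (1.0, 0.5)/cm, w = (0.5, 0.5)
        expected = -np.log(0.5 * np.exp(-2.0) + 0.5 * np.exp(-1.0))
        assert poly.values[0, geom.n_channels // 2] == pytest.approx(
            expected, abs=1e-12
        )
        assert mono.values[0, geom.n_channels // 2] == pytest.approx(
            2.0 * 0.75, abs=1e-12
        )

    def test_single_energy_collapses_to_mono(self, column_setup):
        geom, maps = column_setup
        mats = default_materials()
        m = {"soft": maps["mat"]}
        spec = SpectrumModel((70.0,), (1.0,), 70.0)
        poly, mono = polychromatic_project(m, mats, spec, geom)
        np.testing.assert_allclose(poly.values, mono.values, atol=1e-12)

    def test_rays_missing_object_are_zero(self, column_setup):
        geom, maps = column_setup
        mats = {"mat": MaterialModel("mat", (40.0, 80.0), (1.0, 0.5))}
        spec = SpectrumModel((40.0, 80.0), (0.5, 0.5), 60.0)
        poly, mono = polychromatic_project(maps, mats, spec, geom)
        assert poly.values[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert mono.values[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_poly_concave_nondecreasing_in_path_length(self):
        # thicker and thicker columns -> p(L) rises with diminishing slope
        n = 64
        geom = Geometry.for_image(n, 4, pixel_spacing=0.1)
        mats = default_materials()
        spec = default_spectrum()
        ps = []
        for k in range(0, 36, 5):
            m = np.zeros((n, n))
            m[32 - k // 2 : 32 + (k + 1) // 2, n // 2] = 1.0
            poly, _ = polychromatic_project({"metal": m}, mats, spec, geom)
            ps.append(poly.values[0, n // 2])
        d = np.diff(ps)
        assert np.all(d >= -1e-12)  # nondecreasing
        assert np.all(np.diff(d) <= 1e-9)  # concave

    def test_logsumexp_bounds_per_ray(self, small_sim):
        mats = default_materials()
        spec = default_spectrum()
        mu_soft = mats["soft"].mu_at(np.asarray(spec.energies_kev))
        mu_met = mats["metal"].mu_at(np.asarray(spec.energies_kev))
        ells = [Ellipse(**e) for e in small_sim.manifest["ellipses"]]
        _, maps, _ = make_phantom(PhantomSpec(ells, 64), mats, 70.0, 0.1)
        geom = small_sim.geometry
        L_soft = radon_forward(
            ImageGrid(maps["soft"].astype(float), 0.1), geom
        ).values
        L_met = radon_forward(
            ImageGrid(maps["metal"].astype(float), 0.1), geom
        ).values
        L_soft, L_met = np.clip(L_soft, 0, None), np.clip(L_met, 0, None)
        atten = (
            mu_soft[:, None, None] * L_soft[None] + mu_met[:, None, None] * L_met[None]
        )
        p = small_sim.sino_poly.values
        assert np.all(p <= atten.max(axis=0) + 1e-9)
        assert np.all(p >= atten.min(axis=0) - 1e-9)

    def test_unnormalized_spectrum_raises(self):
        with pytest.raises(ValidationError):
            SpectrumModel((40.0, 80.0), (0.5, 0.6), 60.0)


class TestReferenceScenario:
    def test_same_seed_bit_identical(self):
        a = make_reference_scenario(seed=9, size=64, n_views=45)
        b = make_reference_scenario(seed=9, size=64, n_views=45)
        assert np.array_equal(a.sino_poly.values, b.sino_poly.values)
        assert np.array_equal(a.truth_image.values, b.truth_image.values)
        assert a.manifest == b.manifest

    def test_mono_sinogram_is_radon_of_truth(self, small_sim):
        proj = radon_forward(small_sim.truth_image, small_sim.geometry)
        np.testing.assert_allclose(
            small_sim.sino_mono.values, proj.values, atol=1e-9
        )

    def test_metal_rays_depressed(self, small_sim):
        mp = radon_forward(
            ImageGrid(
                small_sim.true_metal.indicator.astype(float), 0.1
            ),
            small_sim.geometry,
        ).values
        hit = mp > 1e-6 * mp.max()
        frac = np.mean(
            small_sim.sino_poly.values[hit] < small_sim.sino_mono.values[hit]
        )
        assert frac >= 0.95
        off = ~hit
        # metal-free rays carry only mild soft-material hardening
        np.testing.assert_allclose(
            small_sim.sino_poly.values[off], small_sim.sino_mono.values[off],
            atol=0.12,
        )

    def test_metal_free_variant_segments_empty(self):
        sim = make_reference_scenario(seed=5, size=64, n_views=60, n_metal=0)
        assert sim.true_metal.is_empty
        raw = fbp(sim.sino_poly, sim.geometry)
        assert segment_metal(raw).is_empty

    def test_monochromatic_collapse_reconstructs_truth(self, ref_sim):
        # end-to-end consistency: spectrum at the reference energy only
        from tvmar.simulate import default_materials

        mats = default_materials()
        eref = default_spectrum().reference_energy_kev
        ells = [Ellipse(**e) for e in ref_sim.manifest["ellipses"]]
        _, maps, _ = make_phantom(PhantomSpec(ells, 128), mats, eref, 0.1)
        mono_spec = SpectrumModel((eref,), (1.0,), eref)
        poly, _ = polychromatic_project(maps, mats, mono_spec, ref_sim.geometry)
        rec = fbp(poly, ref_sim.geometry)
        truth = ref_sim.truth_image.values
        circ = ref_sim.geometry.circle_mask()
        # away from material boundaries the reconstruction matches the
        # phantom; recorded tolerance 0.1 (edge ringing dominates the rest)
        from scipy.ndimage import binary_dilation

        edges = np.zeros_like(truth, bool)
        edges[:-1, :] |= truth[:-1, :] != truth[1:, :]
        edges[1:, :] |= truth[:-1, :] != truth[1:, :]
        edges[:, :-1] |= truth[:, :-1] != truth[:, 1:]
        edges[:, 1:] |= truth[:, :-1] != truth[:, 1:]
        sel = circ & ~binary_dilation(edges, iterations=3)
        rel = np.sqrt(np.mean((rec.values[sel] - truth[sel]) ** 2))
        rel /= np.sqrt(np.mean(truth[circ] ** 2))
        assert rel < 0.1
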