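"""Renderer contracts: BRDF physics, scene shading, tone mapping, display."""

import numpy as np
import pytest

from glossjnd.render import (DisplayModel, HDRImage, Light, SceneSpec,
                             ToneMapParams, WardMaterial, decode_srgb,
                             display_luminance, encode_srgb, luminance_709,
                             render_scene, tonemap_reinhard, ward_brdf)
from glossjnd.studies import (brdf_reciprocity_error, mc_directional_albedo,
                              quad_directional_albedo)

Z = np.array([0.0, 0.0, 1.0])


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


class TestWardBrdf:
    def test_diffuse_only_limit(self):
        """rho_s = 0 reduces to the Lambertian rho_d / pi for any geometry."""
        mat = WardMaterial(0.0, (0.2, 0.5, 0.1), 0.1)
        rng = np.random.default_rng(3)
        for _ in range(20):
            wi = _unit(np.abs(rng.normal(size=3)))
            wo = _unit(np.abs(rng.normal(size=3)))
            np.testing.assert_allclose(ward_brdf(wi, wo, Z, mat),
                                       np.array(mat.rho_d) / np.pi, rtol=1e-12)

    def test_reciprocity(self):
        """Helmholtz reciprocity over randomized valid geometry."""
        mat = WardMaterial(0.5, (0.1, 0.3, 0.1), 0.19)
        assert brdf_reciprocity_error(mat, n=1000, seed=0) < 1e-12

    def test_invalid_geometry_returns_zero(self):
        mat = WardMaterial(0.5, (0.1, 0.3, 0.1), 0.19)
        below = _unit([0.2, 0.1, -0.5])
        assert np.all(ward_brdf(below, Z, Z, mat) == 0)
        assert np.all(ward_brdf(Z, below, Z, mat) == 0)

    def test_nonnegative_and_finite(self):
        mat = WardMaterial(0.9, (0.05, 0.05, 0.05), 0.05)
        rng = np.random.default_rng(7)
        wi = rng.normal(size=(500, 3))
        wi /= np.linalg.norm(wi, axis=1, keepdims=True)
        wo = rng.normal(size=(500, 3))
        wo /= np.linalg.norm(wo, axis=1, keepdims=True)
        f = ward_brdf(wi, wo, np.broadcast_to(Z, wi.shape), mat)
        assert np.all(np.isfinite(f)) and np.all(f >= 0)

    def test_albedo_bounds_study_material(self, study_material):
        """Monte-Carlo white-sky albedo at normal incidence stays within
        [rho_d, 1] for the study's material."""
        albedo = mc_directional_albedo(study_material, n=100_000, seed=0)
        assert np.all(albedo <= 1.0)
        assert np.all(albedo >= np.array(study_material.rho_d))

    @pytest.mark.parametrize("alpha", [0.01, 0.05, 0.19, 0.5])
    def test_energy_conservation_extreme_material(self, alpha):
        """Quadrature albedo <= 1 even at rho_s = 1 - max(rho_d)."""
        mat = WardMaterial(0.7, (0.3, 0.3, 0.3), alpha)
        assert quad_directional_albedo(mat) <= 1.0 + 1e-6

    def test_material_validation(self):
        with pytest.raises(ValueError):
            WardMaterial(0.8, (0.3, 0.5, 0.3), 0.1)  # energy implausible
        with pytest.raises(ValueError):
            WardMaterial(0.1, (0.1, 0.1, 0.1), 0.0)  # alpha must be > 0


class TestRenderScene:
    def test_zero_lights_zero_object(self, study_material):
        scene = SceneSpec("sphere", (Light("ambient", (0.0, 0.0, 0.0)),),
                          (45.0, 0.0, 3.0), study_material, 48)
        img = render_scene(scene, "full")
        assert np.allclose(img.pixels[img.mask], 0)

    def test_component_additivity(self, point_light_sphere):
        scene, full = point_light_sphere
        diff = render_scene(scene, "diffuse_only")
        spec = render_scene(scene, "specular_only")
        np.testing.assert_allclose(full.pixels, diff.pixels + spec.pixels,
                                   rtol=1e-6, atol=1e-12)

    def test_lambertian_sphere_closed_form(self):
        """Brightest pixel of a matte sphere under a directional light sits
        where normal·light peaks; its value matches rho_d/pi * cos * E."""
        mat = WardMaterial(0.0, (0.2, 0.4, 0.2), 0.1)
        direction = _unit([0.3, -0.2, 0.93])
        E = (2.0, 2.0, 2.0)
        scene = SceneSpec("sphere", (Light("directional", E, direction=tuple(direction)),),
                          (45.0, 30.0, 3.0), mat, 128, background=(0, 0, 0))
        img = render_scene(scene, "full")
        lum = img.luminance
        peak = lum.max()
        # closed form at the surface point whose normal equals the light
        # direction (cos = 1), if that point faces the camera
        expected = luminance_709(np.array(mat.rho_d) / np.pi * np.array(E))
        view = np.array([np.cos(np.deg2rad(45)) * np.cos(np.deg2rad(30)),
                         np.cos(np.deg2rad(45)) * np.sin(np.deg2rad(30)),
                         np.sin(np.deg2rad(45))])
        assert direction @ view > 0  # the peak point is visible
        np.testing.assert_allclose(peak, expected, rtol=0.02)

    def test_sharper_lobe_brighter_highlight(self, study_material):
        """Decreasing alpha concentrates specular energy: max pixel rises."""
        lights = (Light("point", (40.0, 40.0, 40.0), position=(2.0, -1.0, 3.0)),)
        scene = SceneSpec("sphere", lights, (45.0, 30.0, 3.0), study_material, 96)
        peaks = [render_scene(scene.with_alpha(a), "specular_only").pixels.max()
                 for a in (0.01, 0.05, 0.19)]
        assert peaks[0] > peaks[1] > peaks[2]

    def test_unknown_shape_errors(self, study_material):
        scene = SceneSpec("sphere", (Light("ambient", (1, 1, 1)),),
                          (45.0, 0.0, 3.0), study_material, 32)
        object.__setattr__(scene, "shape_id", "torus")
        with pytest.raises(ValueError, match="torus"):
            render_scene(scene)

    @pytest.mark.parametrize("shape,params", [
        ("superellipsoid", {"exponent": 4.0}),
        ("bumpy_sphere", {"bump_amplitude": 0.08, "bump_frequency": 6.0}),
    ])
    def test_other_shapes_render(self, study_material, shape, params):
        scene = SceneSpec(shape, (Light("ambient", (0.5, 0.5, 0.5)),),
                          (30.0, 10.0, 3.0), study_material, 48,
                          shape_params=params)
        img = render_scene(scene)
        assert img.mask.sum() > 100
        assert np.all(np.isfinite(img.pixels))


class TestToneMapAndDisplay:
    def test_zero_image_maps_to_zero(self):
        img = HDRImage(np.zeros((8, 8, 3)))
        assert np.all(tonemap_reinhard(img) == 0)

    def test_uniform_closed_form(self):
        """Uniform luminance L: geometric mean = L, so Ld = key/(1+key)."""
        img = HDRImage(np.full((16, 16, 3), 2.5))
        params = ToneMapParams(key=0.18, burn=0.0)
        out = tonemap_reinhard(img, params)
        np.testing.assert_allclose(luminance_709(out), 0.18 / 1.18, rtol=1e-6)

    def test_monotone_in_luminance(self, rng):
        vals = np.sort(rng.uniform(0, 50, 64))
        img = HDRImage(np.repeat(vals, 3).reshape(8, 8, 3))
        out = luminance_709(tonemap_reinhard(img))
        assert np.all(np.diff(out.ravel()) >= -1e-12)

    def test_srgb_roundtrip_and_endpoints(self):
        grid = np.linspace(0, 1, 256)
        assert encode_srgb(np.array(0.0)) == 0
        assert encode_srgb(np.array(1.0)) == 255
        # lossless over representable codes; linear error bounded by half the
        # local quantization step (widest near white, ~2.3/255 per code)
        codes = np.arange(256, dtype=np.uint8)
        np.testing.assert_array_equal(encode_srgb(decode_srgb(codes)), codes)
        assert np.max(np.abs(decode_srgb(encode_srgb(grid)) - grid)) <= 1.2 / 255
        # encode is monotone
        assert np.all(np.diff(encode_srgb(grid).astype(int)) >= 0)
        # mid-grey lands far above the linear code (0.18*255 = 46): the
        # standard curve gives 0.4613*255 = 117.6 -> code 118
        assert encode_srgb(np.array(0.18)) >= 118

    def test_display_calibration_range(self):
        display = DisplayModel()
        assert display_luminance(np.array(1.0), display) == 100.0
        assert display_luminance(np.array(0.0), display) == 1.0
        ramp = np.linspace(0, 1, 32)
        assert np.all(np.diff(display_luminance(ramp, display)) >= 0)

    def test_composition_maps_into_display_range(self, point_light_sphere):
        _, img = point_light_sphere
        lum = display_luminance(decode_srgb(encode_srgb(tonemap_reinhard(img))))
        assert lum.min() >= 1.0 - 1e-9 and lum.max() <= 100.0 + 1e-9
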