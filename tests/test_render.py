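"""Phong renderer closed forms and invariances."""

import numpy as np
import pytest
from scipy import ndimage

from perikymata.render import (LightComponent, LightSource, ViewConfig,
                               default_ls1, default_ls2, multi_view_plate,
                               render_phong, rotate_surface)
from perikymata.surface_seg import SurfaceModel

from conftest import make_sphere_surface


def _flat_plate(n=20):
    yy, xx = np.mgrid[0:n, 0:n]
    pos = np.stack([np.zeros(n * n), yy.ravel().astype(float),
                    xx.ravel().astype(float)], axis=1)
    nrm = np.tile([1.0, 0.0, 0.0], (n * n, 1))
    return SurfaceModel(pos, nrm, "OES", 1.0, (1, n, n))


VIEW = ViewConfig(view=(-1, 0, 0), up=(0, 1, 0), pixel_size_um=1.0)


def _only(ambient=0.0, diffuse=0.0, specular=0.0, color=(1, 1, 1),
          direction=(-1, 0, 0), shininess=30.0):
    return LightSource(direction=direction,
                       ambient=LightComponent((1, 1, 1), ambient),
                       diffuse=LightComponent(color, diffuse),
                       specular=LightComponent(color, specular),
                       shininess=shininess)


class TestClosedForms:
    def test_ambient_only_uniform_and_normal_independent(self):
        plate = _flat_plate()
        img = render_phong(plate, [_only(ambient=100)], VIEW)
        covered = img.sum(axis=2) > 0
        vals = img[covered]
        assert np.allclose(vals, 100 / 255)
        # scrambling normals leaves the ambient image unchanged
        rng = np.random.default_rng(0)
        scrambled = SurfaceModel(plate.positions,
                                 rng.normal(size=plate.normals.shape),
                                 "OES", 1.0, plate.volume_shape)
        scrambled.normals /= np.linalg.norm(scrambled.normals, axis=1,
                                            keepdims=True)
        # keep elements facing the camera so they are not culled
        flip = scrambled.normals[:, 0] > 0
        scrambled.normals[flip] *= -1
        img2 = render_phong(scrambled, [_only(ambient=100)], VIEW)
        np.testing.assert_allclose(img2[img2.sum(axis=2) > 0], 100 / 255)

    def test_diffuse_head_on_plate(self):
        plate = _flat_plate()
        img = render_phong(plate, [_only(diffuse=200,
                                         color=(1, 0.5, 0.25))], VIEW)
        covered = img.sum(axis=2) > 0
        expected = np.array([1, 0.5, 0.25]) * 200 / 255
        np.testing.assert_allclose(
            img[covered], np.tile(expected, (covered.sum(), 1)))

    def test_specular_highlight_at_mirror_point(self):
        sphere = make_sphere_surface(radius=25.0, center=30.0,
                                     cap_only=True)
        img = render_phong(sphere, [_only(specular=255, shininess=60)],
                           VIEW)
        lum = img.sum(axis=2)
        peak = np.unravel_index(np.argmax(lum), lum.shape)
        center = (lum.shape[0] // 2, lum.shape[1] // 2)
        # light along the view axis: half vector = view axis, highlight at
        # the sphere point whose normal faces the camera (image centre)
        assert abs(peak[0] - center[0]) <= 1
        assert abs(peak[1] - center[1]) <= 1

    def test_output_monotone_in_intensity(self):
        sphere = make_sphere_surface(cap_only=True)
        lo = render_phong(sphere, [_only(ambient=10, diffuse=60)], VIEW)
        hi = render_phong(sphere, [_only(ambient=20, diffuse=120)], VIEW)
        assert np.all(hi >= lo - 1e-12)


class TestPresets:
    def test_ls2_intensities_follow_protocol(self):
        ls2 = default_ls2()
        assert ls2.ambient.intensity == 5
        assert ls2.ambient.color == (1.0, 1.0, 1.0)
        assert ls2.diffuse.intensity == 35
        assert ls2.diffuse.color == (1.0, 0.6, 0.2)      # orange
        assert ls2.specular.intensity == 200
        assert ls2.specular.color == (0.8, 0.9, 1.0)     # pale blue
        assert ls2.specular.intensity / ls2.diffuse.intensity \
            == pytest.approx(200 / 35)

    def test_ls1_white_head_on(self):
        ls1 = default_ls1((0, 1, 0))
        assert ls1.direction == (0.0, 1.0, 0.0)
        for comp in (ls1.ambient, ls1.diffuse, ls1.specular):
            assert comp.color == (1.0, 1.0, 1.0)


class TestMultiView:
    def test_45_degree_step_gives_8_views(self):
        sphere = make_sphere_surface()
        views = multi_view_plate(sphere, [default_ls1((-1, 0, 0))], VIEW,
                                 45.0)
        assert len(views) == 8

    def test_360_step_reproduces_direct_render(self):
        sphere = make_sphere_surface()
        views = multi_view_plate(sphere, [default_ls1((-1, 0, 0))], VIEW,
                                 360.0)
        assert len(views) == 1

    def test_step_not_dividing_360_rejected(self):
        sphere = make_sphere_surface()
        with pytest.raises(ValueError):
            multi_view_plate(sphere, [default_ls1((-1, 0, 0))], VIEW, 50.0)

    def test_axisymmetric_views_pairwise_identical(self):
        sphere = make_sphere_surface()  # rotationally symmetric about z
        views = multi_view_plate(sphere, [default_ls1((-1, 0, 0)),
                                          default_ls2((-1, 0, 0))],
                                 VIEW, 90.0)
        ref = views[0]
        for v in views[1:]:
            rms = np.sqrt(((v - ref) ** 2).mean())
            assert rms < 0.02 * max(ref.mean(), 1e-6) / max(ref.mean(),
                                                            1e-6) + 0.02


class TestEquivariance:
    def test_rotating_model_and_lights_preserves_image(self):
        # bumpy sphere cap, generic light; rotate both by 90 deg about the
        # view axis and un-rotate the image: RMS below 2 percent
        sphere = make_sphere_surface(radius=25.0, center=30.0,
                                     cap_only=True)
        th = np.arctan2(sphere.normals[:, 1], sphere.normals[:, 2])
        bump = 1 + 0.1 * np.sin(3 * th) * (1 - sphere.normals[:, 0] ** 2)
        pos = (sphere.positions - 30.0) * bump[:, None] + 30.0
        bumpy = SurfaceModel(pos, sphere.normals, "OES", 1.0,
                             sphere.volume_shape)
        view = ViewConfig(view=(-1, 0, 0), up=(0, 1, 0), pixel_size_um=1.0,
                          center_um=np.array([30.0, 30.0, 30.0]),
                          half_extent_um=30.0)
        light = _only(ambient=20, diffuse=150, specular=100,
                      direction=(-0.5, 0.7, 0.3))
        img1 = render_phong(bumpy, [light], view)

        rot = rotate_surface(bumpy, 90.0, axis_point_px=(30, 30, 30),
                             axis=(1, 0, 0))
        d = np.asarray(light.direction)
        light_rot = LightSource(direction=(d[0], -d[2], d[1]),
                                ambient=light.ambient,
                                diffuse=light.diffuse,
                                specular=light.specular,
                                shininess=light.shininess)
        img2 = np.rot90(render_phong(rot, [light_rot], view), k=-1,
                        axes=(0, 1))
        a = ndimage.gaussian_filter(img1, (1, 1, 0))
        b = ndimage.gaussian_filter(img2, (1, 1, 0))
        m = (a.sum(axis=2) > 0.01) & (b.sum(axis=2) > 0.01)
        rms = np.sqrt(((a - b)[m] ** 2).mean())
        assert rms < 0.02


class TestModesAndErrors:
    def test_density_mode_flat_shading(self):
        plate = _flat_plate()
        plate.density_attr = plate.positions[:, 2] / 19.0  # gradient in x
        view = ViewConfig(view=(-1, 0, 0), up=(0, 1, 0), pixel_size_um=1.0,
                          mode="density")
        img = render_phong(plate, [_only(ambient=10)], view)
        lum = img.sum(axis=2)
        row = lum[lum.sum(axis=1) > 0][0]
        inside = row[row > 0]
        # flat shading follows the attribute: monotone across the image,
        # spanning the 0.25..1.0 albedo range regardless of the lights
        assert np.all(np.diff(inside) > 0) or np.all(np.diff(inside) < 0)
        assert inside.max() / inside.min() == pytest.approx(4.0, rel=0.1)

    def test_normalize_gradient_ignores_attribute(self):
        plate = _flat_plate()
        img_plain = render_phong(plate, [_only(diffuse=100)], VIEW)
        plate.density_attr = np.linspace(0, 1, len(plate))
        view_ng = ViewConfig(view=(-1, 0, 0), up=(0, 1, 0),
                             pixel_size_um=1.0, mode="normalize_gradient")
        img_ng = render_phong(plate, [_only(diffuse=100)], view_ng)
        np.testing.assert_allclose(img_ng, img_plain)

    def test_empty_surface_rejected(self):
        empty = SurfaceModel(np.empty((0, 3)), np.empty((0, 3)), "OES",
                             1.0, (1, 1, 1))
        with pytest.raises(ValueError):
            render_phong(empty, [_only(ambient=10)], VIEW)

    def test_light_count_bounds(self):
        plate = _flat_plate()
        with pytest.raises(ValueError):
            render_phong(plate, [], VIEW)
        with pytest.raises(ValueError):
            render_phong(plate, [_only(ambient=1)] * 5, VIEW)
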