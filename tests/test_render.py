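"""First-hit ray casting, fusion blending, clip planes, 2D fusion."""
import numpy as np
import pytest

from bonefuse import (BinaryMask, Camera, ClipPlane, RenderSettings,
                      TransferFunction, Volume, first_hit, fuse2d_slices,
                      make_grid, render_cross_section, render_ct,
                      render_fusion3d)

BG = np.array([0.0, 0.0, 0.0])


def slab_scene(n=24, spacing=2.0, lo=8, hi=16, hu=800.0):
    """Axis-aligned solid slab lo <= x-index < hi spanning y/z."""
    ct = make_grid((n, n, n), spacing=spacing)
    ct.values[:] = -1000.0
    ct.values[lo:hi, :, :] = hu
    bone_vals = np.zeros((n, n, n), dtype=bool)
    bone_vals[lo:hi, :, :] = True
    return ct, BinaryMask(values=bone_vals, affine=ct.affine)


def nonbackground(img):
    return np.any(img > 1e-9, axis=2)


def hollow_bone_scene(n=32, spacing=2.0, r_outer=24.0, r_inner=16.0):
    """Spherical cortical shell (800 HU) around marrow (100 HU)."""
    ct = make_grid((n, n, n), spacing=spacing)
    c = (n - 1) * spacing / 2.0
    x, y, z = np.ogrid[0:n, 0:n, 0:n]
    d2 = ((x * spacing - c) ** 2 + (y * spacing - c) ** 2
          + (z * spacing - c) ** 2)
    vals = np.full((n, n, n), -1000.0)
    outer = d2 <= r_outer ** 2
    inner = d2 <= r_inner ** 2
    vals[outer] = 800.0
    vals[inner] = 100.0
    ct.values[:] = vals
    return ct, BinaryMask(values=outer, affine=ct.affine)


class TestFirstHit:
    def test_ray_missing_volume_returns_none(self):
        _, bone = slab_scene()
        hit, _ = first_hit(np.array([-100.0, -100.0, -100.0]),
                           np.array([0.0, 0.0, 1.0]), bone)
        assert hit is False or hit == False  # noqa: E712

    def test_axis_aligned_slab_entry_face(self):
        ct, bone = slab_scene(spacing=2.0, lo=8, hi=16)
        settings = RenderSettings(step=1.0)
        origin = np.array([-50.0, 24.0, 24.0])
        hit, point = first_hit(origin, np.array([1.0, 0.0, 0.0]), bone,
                               settings=settings, ct_for_step=ct)
        assert hit
        # entry face of voxel cell 8 lies at x = (8 - 0.5) * 2 = 15 mm
        assert abs(point[0] - 15.0) <= 0.5 + 1e-9  # within step/2

    def test_clip_removing_everything_gives_no_hits(self):
        ct, bone = slab_scene()
        clip = ClipPlane(normal=(0.0, 0.0, -1.0), offset=-1000.0)  # keeps z <= -1000
        cam = Camera.facing(ct, width=8, height=8)
        origins = cam.ray_origins()
        hits, _ = first_hit(origins, cam.view, bone, clip=clip, ct_for_step=ct)
        assert not hits.any()


class TestRenderCT:
    def test_empty_mask_renders_background(self):
        ct, _ = slab_scene()
        bone = BinaryMask(values=np.zeros(ct.shape, dtype=bool), affine=ct.affine)
        cam = Camera.facing(ct, width=16, height=16)
        img = render_ct(ct, bone, cam)
        assert np.allclose(img, BG)

    def test_single_voxel_footprint(self):
        n, spacing = 24, 2.0
        ct = make_grid((n, n, n), spacing=spacing)
        ct.values[:] = -1000.0
        ct.values[12, 12, 12] = 800.0
        bone_vals = np.zeros((n, n, n), dtype=bool)
        bone_vals[12, 12, 12] = True
        bone = BinaryMask(values=bone_vals, affine=ct.affine)
        cam = Camera(view=(1.0, 0.0, 0.0), up=(0.0, 0.0, 1.0), width=48, height=48,
                     pixel_spacing=1.0, center=np.array([24.0, 24.0, 24.0]))
        img = render_ct(ct, bone, cam)
        # voxel cell is 2x2 mm across the view; pixels 1 mm -> ~4 non-bg pixels
        count = nonbackground(img).sum()
        assert count == pytest.approx(4, abs=2)

    def test_zero_opacity_compositing_is_background(self):
        ct, bone = slab_scene()
        tf = TransferFunction(ct_points=[(-1000.0, (1, 1, 1), 0.0),
                                         (3000.0, (1, 1, 1), 0.0)])
        cam = Camera.facing(ct, width=12, height=12)
        img = render_ct(ct, bone, cam, tf=tf,
                        settings=RenderSettings(surface_mode="compositing"))
        assert np.allclose(img, BG)

    def test_occlusion_independence(self):
        ct, bone = slab_scene(lo=8, hi=16)
        cam = Camera(view=(1.0, 0.0, 0.0), up=(0.0, 0.0, 1.0), width=16, height=16,
                     pixel_spacing=3.0, center=np.array([24.0, 24.0, 24.0]))
        img_before = render_ct(ct, bone, cam)
        deep = ct.copy_with(ct.values)
        deep.values[14, :, :] = 3000.0  # behind the x=8 entry surface
        img_after = render_ct(deep, bone, cam)
        assert np.allclose(img_before, img_after)

    def test_fully_opaque_compositing_matches_opaque_surface(self):
        # a uniform-HU slab with opacity 1 at its HU: the first composited
        # sample saturates and must equal the first-hit surface shading
        ct, bone = slab_scene(hu=1000.0)
        tf = TransferFunction()
        cam = Camera.facing(ct, view=(1.0, 0.0, 0.0), up=(0.0, 0.0, 1.0),
                            width=10, height=10)
        opaque = render_ct(ct, bone, cam, tf=tf,
                           settings=RenderSettings(surface_mode="opaque"))
        comp = render_ct(ct, bone, cam, tf=tf,
                         settings=RenderSettings(surface_mode="compositing"))
        assert np.allclose(opaque, comp, atol=1e-6)


class TestFusion3D:
    @pytest.fixture
    def scene(self):
        ct, bone = slab_scene()
        spect = make_grid(ct.shape, spacing=2.0, modality="spect")
        spect.values[:] = 0.0
        tf = TransferFunction(spect_window=(0.0, 100.0))
        cam = Camera.facing(ct, view=(1.0, 0.0, 0.0), up=(0.0, 0.0, 1.0),
                            width=20, height=20)
        return ct, bone, spect, tf, cam

    def test_beta_zero_identical_to_ct_render(self, scene):
        ct, bone, spect, tf, cam = scene
        spect.values[:] = 50.0
        s = RenderSettings(beta=0.0)
        assert np.array_equal(render_fusion3d(ct, bone, spect, cam, tf=tf, settings=s),
                              render_ct(ct, bone, cam, tf=tf, settings=s))

    def test_zero_uptake_identical_to_ct_render_any_beta(self, scene):
        ct, bone, spect, tf, cam = scene
        for beta in (0.25, 1.0):
            s = RenderSettings(beta=beta)
            assert np.array_equal(
                render_fusion3d(ct, bone, spect, cam, tf=tf, settings=s),
                render_ct(ct, bone, cam, tf=tf, settings=s))

    def test_window_max_uptake_beta_one_gives_pure_lut_color(self):
        # single-voxel bone at the SPECT window maximum: blend weight 1
        n = 16
        ct = make_grid((n, n, n), spacing=2.0)
        ct.values[:] = -1000.0
        ct.values[8, 8, 8] = 800.0
        bone_vals = np.zeros((n, n, n), dtype=bool)
        bone_vals[8, 8, 8] = True
        bone = BinaryMask(values=bone_vals, affine=ct.affine)
        spect = make_grid(ct.shape, spacing=2.0, modality="spect")
        spect.values[:] = 100.0
        tf = TransferFunction(spect_window=(0.0, 100.0))
        cam = Camera(view=(1.0, 0.0, 0.0), up=(0.0, 0.0, 1.0), width=3, height=3,
                     pixel_spacing=0.5, center=np.array([16.0, 16.0, 16.0]))
        img = render_fusion3d(ct, bone, spect, cam, tf=tf,
                              settings=RenderSettings(beta=1.0))
        center_px = img[1, 1]
        assert np.allclose(center_px, tf.spect_color(1.0), atol=1e-9)

    def test_no_spect_color_on_background_pixels(self, segmented_phantom):
        ct, spect_clean, bone, _ = segmented_phantom
        tf = TransferFunction().with_spect_window_from(spect_clean, bone)
        cam = Camera.facing(ct, width=64, height=64)
        fused = render_fusion3d(ct, bone, spect_clean, cam, tf=tf)
        ct_only = render_ct(ct, bone, cam, tf=tf)
        bg = ~nonbackground(ct_only)
        assert np.allclose(fused[bg], BG)

    def test_blend_is_convex_combination(self, segmented_phantom):
        ct, spect_clean, bone, _ = segmented_phantom
        tf = TransferFunction().with_spect_window_from(spect_clean, bone)
        cam = Camera.facing(ct, width=48, height=48)
        s = RenderSettings(beta=0.7)
        fused = render_fusion3d(ct, bone, spect_clean, cam, tf=tf, settings=s)
        ct_img = render_ct(ct, bone, cam, tf=tf, settings=s)
        hit = nonbackground(ct_img)
        low = np.minimum(ct_img[hit], 0.0)
        high = np.maximum(ct_img[hit], 1.0)
        assert np.all(fused[hit] >= low - 1e-9)
        assert np.all(fused[hit] <= high + 1e-9)

    def test_grid_mismatch_raises(self, scene):
        from bonefuse import GeometryError
        ct, bone, spect, tf, cam = scene
        coarse = make_grid((8, 8, 8), spacing=6.0, modality="spect")
        with pytest.raises(GeometryError):
            render_fusion3d(ct, bone, coarse, cam, tf=tf)


class TestClipPlane:
    def test_clip_outside_volume_is_identity(self, segmented_phantom):
        ct, spect_clean, bone, _ = segmented_phantom
        tf = TransferFunction().with_spect_window_from(spect_clean, bone)
        cam = Camera.facing(ct, width=40, height=40)
        clip = ClipPlane(normal=(0.0, 1.0, 0.0), offset=1e6)
        assert np.array_equal(
            render_fusion3d(ct, bone, spect_clean, cam, tf=tf, clip=clip),
            render_fusion3d(ct, bone, spect_clean, cam, tf=tf))

    def test_clip_monotonicity(self, segmented_phantom):
        # enlarging the removed half-space never creates non-background pixels
        ct, spect_clean, bone, _ = segmented_phantom
        tf = TransferFunction().with_spect_window_from(spect_clean, bone)
        cam = Camera.facing(ct, width=40, height=40)
        fov_y = ct.shape[1] * ct.spacing[1]
        prev = None
        for frac in (1.0, 0.6, 0.45, 0.0):
            clip = ClipPlane(normal=(0.0, 1.0, 0.0), offset=frac * fov_y)
            img = render_fusion3d(ct, bone, spect_clean, cam, tf=tf, clip=clip)
            nb = nonbackground(img)
            if prev is not None:
                assert not np.any(nb & ~prev)
            prev = nb

    def test_cross_section_shows_marrow_inside_cortex(self):
        # bisect a hollow bone: the cut face exposes a marrow-colored core
        # surrounded by cortex-colored pixels
        ct, bone = hollow_bone_scene()
        spect = make_grid(ct.shape, spacing=2.0, modality="spect")
        tf = TransferFunction(spect_window=(0.0, 1.0))
        c = ct.shape[1] * ct.spacing[1] / 2.0
        clip = ClipPlane(normal=(0.0, 1.0, 0.0), offset=c)
        cam = Camera.facing(ct, view=(0.0, -1.0, 0.0), up=(0.0, 0.0, 1.0),
                            width=48, height=48)
        img = render_cross_section(ct, bone, spect, clip, cam, tf=tf)
        h = img.shape[0] // 2
        center_px = img[h, img.shape[1] // 2]
        marrow_col = tf.ct_color(100.0)
        cortex_col = tf.ct_color(800.0)
        # center of the cut face is marrow; offset toward the rim is cortex
        assert np.linalg.norm(center_px / max(center_px.max(), 1e-9)
                              - marrow_col / max(marrow_col.max(), 1e-9)) < 0.35
        row = img[h]
        nb = nonbackground(img)[h]
        edge_idx = np.flatnonzero(nb)[1]
        edge_px = row[edge_idx]
        assert edge_px.sum() > center_px.sum()  # cortex brighter than marrow
        assert np.linalg.norm(edge_px - center_px) > 0.1

    def test_plane_removing_everything_is_background(self):
        ct, bone = slab_scene()
        spect = make_grid(ct.shape, spacing=2.0, modality="spect")
        clip = ClipPlane(normal=(0.0, -1.0, 0.0), offset=-1e6)
        cam = Camera.facing(ct, view=(0.0, 1.0, 0.0), up=(0.0, 0.0, 1.0),
                            width=16, height=16)
        img = render_cross_section(ct, bone, spect, clip, cam,
                                   tf=TransferFunction(spect_window=(0, 1)))
        assert np.allclose(img, BG)


class TestFuse2D:
    @pytest.fixture
    def pair(self):
        ct = make_grid((8, 8, 8), spacing=2.0)
        ct.values[:] = 650.0  # halfway through the default (-200, 1500) window
        spect = make_grid((8, 8, 8), spacing=2.0, modality="spect")
        spect.values[:] = 1.0
        return ct, spect

    def test_alpha_zero_is_pure_ct(self, pair):
        ct, spect = pair
        tf = TransferFunction(spect_window=(0.0, 1.0))
        stack = fuse2d_slices(ct, spect, axis="axial", alpha=0.0, tf=tf)
        assert np.allclose(stack, 0.5)

    def test_alpha_one_uniform_max_is_lut_top(self, pair):
        ct, spect = pair
        tf = TransferFunction(spect_window=(0.0, 1.0))
        stack = fuse2d_slices(ct, spect, axis="coronal", alpha=1.0, tf=tf)
        assert np.allclose(stack, tf.spect_color(1.0))

    def test_alpha_half_is_exact_average(self, pair):
        ct, spect = pair
        tf = TransferFunction(spect_window=(0.0, 1.0))
        stack = fuse2d_slices(ct, spect, axis="sagittal", alpha=0.5, tf=tf)
        expected = 0.5 * np.array([0.5, 0.5, 0.5]) + 0.5 * tf.spect_color(1.0)
        assert np.allclose(stack[0, 0, 0], expected)

    def test_slice_count_matches_axis(self, pair):
        ct, spect = pair
        stack = fuse2d_slices(ct, spect, axis="axial", alpha=0.5)
        assert stack.shape == (8, 8, 8, 3)
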