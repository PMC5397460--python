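"""Fusion display: ray-cast CT bone rendering with SPECT surface projection.

The display method renders the segmented bone from CT by orthographic ray
casting (opaque first-hit surface by default, optional front-to-back
compositing), then colors each surface point by the SPECT value interpolated
at the corresponding world location and blends the metabolic color with the
shaded CT color.  Because the bone surface is opaque, metabolic data appear
only on the visible bone — blurred SPECT activity outside the skeleton is
never displayed.  Clip-plane editing removes a half-space so that rays strike
the cut face, revealing internal structure and metabolism in cross-section.
Conventional 2D fused slices are provided for comparison.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, GeometryError, Volume


@dataclass
class Camera:
    """Orthographic camera: parallel rays along ``view`` through an image plane.

    The image plane passes through ``center`` (world mm), spanned by
    ``up`` (image +y, row 0 at top) and right = view x up (image +x), with
    square pixels of ``pixel_spacing`` mm.
    """

    view: np.ndarray
    up: np.ndarray
    width: int = 128
    height: int = 128
    pixel_spacing: float = 2.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.view = np.asarray(self.view, dtype=np.float64)
        self.up = np.asarray(self.up, dtype=np.float64)
        self.center = np.asarray(self.center, dtype=np.float64)
        nv, nu = np.linalg.norm(self.view), np.linalg.norm(self.up)
        if nv < 1e-12 or nu < 1e-12:
            raise ValueError("view and up must be nonzero")
        self.view = self.view / nv
        self.up = self.up / nu
        if abs(np.dot(self.view, self.up)) > 1e-8:
            raise ValueError("view and up must be orthogonal")

    @property
    def right(self) -> np.ndarray:
        return np.cross(self.view, self.up)

    def ray_origins(self) -> np.ndarray:
        """Per-pixel ray origins on the image plane, shape (H*W, 3), row-major."""
        ix = np.arange(self.width) - (self.width - 1) / 2.0
        iy = (self.height - 1) / 2.0 - np.arange(self.height)
        u, v = np.meshgrid(ix * self.pixel_spacing, iy * self.pixel_spacing)
        origins = (self.center[None, :]
                   + u.reshape(-1, 1) * self.right[None, :]
                   + v.reshape(-1, 1) * self.up[None, :])
        return origins

    @classmethod
    def facing(cls, vol: Volume, view=(0.0, 1.0, 0.0), up=(0.0, 0.0, 1.0),
               width: int = 128, height: int = 128,
               pixel_spacing: float | None = None) -> "Camera":
        """Camera centered on the volume's world centroid looking along ``view``."""
        lo, hi = vol.world_bounds()
        if pixel_spacing is None:
            pixel_spacing = float(max(hi - lo) / max(width, height))
        return cls(view=np.asarray(view, float), up=np.asarray(up, float),
                   width=width, height=height, pixel_spacing=pixel_spacing,
                   center=(lo + hi) / 2.0)


@dataclass
class ClipPlane:
    """Half-space removal: points with n . x > d (mm) are cut away."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=np.float64)
        n = np.linalg.norm(self.normal)
        if n < 1e-12:
            raise ValueError("clip normal must be nonzero")
        self.normal = self.normal / n
        self.offset = float(self.offset)

    def keeps(self, points: np.ndarray) -> np.ndarray:
        return points @ self.normal <= self.offset


def _interp_breakpoints(x, bp_x, bp_y) -> np.ndarray:
    """Piecewise-linear interpolation of (possibly vector-valued) breakpoints."""
    x = np.asarray(x, dtype=np.float64)
    bp_y = np.asarray(bp_y, dtype=np.float64)
    if bp_y.ndim == 1:
        return np.interp(x, bp_x, bp_y)
    return np.stack([np.interp(x, bp_x, bp_y[:, c]) for c in range(bp_y.shape[1])],
                    axis=-1)


@dataclass
class TransferFunction:
    """Color/opacity maps for CT and a color LUT for normalized SPECT.

    ``ct_points`` maps HU to (r, g, b, opacity); ``spect_points`` maps the
    window-normalized SPECT value in [0, 1] to (r, g, b) (a hot-metal-style
    scale by default).  ``spect_window`` holds the (lower, upper) display
    window in counts; ``ct_window`` is the grayscale window for 2D slices.
    """

    ct_points: list = field(default_factory=lambda: [
        (-1000.0, (0.00, 0.00, 0.00), 0.0),
        (100.0,   (0.25, 0.20, 0.15), 0.0),
        (300.0,   (0.85, 0.80, 0.70), 0.6),
        (1000.0,  (1.00, 0.98, 0.95), 1.0),
        (3000.0,  (1.00, 1.00, 1.00), 1.0),
    ])
    spect_points: list = field(default_factory=lambda: [
        (0.00, (0.0, 0.0, 0.0)),
        (0.25, (0.5, 0.0, 0.0)),
        (0.50, (1.0, 0.25, 0.0)),
        (0.75, (1.0, 0.8, 0.0)),
        (1.00, (1.0, 1.0, 1.0)),
    ])
    spect_window: tuple = (0.0, 1.0)
    ct_window: tuple = (-200.0, 1500.0)

    def __post_init__(self) -> None:
        hu = [p[0] for p in self.ct_points]
        sv = [p[0] for p in self.spect_points]
        if np.any(np.diff(hu) <= 0) or np.any(np.diff(sv) <= 0):
            raise ValueError("transfer-function breakpoints must be strictly increasing")
        ops = [p[2] for p in self.ct_points]
        if min(ops) < 0 or max(ops) > 1:
            raise ValueError("opacity must lie in [0, 1]")
        if self.spect_window[1] <= self.spect_window[0]:
            raise ValueError("spect_window upper bound must exceed lower bound")

    def ct_color(self, hu) -> np.ndarray:
        xs = [p[0] for p in self.ct_points]
        cols = [p[1] for p in self.ct_points]
        return _interp_breakpoints(hu, xs, cols)

    def ct_opacity(self, hu) -> np.ndarray:
        xs = [p[0] for p in self.ct_points]
        ops = [p[2] for p in self.ct_points]
        return _interp_breakpoints(hu, xs, ops)

    def spect_color(self, s_norm) -> np.ndarray:
        xs = [p[0] for p in self.spect_points]
        cols = [p[1] for p in self.spect_points]
        return _interp_breakpoints(np.clip(s_norm, 0.0, 1.0), xs, cols)

    def normalize_spect(self, counts) -> np.ndarray:
        lo, hi = self.spect_window
        return np.clip((np.asarray(counts, float) - lo) / (hi - lo), 0.0, 1.0)

    def with_spect_window_from(self, spect: Volume, bone: BinaryMask,
                               percentile: float = 99.5) -> "TransferFunction":
        """Set the SPECT window to [0, in-mask upper percentile]."""
        inside = spect.values[bone.values]
        hi = float(np.percentile(inside, percentile)) if inside.size else float(spect.values.max())
        if hi <= 0:
            hi = 1.0
        return TransferFunction(ct_points=self.ct_points, spect_points=self.spect_points,
                                spect_window=(0.0, hi), ct_window=self.ct_window)


@dataclass
class RenderSettings:
    """Rendering knobs: blend weight, surface mode, step, shading, background.

    beta is the SPECT blend weight in [0, 1]; with ``uptake_modulated`` the
    effective weight is beta * w(s) where w is the normalized uptake, so cold
    bone renders as plain CT.  ``step`` defaults to half the minimum CT voxel
    spacing.  Shading is a headlight Lambertian with the given ambient and
    diffuse coefficients.
    """

    beta: float = 0.5
    surface_mode: str = "opaque"  # opaque | compositing
    step: float | None = None
    ambient: float = 0.3
    diffuse: float = 0.7
    background: tuple = (0.0, 0.0, 0.0)
    uptake_modulated: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.step is not None and self.step <= 0:
            raise ValueError("step must be positive")
        if self.surface_mode not in ("opaque", "compositing"):
            raise ValueError(f"unknown surface mode {self.surface_mode!r}")

    def step_for(self, vol: Volume) -> float:
        return self.step if self.step is not None else float(vol.spacing.min()) / 2.0


def _trilinear(vol_values: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Trilinear sample at continuous indices, 0 outside."""
    return ndimage.map_coordinates(vol_values, idx.T, order=1, mode="constant",
                                   cval=0.0, prefilter=False)


class _RayMarcher:
    """Shared geometry for marching a bundle of parallel rays through a grid."""

    def __init__(self, bone: BinaryMask, direction: np.ndarray, step: float,
                 clip: ClipPlane | None):
        self.mask = bone.values
        self.affine = bone.affine
        self.inv = np.linalg.inv(bone.affine)
        self.direction = np.asarray(direction, dtype=np.float64)
        self.step = float(step)
        self.clip = clip
        self.shape = np.array(bone.shape)

    def to_index(self, points: np.ndarray) -> np.ndarray:
        return points @ self.inv[:3, :3].T + self.inv[:3, 3]

    def inside(self, points: np.ndarray) -> np.ndarray:
        """Sample occupancy at world points: nearest-voxel mask and not clipped."""
        idx = np.round(self.to_index(points)).astype(np.int64)
        ok = np.all((idx >= 0) & (idx < self.shape), axis=1)
        res = np.zeros(len(points), dtype=bool)
        if ok.any():
            i = idx[ok]
            res[ok] = self.mask[i[:, 0], i[:, 1], i[:, 2]]
        if self.clip is not None:
            res &= self.clip.keeps(points)
        return res

    def t_range(self, origins: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Entry/exit ray parameters against the grid bounding box."""
        o_idx = self.to_index(origins)
        d_idx = self.inv[:3, :3] @ self.direction
        lo, hi = -0.5, self.shape - 0.5
        t_near = np.full(len(origins), -np.inf)
        t_far = np.full(len(origins), np.inf)
        for a in range(3):
            d = d_idx[a]
            if abs(d) < 1e-12:
                out = (o_idx[:, a] < lo) | (o_idx[:, a] > hi[a])
                t_near[out], t_far[out] = np.inf, -np.inf
            else:
                ta = (lo - o_idx[:, a]) / d
                tb = (hi[a] - o_idx[:, a]) / d
                t_near = np.maximum(t_near, np.minimum(ta, tb))
                t_far = np.minimum(t_far, np.maximum(ta, tb))
        return t_near, t_far


def first_hit(origins, direction, bone: BinaryMask,
              clip: ClipPlane | None = None,
              settings: RenderSettings | None = None,
              ct_for_step: Volume | None = None):
    """March rays through the bone mask; return the first surface samples.

    Rays ``x = origin + t * direction`` are sampled every ``settings.step`` mm
    from the bounding-box entry point; the first sample inside the (clipped)
    mask is refined by one bisection step between the bracketing samples.

    Returns ``(hit, points)`` where ``hit`` is a boolean array (one entry per
    ray; False means the ray exits without a hit) and ``points`` the world-mm
    hit locations (undefined where ``hit`` is False).  A single (3,)-shaped
    origin yields scalar/1-point results.
    """
    settings = settings or RenderSettings()
    single = np.asarray(origins).ndim == 1
    origins = np.atleast_2d(np.asarray(origins, dtype=np.float64))
    direction = np.asarray(direction, dtype=np.float64)
    direction = direction / np.linalg.norm(direction)
    ref = ct_for_step if ct_for_step is not None else Volume(
        values=np.zeros((2, 2, 2)), affine=bone.affine)
    step = settings.step_for(ref)

    marcher = _RayMarcher(bone, direction, step, clip)
    t_near, t_far = marcher.t_range(origins)
    n = len(origins)
    hit = np.zeros(n, dtype=bool)
    t_hit = np.zeros(n)
    active = t_near <= t_far
    t = np.where(active, t_near, 0.0)
    max_iter = int(np.ceil((np.max(t_far[active] - t_near[active]) if active.any() else 0.0)
                           / step)) + 2
    for _ in range(max_iter):
        if not active.any():
            break
        pts = origins[active] + t[active, None] * direction[None, :]
        ins = marcher.inside(pts)
        idx_active = np.flatnonzero(active)
        newly = idx_active[ins]
        hit[newly] = True
        t_hit[newly] = t[newly]
        active[newly] = False
        t[active] += step
        active &= t <= t_far + 1e-9

    # one bisection refinement between last-outside and first-inside samples
    if hit.any():
        h = np.flatnonzero(hit)
        t_lo = t_hit[h] - step
        t_hi = t_hit[h].copy()
        t_mid = (t_lo + t_hi) / 2.0
        pts_mid = origins[h] + t_mid[:, None] * direction[None, :]
        ins_mid = marcher.inside(pts_mid)
        t_hi[ins_mid] = t_mid[ins_mid]
        t_lo[~ins_mid] = t_mid[~ins_mid]
        t_hit[h] = (t_lo + t_hi) / 2.0

    points = origins + t_hit[:, None] * direction[None, :]
    if single:
        return bool(hit[0]), points[0]
    return hit, points


def _world_gradient(ct: Volume) -> np.ndarray:
    """Central-difference HU gradient rotated to world axes, shape (nx,ny,nz,3)."""
    g = np.stack(np.gradient(ct.values), axis=-1)  # d/d(index)
    m = np.linalg.inv(ct.affine[:3, :3]).T  # chain rule: grad_world = A^-T grad_index
    return g @ m.T


def _shade(ct: Volume, points: np.ndarray, view: np.ndarray,
           settings: RenderSettings, grad: np.ndarray | None = None,
           fixed_normal: np.ndarray | None = None) -> np.ndarray:
    """Headlight Lambertian factor at surface points."""
    if fixed_normal is not None:
        ndotl = abs(float(np.dot(fixed_normal, view)))
        return np.full(len(points), min(1.0, settings.ambient + settings.diffuse * ndotl))
    if grad is None:
        grad = _world_gradient(ct)
    inv = np.linalg.inv(ct.affine)
    idx = np.clip(np.round(points @ inv[:3, :3].T + inv[:3, 3]).astype(int),
                  0, np.array(ct.shape) - 1)
    g = grad[idx[:, 0], idx[:, 1], idx[:, 2]]
    norms = np.linalg.norm(g, axis=1)
    # outward normal opposes the HU gradient (density increases into bone)
    ndotl = np.where(norms > 1e-9,
                     np.clip((g @ view) / np.maximum(norms, 1e-9), 0.0, None),
                     1.0)
    return np.clip(settings.ambient + settings.diffuse * ndotl, 0.0, 1.0)


def _sample(vol: Volume, points: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(vol.affine)
    idx = points @ inv[:3, :3].T + inv[:3, 3]
    return _trilinear(vol.values, idx)


def _surface_pass(ct: Volume, bone: BinaryMask, camera: Camera,
                  tf: TransferFunction, clip: ClipPlane | None,
                  settings: RenderSettings):
    """Opaque first-hit pass: per-pixel hits, shaded CT colors, cut-face flags."""
    origins = camera.ray_origins()
    hit, points = first_hit(origins, camera.view, bone, clip=clip,
                            settings=settings, ct_for_step=ct)
    colors = np.empty((len(origins), 3))
    colors[:] = settings.background
    cutface = np.zeros(len(origins), dtype=bool)
    if hit.any():
        step = settings.step_for(ct)
        p = points[hit]
        if clip is not None:
            cutface[hit] = (p @ clip.normal) >= clip.offset - step
        # color and shade from the first voxel inside the surface: the refined
        # hit point sits on the air/bone boundary where trilinear HU is a
        # meaningless mixture, so nudge half a step along the ray
        p_in = p + (step / 2.0) * camera.view[None, :]
        inv = np.linalg.inv(ct.affine)
        idx = np.clip(np.round(p_in @ inv[:3, :3].T + inv[:3, 3]).astype(int),
                      0, np.array(ct.shape) - 1)
        hu = ct.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        grad = _world_gradient(ct)
        shade = _shade(ct, p_in, camera.view, settings, grad=grad)
        if clip is not None and cutface.any():
            cf = cutface[hit]
            shade[cf] = _shade(ct, p_in[cf], camera.view, settings,
                               fixed_normal=clip.normal)
        colors[hit] = tf.ct_color(hu) * shade[:, None]
    return hit, points, colors, cutface


def _composite_pass(ct: Volume, bone: BinaryMask, camera: Camera,
                    tf: TransferFunction, clip: ClipPlane | None,
                    settings: RenderSettings) -> np.ndarray:
    """Front-to-back compositing of shaded, transfer-function-mapped samples."""
    origins = camera.ray_origins()
    step = settings.step_for(ct)
    marcher = _RayMarcher(bone, camera.view, step, clip)
    t_near, t_far = marcher.t_range(origins)
    n = len(origins)
    color = np.zeros((n, 3))
    alpha = np.zeros(n)
    active = t_near <= t_far
    t = np.where(active, t_near, 0.0)
    grad = _world_gradient(ct)
    max_iter = int(np.ceil((np.max(t_far[active] - t_near[active]) if active.any() else 0.0)
                           / step)) + 2
    for _ in range(max_iter):
        if not active.any():
            break
        ia = np.flatnonzero(active)
        pts = origins[ia] + t[ia, None] * camera.view[None, :]
        ins = marcher.inside(pts)
        if ins.any():
            sel = ia[ins]
            p = pts[ins]
            hu = _sample(ct, p)
            a = tf.ct_opacity(hu)
            c = tf.ct_color(hu) * _shade(ct, p, camera.view, settings, grad=grad)[:, None]
            trans = 1.0 - alpha[sel]
            color[sel] += (trans * a)[:, None] * c
            alpha[sel] += trans * a
        t[active] += step
        active &= (t <= t_far + 1e-9) & (alpha < 0.995)
    bg = np.asarray(settings.background, dtype=np.float64)
    color += (1.0 - alpha)[:, None] * bg[None, :]
    return color


def render_ct(ct: Volume, bone: BinaryMask, camera: Camera,
              tf: TransferFunction | None = None,
              clip: ClipPlane | None = None,
              settings: RenderSettings | None = None) -> np.ndarray:
    """Volume-render the segmented bone from CT alone; (H, W, 3) floats in [0,1].

    Opaque mode colors each pixel with the Lambertian-shaded CT transfer color
    at the first bone-surface hit; compositing mode accumulates front-to-back
    with the transfer-function opacity.
    """
    tf = tf or TransferFunction()
    settings = settings or RenderSettings()
    if not bone.same_grid(ct):
        raise GeometryError("bone mask and CT must share a grid")
    if settings.surface_mode == "compositing":
        colors = _composite_pass(ct, bone, camera, tf, clip, settings)
    else:
        _, _, colors, _ = _surface_pass(ct, bone, camera, tf, clip, settings)
    return np.clip(colors.reshape(camera.height, camera.width, 3), 0.0, 1.0)


def render_fusion3d(ct: Volume, bone: BinaryMask, spect: Volume, camera: Camera,
                    tf: TransferFunction | None = None,
                    clip: ClipPlane | None = None,
                    settings: RenderSettings | None = None) -> np.ndarray:
    """Project SPECT onto the rendered bone surface and blend with the CT color.

    For each pixel with surface hit p, the SPECT value is interpolated at p,
    normalized by the display window to s in [0, 1], and the pixel becomes
    ``(1 - beta*w(s)) * ct_shaded + beta*w(s) * LUT(s)`` with w(s) = s when
    uptake-modulated (so zero-uptake bone shows pure CT color) or w = 1 for a
    constant blend.  Pixels without a hit keep the background color: no
    extraosseous uptake is ever displayed.
    """
    tf = tf or TransferFunction()
    settings = settings or RenderSettings()
    if not bone.same_grid(ct):
        raise GeometryError("bone mask and CT must share a grid")
    if spect.shape != ct.shape or not np.allclose(spect.affine, ct.affine, atol=1e-6):
        raise GeometryError("SPECT must be resampled to the CT grid before fusion")
    hit, points, colors, _ = _surface_pass(ct, bone, camera, tf, clip, settings)
    if hit.any() and settings.beta > 0:
        s = tf.normalize_spect(_sample(spect, points[hit]))
        w = s if settings.uptake_modulated else np.ones_like(s)
        bw = settings.beta * w
        colors[hit] = (1.0 - bw)[:, None] * colors[hit] + bw[:, None] * tf.spect_color(s)
    return np.clip(colors.reshape(camera.height, camera.width, 3), 0.0, 1.0)


def render_cross_section(ct: Volume, bone: BinaryMask, spect: Volume,
                         clip: ClipPlane, camera: Camera,
                         tf: TransferFunction | None = None,
                         settings: RenderSettings | None = None) -> np.ndarray:
    """Clip-plane cross-section: fused CT/SPECT values shown on the cut face.

    As :func:`render_fusion3d`, but rays that first strike the clip plane
    inside the bone are colored by the fused CT/SPECT values on the cut face
    (flat-shaded with the plane normal), revealing internal bone structure and
    metabolism.  Works best with the camera viewing the cut face on (within
    ~30 degrees of the plane normal).
    """
    import warnings as _w

    tf = tf or TransferFunction()
    settings = settings or RenderSettings()
    if float(np.dot(camera.view, clip.normal)) > -np.cos(np.deg2rad(30.0)):
        _w.warn("camera is more than 30 degrees off the clip normal; "
                "the cut face is viewed obliquely")
    hit, points, colors, cutface = _surface_pass(ct, bone, camera, tf, clip, settings)
    if hit.any() and settings.beta >= 0:
        s = tf.normalize_spect(_sample(spect, points[hit]))
        w = s if settings.uptake_modulated else np.ones_like(s)
        bw = settings.beta * w
        colors[hit] = (1.0 - bw)[:, None] * colors[hit] + bw[:, None] * tf.spect_color(s)
    return np.clip(colors.reshape(camera.height, camera.width, 3), 0.0, 1.0)


def fuse2d_slices(ct: Volume, spect: Volume, axis: str = "axial",
                  alpha: float = 0.5,
                  tf: TransferFunction | None = None) -> np.ndarray:
    """Conventional 2D fusion: windowed CT grayscale + LUT-colored SPECT.

    Returns an (n_slices, H, W, 3) stack; each pixel is
    ``(1 - alpha) * ct_gray + alpha * LUT(s)``.
    """
    tf = tf or TransferFunction()
    if spect.shape != ct.shape or not np.allclose(spect.affine, ct.affine, atol=1e-6):
        raise GeometryError("SPECT must be on the CT grid for 2D fusion")
    axes = {"sagittal": 0, "coronal": 1, "axial": 2}
    if axis not in axes:
        raise ValueError(f"axis must be one of {sorted(axes)}, got {axis!r}")
    a = axes[axis]
    ct_vals = np.moveaxis(ct.values, a, 0)
    sp_vals = np.moveaxis(spect.values, a, 0)
    lo, hi = tf.ct_window
    gray = np.clip((ct_vals - lo) / (hi - lo), 0.0, 1.0)
    s = tf.normalize_spect(sp_vals)
    lut = tf.spect_color(s.ravel()).reshape(s.shape + (3,))
    out = (1.0 - alpha) * gray[..., None] + alpha * lut
    return np.clip(out, 0.0, 1.0)


def save_image(image: np.ndarray, path: str) -> None:
    """Write an (H, W, 3) float image in [0, 1] as 8-bit PNG."""
    from PIL import Image

    arr = np.clip(np.asarray(image) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)
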