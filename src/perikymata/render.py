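"""Phong rendering of voxel surface models under colored directional lights.

The renderer reproduces a topo-densitometric visualization protocol: a
surface model is lit by up to four directional light sources, each with
ambient, diffuse and specular components whose intensities follow a 0-255
convention.  The canonical setup uses a white light facing the surface
(LS1) plus a second source (LS2) with a low white ambient (5), a moderate
orange diffuse (35) and a strong pale-blue specular component (about 200),
aimed alternately from above and below at grazing incidence; the two
resulting images are later merged by high-frequency reinforcement (see
:mod:`perikymata.composite`).

Projection is orthographic; surface elements are splatted as single-pixel
points through a z-buffer after back-face culling.  Three shading modes
exist: ``phong`` (topography shaded, diffuse term modulated by the density
attribute when present - the topo-densitometric mode), ``normalize_gradient``
(pure topography, density ignored) and ``density`` (flat shading driven by
the density attribute alone).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .surface_seg import SurfaceModel

__all__ = [
    "LightComponent",
    "LightSource",
    "ViewConfig",
    "default_ls1",
    "default_ls2",
    "render_phong",
    "rotate_surface",
    "multi_view_plate",
]

PALE_BLUE = (0.8, 0.9, 1.0)
ORANGE = (1.0, 0.6, 0.2)
WHITE = (1.0, 1.0, 1.0)


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction")
    return v / n


@dataclass(frozen=True)
class LightComponent:
    """One additive light term: an RGB hue and a 0-255 intensity."""

    color: tuple[float, float, float]
    intensity: float

    def __post_init__(self) -> None:
        if any(not 0 <= c <= 1 for c in self.color):
            raise ValueError("color channels must be in [0, 1]")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")

    @property
    def rgb(self) -> np.ndarray:
        """Effective linear RGB contribution (intensity / 255 x color)."""
        return np.asarray(self.color, dtype=float) * (self.intensity / 255.0)


@dataclass(frozen=True)
class LightSource:
    """Directional light with ambient, diffuse and specular components.

    ``direction`` points from the light toward the surface, in (z, y, x)
    component order matching the volume axes.
    """

    direction: tuple[float, float, float]
    ambient: LightComponent
    diffuse: LightComponent
    specular: LightComponent
    shininess: float = 30.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction",
                           tuple(_unit(np.asarray(self.direction))))
        if self.shininess < 1:
            raise ValueError("shininess must be >= 1")


def default_ls1(view_direction: Sequence[float] = (0.0, 0.0, -1.0)
                ) -> LightSource:
    """White head-on light aimed along the viewing axis."""
    return LightSource(
        direction=tuple(_unit(np.asarray(view_direction))),
        ambient=LightComponent(WHITE, 20.0),
        diffuse=LightComponent(WHITE, 120.0),
        specular=LightComponent(WHITE, 60.0),
    )


def default_ls2(direction: Sequence[float] = (-1.0, 0.0, 0.0)
                ) -> LightSource:
    """Second light preset: low white ambient (5), orange diffuse (35),
    pale-blue specular (about 200); by default aimed from the top (down the
    crown axis) for grazing incidence on a vertically oriented tooth."""
    return LightSource(
        direction=tuple(_unit(np.asarray(direction))),
        ambient=LightComponent(WHITE, 5.0),
        diffuse=LightComponent(ORANGE, 35.0),
        specular=LightComponent(PALE_BLUE, 200.0),
    )


@dataclass
class ViewConfig:
    """Orthographic camera: view axis, screen-up vector and pixel size.

    ``up`` is re-orthogonalized against ``view``.  ``center_um`` and
    ``half_extent_um``, when given, fix the image footprint (useful for
    animations where the framing must not change between frames);
    otherwise the footprint is fitted to the surface.
    """

    view: tuple[float, float, float] = (0.0, 0.0, -1.0)
    up: tuple[float, float, float] = (1.0, 0.0, 0.0)
    pixel_size_um: float = 1.0
    mode: str = "phong"
    center_um: np.ndarray | None = None
    half_extent_um: float | None = None

    def __post_init__(self) -> None:
        f = _unit(np.asarray(self.view))
        u = np.asarray(self.up, dtype=float)
        u = u - np.dot(u, f) * f
        if np.linalg.norm(u) < 1e-12:
            raise ValueError("up vector parallel to view direction")
        u = _unit(u)
        self.view = tuple(f)
        self.up = tuple(u)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.mode not in ("phong", "normalize_gradient", "density"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _shade(surf: SurfaceModel, lights: Sequence[LightSource],
           view_f: np.ndarray, mode: str) -> np.ndarray:
    """Per-element RGB in [0, 1] before splatting."""
    n = surf.normals
    attr = surf.density_attr
    if mode != "normalize_gradient" and attr is not None and len(attr):
        span = float(attr.max() - attr.min())
        norm_attr = ((attr - attr.min()) / span if span > 0
                     else np.ones_like(attr))
        albedo = 0.25 + 0.75 * norm_attr
    else:
        albedo = np.ones(len(surf))

    if mode == "density":
        return np.clip(albedo[:, None] * np.ones((1, 3)), 0.0, 1.0)

    v_dir = -view_f  # surface -> viewer
    rgb = np.zeros((len(surf), 3))
    for light in lights:
        l_vec = -np.asarray(light.direction)  # surface -> light
        ndotl = np.clip(n @ l_vec, 0.0, None)
        refl = 2.0 * ndotl[:, None] * n - l_vec[None, :]
        rdotv = np.clip(refl @ v_dir, 0.0, None)
        spec = np.where(ndotl > 0, rdotv ** light.shininess, 0.0)
        rgb += light.ambient.rgb[None, :]
        rgb += (ndotl * albedo)[:, None] * light.diffuse.rgb[None, :]
        rgb += spec[:, None] * light.specular.rgb[None, :]
    return np.clip(rgb, 0.0, 1.0)


def render_phong(surf: SurfaceModel, lights: Sequence[LightSource],
                 view: ViewConfig) -> np.ndarray:
    """Render a surface model to an RGB image (H, W, 3) in [0, 1]."""
    if len(surf) == 0:
        raise ValueError("cannot render an empty surface")
    if not 1 <= len(lights) <= 4:
        raise ValueError("need between 1 and 4 light sources")
    f = np.asarray(view.view)
    u = np.asarray(view.up)
    r = np.cross(f, u)

    pos_um = surf.positions * surf.voxel_size_um
    if view.center_um is not None:
        center = np.asarray(view.center_um, dtype=float)
    else:
        center = 0.5 * (pos_um.min(axis=0) + pos_um.max(axis=0))
    rel = pos_um - center
    cols = rel @ r / view.pixel_size_um
    rows = -(rel @ u) / view.pixel_size_um
    depth = rel @ f

    if view.half_extent_um is not None:
        half_px = int(np.ceil(view.half_extent_um / view.pixel_size_um))
    else:
        half_px = int(np.ceil(max(np.abs(cols).max(), np.abs(rows).max())))
    size = 2 * half_px + 1
    # floor(x + 0.5): np.round's half-to-even would collapse adjacent
    # half-integer columns onto one pixel
    ci = np.floor(cols + 0.5).astype(int) + half_px
    ri = np.floor(rows + 0.5).astype(int) + half_px

    facing = surf.normals @ f < 0  # toward the camera
    in_frame = (ci >= 0) & (ci < size) & (ri >= 0) & (ri < size)
    keep = facing & in_frame
    if not keep.any():
        return np.zeros((size, size, 3))

    shade = _shade(surf, lights, f, view.mode)
    ri, ci, depth, shade = ri[keep], ci[keep], depth[keep], shade[keep]
    # z-buffer by ordered overwrite: sort far-to-near, nearest wins
    order = np.argsort(-depth, kind="stable")
    img = np.zeros((size, size, 3))
    img[ri[order], ci[order]] = shade[order]
    return img


def rotate_surface(surf: SurfaceModel, angle_deg: float,
                   axis_point_px: Sequence[float] | None = None,
                   axis: Sequence[float] = (1.0, 0.0, 0.0)) -> SurfaceModel:
    """Rotate a surface model about an axis through ``axis_point_px``.

    Default axis is the volume z axis (the crown's long axis by the
    package's phantom convention); the rotation sense is counterclockwise
    when viewed from the cusp (positive-z) end.
    """
    a = _unit(np.asarray(axis))
    if axis_point_px is None:
        axis_point_px = surf.positions.mean(axis=0)
    p0 = np.asarray(axis_point_px, dtype=float)
    th = np.deg2rad(angle_deg)
    # Rodrigues rotation matrix
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    pos = (surf.positions - p0) @ R.T + p0
    nrm = surf.normals @ R.T
    return replace(surf, positions=pos, normals=nrm, mask=None)


def multi_view_plate(surf: SurfaceModel, lights: Sequence[LightSource],
                     view: ViewConfig, step_deg: float = 45.0
                     ) -> list[np.ndarray]:
    """Render the model at successive rotations about its long axis.

    A 45 degree step yields the classic eight-view plate.  Framing is held
    fixed across views (bounding-sphere footprint) so images are directly
    comparable.
    """
    if step_deg <= 0 or not np.isclose(360.0 % step_deg, 0.0):
        raise ValueError("step_deg must divide 360")
    n_views = int(round(360.0 / step_deg))
    centroid = surf.positions.mean(axis=0)
    center_um = centroid * surf.voxel_size_um
    pos_um = surf.positions * surf.voxel_size_um
    radius = np.linalg.norm(pos_um - center_um[None, :], axis=1).max()
    fixed = replace(view, center_um=center_um,
                    half_extent_um=float(radius) * 1.05)
    images = []
    for k in range(n_views):
        rotated = rotate_surface(surf, k * step_deg, axis_point_px=centroid)
        images.append(render_phong(rotated, lights, fixed))
    return images
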