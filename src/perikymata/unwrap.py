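"""Rotational unwrapping of a crown or root surface.

The tooth model is rotated in small steps about its long axis under fixed
lights and camera; at every step the single pixel column through the
projection of the rotation axis is extracted, and the columns are
concatenated left to right over a full revolution.  The result is a 2D
angle x height map on which perikymata, hypoplasias and periradicular
bands can be followed around the whole circumference.  Where the local
radius differs from the mean radius the map is azimuthally distorted -
an accepted property of this deliberately simple flattening.

Rotation sense is counterclockwise viewed from the cusp (positive z) end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .composite import luminance
from .render import LightSource, ViewConfig, render_phong, rotate_surface
from .surface_seg import SurfaceModel

__all__ = ["UnwrappedMap", "unwrap_surface", "suggest_angle_step"]


@dataclass
class UnwrappedMap:
    """Unwrapped surface map: rows = height (cusp at row 0), columns =
    azimuth; ``column k`` corresponds to rotation angle ``k x
    angle_step_deg``."""

    image: np.ndarray            # (height, n_columns) luminance
    angle_step_deg: float
    axis_point_px: np.ndarray    # (z, y, x) point on the rotation axis
    pixel_size_um: float

    def __post_init__(self) -> None:
        ncols = self.image.shape[1]
        if not np.isclose(ncols * self.angle_step_deg, 360.0):
            raise ValueError("columns x angle_step_deg must equal 360")

    @property
    def n_columns(self) -> int:
        return self.image.shape[1]

    def column_azimuth_deg(self, col: int) -> float:
        return col * self.angle_step_deg


def suggest_angle_step(surf: SurfaceModel,
                       axis_point_px: Sequence[float] | None = None,
                       pixel_size_um: float | None = None) -> float:
    """Largest angular step (deg) without azimuthal undersampling.

    Chosen so the arc travelled by the outermost surface element per step
    is at most one rendered pixel: step <= 360 / (2 pi r_max).
    """
    if pixel_size_um is None:
        pixel_size_um = surf.voxel_size_um
    if axis_point_px is None:
        axis_point_px = surf.positions.mean(axis=0)
    p0 = np.asarray(axis_point_px, dtype=float)
    radial = (surf.positions - p0)[:, 1:]  # (y, x) offsets from the axis
    r_max_px = (np.linalg.norm(radial, axis=1).max()
                * surf.voxel_size_um / pixel_size_um)
    if r_max_px <= 0:
        return 360.0
    return 360.0 / (2.0 * np.pi * r_max_px)


def unwrap_surface(surf: SurfaceModel, lights: Sequence[LightSource],
                   axis_point_px: Sequence[float] | None = None,
                   angle_step_deg: float = 1.0,
                   view: ViewConfig | None = None) -> UnwrappedMap:
    """Unwrap a surface by single-column concatenation over 360 degrees.

    The camera looks horizontally (perpendicular to the long axis) with
    the cusp end up; framing is centred on the rotation axis so the
    extracted central column always contains the axis projection.
    """
    if angle_step_deg <= 0 or not np.isclose(
            round(360.0 / angle_step_deg) * angle_step_deg, 360.0):
        raise ValueError("angle_step_deg must divide 360")
    if axis_point_px is None:
        axis_point_px = surf.positions.mean(axis=0)
    p0 = np.asarray(axis_point_px, dtype=float)

    vs = surf.voxel_size_um
    if view is None:
        view = ViewConfig(view=(0.0, 1.0, 0.0), up=(1.0, 0.0, 0.0),
                          pixel_size_um=vs)
    rel_um = (surf.positions - p0) * vs
    half_extent = float(np.abs(rel_um).max()) * 1.05 + view.pixel_size_um
    fixed = replace(view, center_um=p0 * vs, half_extent_um=half_extent)

    n_cols = int(round(360.0 / angle_step_deg))
    columns = []
    for k in range(n_cols):
        rotated = rotate_surface(surf, k * angle_step_deg,
                                 axis_point_px=p0)
        img = luminance(render_phong(rotated, lights, fixed))
        columns.append(img[:, img.shape[1] // 2])
    image = np.stack(columns, axis=1)
    return UnwrappedMap(image=image, angle_step_deg=angle_step_deg,
                        axis_point_px=p0, pixel_size_um=view.pixel_size_um)
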