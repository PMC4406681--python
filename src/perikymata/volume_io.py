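"""Tomographic volume I/O, pre-processing and virtual histological slicing.

Volumes are 3D scalar grids in ``(z, y, x)`` index order with an isotropic
voxel size in micrometres.  Physical positions refer to voxel centres:
``position_um = origin_um + index * voxel_size_um``.

The pre-processing chain mirrors a typical propagation phase-contrast
microtomography workflow: 32-bit reconstructions are windowed to 16 bits,
sub-scans are concatenated along the rotation (z) axis, ring artifacts are
optionally suppressed slice-by-slice, and a 2x2x2 binned copy (double voxel
size, improved signal-to-noise) is produced for overview work.  Virtual
slices of arbitrary orientation and thickness are extracted by trilinear
interpolation and averaged through the slab thickness.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "Volume",
    "SlicePlane",
    "read_tiff_stack",
    "write_tiff_stack",
    "to_16bit",
    "default_window",
    "concat_subscans",
    "bin2",
    "suppress_rings",
    "reslice",
]


class FormatError(ValueError):
    """Inconsistent slice shapes, bit depths or image geometries."""


class GeometryError(ValueError):
    """A slicing plane misses the volume."""


@dataclass
class Volume:
    """A 3D scalar image with physical voxel size.

    Attributes
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Scalar grid; any float or integer dtype.
    voxel_size_um : float
        Isotropic edge length of one voxel, micrometres (> 0).
    bit_depth : int
        Nominal acquisition bit depth, 16 or 32.
    origin_um : ndarray, shape (3,)
        Physical position of voxel (0, 0, 0), in (z, y, x) order.
    """

    voxels: np.ndarray
    voxel_size_um: float
    bit_depth: int = 32
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a non-empty 3D array")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        if self.bit_depth not in (16, 32):
            raise ValueError("bit_depth must be 16 or 32")
        self.origin_um = np.asarray(self.origin_um, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def copy(self) -> "Volume":
        return replace(self, voxels=self.voxels.copy(),
                       origin_um=self.origin_um.copy())


@dataclass
class SlicePlane:
    """An oriented slab for virtual sectioning.

    ``normal`` is given in (z, y, x) component order and is normalized on
    construction; ``thickness_um`` is the full slab thickness over which
    samples are averaged.
    """

    origin_um: np.ndarray
    normal: np.ndarray
    thickness_um: float

    def __post_init__(self) -> None:
        self.origin_um = np.asarray(self.origin_um, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("normal must be non-zero")
        self.normal = n / norm
        if not self.thickness_um > 0:
            raise ValueError("thickness_um must be positive")


_NUM_RE = re.compile(r"\d+")


def read_tiff_stack(path: str | Path, voxel_size_um: float) -> Volume:
    """Read a multipage TIFF file or a directory of single-page TIFFs.

    Directory slices are stacked in lexicographic filename order.  All
    slices must share one 2D shape and dtype.  A sidecar ``<name>.json``
    written by :func:`write_tiff_stack` overrides ``voxel_size_um`` if its
    value differs only through the caller passing ``None``.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF files in {path}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        dtypes = {s.dtype for s in slices}
        if len(shapes) > 1 or len(dtypes) > 1:
            raise FormatError("mixed slice shapes or bit depths in stack")
        arr = np.stack(slices, axis=0)
        sidecar = path / "volume.json"
    else:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        sidecar = path.with_suffix(".json")
    if voxel_size_um is None:
        if not sidecar.exists():
            raise ValueError("voxel_size_um not given and no sidecar found")
        voxel_size_um = json.loads(sidecar.read_text())["voxel_size_um"]
    bit_depth = 16 if arr.dtype.itemsize <= 2 else 32
    return Volume(arr, float(voxel_size_um), bit_depth=bit_depth)


def write_tiff_stack(vol: Volume, path: str | Path,
                     meta: dict | None = None) -> Path:
    """Write a volume as one multipage TIFF plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, vol.voxels)
    sidecar = path.with_suffix(".json")
    payload = {"voxel_size_um": vol.voxel_size_um,
               "bit_depth": vol.bit_depth,
               "shape": list(vol.shape),
               "origin_um": list(vol.origin_um)}
    if meta:
        payload.update(meta)
    sidecar.write_text(json.dumps(payload, indent=2))
    return path


def default_window(vol: Volume,
                   percentiles: tuple[float, float] = (0.1, 99.9)
                   ) -> tuple[float, float]:
    """Robust (lo, hi) grey window for 16-bit conversion."""
    lo, hi = np.percentile(vol.voxels, percentiles)
    if lo >= hi:  # flat volume
        lo, hi = float(vol.voxels.min()), float(vol.voxels.min()) + 1.0
    return float(lo), float(hi)


def to_16bit(vol: Volume, lo: float, hi: float) -> Volume:
    """Window a volume linearly from [lo, hi] to the full uint16 range.

    Values outside the window are clipped; ``lo`` maps to 0 and ``hi`` to
    65535, with round-half-up quantization.
    """
    if not lo < hi:
        raise ValueError("lo must be strictly less than hi")
    x = (np.asarray(vol.voxels, dtype=np.float64) - lo) / (hi - lo)
    out = np.floor(np.clip(x, 0.0, 1.0) * 65535.0 + 0.5).astype(np.uint16)
    return replace(vol, voxels=out, bit_depth=16,
                   origin_um=vol.origin_um.copy())


def concat_subscans(parts: Sequence[Volume]) -> Volume:
    """Concatenate sub-scans along z, preserving order."""
    if not parts:
        raise ValueError("need at least one sub-scan")
    first = parts[0]
    for p in parts[1:]:
        if p.voxels.shape[1:] != first.voxels.shape[1:]:
            raise FormatError("in-plane shapes differ between sub-scans")
        if not np.isclose(p.voxel_size_um, first.voxel_size_um):
            raise FormatError("voxel sizes differ between sub-scans")
    vox = np.concatenate([p.voxels for p in parts], axis=0)
    return replace(first, voxels=vox, origin_um=first.origin_um.copy())


def bin2(vol: Volume) -> Volume:
    """2x2x2 mean binning: halved dimensions, doubled voxel size.

    Trailing planes of odd-sized axes are dropped.  The grid origin moves
    half an input voxel so that output voxel centres sit at the centre of
    each 2x2x2 block.
    """
    z, y, x = (d // 2 * 2 for d in vol.shape)
    v = np.asarray(vol.voxels[:z, :y, :x], dtype=np.float64)
    out = v.reshape(z // 2, 2, y // 2, 2, x // 2, 2).mean(axis=(1, 3, 5))
    if np.issubdtype(vol.voxels.dtype, np.floating):
        out = out.astype(vol.voxels.dtype)
    return replace(vol, voxels=out, voxel_size_um=vol.voxel_size_um * 2,
                   origin_um=vol.origin_um + vol.voxel_size_um / 2)


def _polar_ring_estimate(sl: np.ndarray, kernel_width_px: int) -> np.ndarray:
    """Per-slice ring pattern estimate by polar residual analysis.

    The slice is resampled onto a polar (radius x angle) grid about its
    centre; the angular mean at each radius captures circularly symmetric
    structure.  Subtracting a running median (width ``kernel_width_px``) of
    that radial profile isolates the narrow ring component, which is then
    mapped back to Cartesian coordinates.
    """
    ny, nx = sl.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    rmax = int(np.ceil(np.hypot(max(cy, ny - 1 - cy), max(cx, nx - 1 - cx))))
    nr, na = rmax + 1, max(90, 4 * rmax)
    r = np.arange(nr, dtype=np.float64)
    th = np.linspace(0, 2 * np.pi, na, endpoint=False)
    yy = cy + r[:, None] * np.sin(th)[None, :]
    xx = cx + r[:, None] * np.cos(th)[None, :]
    inside = (yy >= 0) & (yy <= ny - 1) & (xx >= 0) & (xx <= nx - 1)
    polar = ndimage.map_coordinates(np.asarray(sl, dtype=np.float64),
                                    [yy, xx], order=1, mode="nearest")
    counts = inside.sum(axis=1)
    radial = np.where(counts > 0,
                      (polar * inside).sum(axis=1) / np.maximum(counts, 1),
                      0.0)
    smooth = ndimage.median_filter(radial, size=kernel_width_px,
                                   mode="nearest")
    ring_profile = radial - smooth
    # back to Cartesian: each pixel takes the ring value at its radius
    yg, xg = np.mgrid[0:ny, 0:nx]
    rad = np.hypot(yg - cy, xg - cx)
    return np.interp(rad.ravel(), r, ring_profile).reshape(ny, nx)


def suppress_rings(vol: Volume, kernel_width_px: int = 21) -> Volume:
    """Suppress concentric ring artifacts slice by slice.

    Rings are assumed centred on the reconstruction (slice) centre.  The
    estimated ring pattern is subtracted from every slice; the slice mean is
    restored exactly, so global intensity statistics are preserved.
    """
    if kernel_width_px < 3 or kernel_width_px % 2 == 0:
        raise ValueError("kernel_width_px must be odd and >= 3")
    if kernel_width_px > max(vol.shape[1], vol.shape[2]):
        raise ValueError("kernel_width_px larger than slice extent")
    out = np.empty_like(np.asarray(vol.voxels, dtype=np.float64))
    for k in range(vol.shape[0]):
        sl = np.asarray(vol.voxels[k], dtype=np.float64)
        ring = _polar_ring_estimate(sl, kernel_width_px)
        corrected = sl - ring
        corrected += sl.mean() - corrected.mean()
        out[k] = corrected
    if np.issubdtype(vol.voxels.dtype, np.floating):
        out = out.astype(vol.voxels.dtype)
    return replace(vol, voxels=out, origin_um=vol.origin_um.copy())


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane (row, col) basis for a slab normal."""
    n = np.asarray(normal, dtype=float)
    helper = np.zeros(3)
    helper[np.argmin(np.abs(n))] = 1.0
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def reslice(vol: Volume, plane: SlicePlane) -> np.ndarray:
    """Extract a virtual histological slice of arbitrary orientation.

    The slab is sampled on planes spaced one voxel apart through its
    thickness and averaged (mean projection).  Output pixel size equals the
    volume's voxel size.  For axis-aligned normals the in-plane axes are the
    two remaining volume axes in (z, y, x) order, so a one-voxel-thick
    axis-aligned slab reproduces the corresponding raw slice exactly.
    """
    vs = vol.voxel_size_um
    n = plane.normal
    # fractional voxel coordinate of the plane origin
    c0 = (plane.origin_um - vol.origin_um) / vs
    shape = np.array(vol.shape, dtype=float)
    if np.any(c0 < -0.5) or np.any(c0 > shape - 0.5):
        raise GeometryError("plane origin lies outside the volume")
    nsamp = max(1, int(np.ceil(plane.thickness_um / vs - 1e-9)))
    offsets = (np.arange(nsamp) - (nsamp - 1) / 2.0)  # voxels along normal

    axis_aligned = np.isclose(np.abs(n).max(), 1.0, atol=1e-9)
    if axis_aligned:
        ax = int(np.argmax(np.abs(n)))
        others = [a for a in range(3) if a != ax]
        rows, cols = (int(vol.shape[a]) for a in others)
        rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)
        acc = np.zeros((rows, cols), dtype=np.float64)
        data = np.asarray(vol.voxels, dtype=np.float64)
        for off in offsets:
            k = c0[ax] + off * np.sign(n[ax])
            coords = [None, None, None]
            coords[ax] = np.full_like(rr, k)
            coords[others[0]] = rr
            coords[others[1]] = cc
            if np.isclose(k, round(k), atol=1e-9) and 0 <= round(k) < vol.shape[ax]:
                idx = [slice(None)] * 3
                idx[ax] = int(round(k))
                acc += data[tuple(idx)]
            else:
                acc += ndimage.map_coordinates(data, coords, order=1,
                                               mode="nearest")
        return acc / nsamp

    u, v = _plane_basis(n)
    # project the volume's corner positions onto (u, v) to size the output
    corners = np.array([[i, j, k] for i in (0, shape[0] - 1)
                        for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)])
    rel = corners - c0
    pu = rel @ u
    pv = rel @ v
    ur = np.arange(np.floor(pu.min()), np.ceil(pu.max()) + 1)
    vr = np.arange(np.floor(pv.min()), np.ceil(pv.max()) + 1)
    if ur.size == 0 or vr.size == 0:
        raise GeometryError("plane does not intersect the volume")
    uu, vv = np.meshgrid(ur, vr, indexing="ij")
    data = np.asarray(vol.voxels, dtype=np.float64)
    acc = np.zeros(uu.shape, dtype=np.float64)
    for off in offsets:
        pts = (c0[None, None, :] + uu[..., None] * u + vv[..., None] * v
               + off * n)
        acc += ndimage.map_coordinates(
            data, [pts[..., 0], pts[..., 1], pts[..., 2]],
            order=1, mode="nearest")
    return acc / nsamp
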