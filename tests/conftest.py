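"""Shared fixtures: small phantoms and analytic surface models.

Phantom volumes are generated once per session; they are the ground-truth
substrate for segmentation, rendering, unwrapping and counting tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from perikymata import phantom as ph
from perikymata.surface_seg import SurfaceModel


@pytest.fixture(scope="session")
def small_spec() -> ph.ToothPhantomSpec:
    return ph.ToothPhantomSpec()  # 240 um crown, 10 ridges at 24 um


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """(volume, truth) without fringes, 2 um voxels."""
    return ph.build_phantom(small_spec, 2.0)


@pytest.fixture(scope="session")
def fringed_phantom(small_phantom):
    vol, truth = small_phantom
    return ph.add_phase_fringes(vol), truth


@pytest.fixture(scope="session")
def defect_spec() -> ph.ToothPhantomSpec:
    return ph.ToothPhantomSpec(
        defects=[(0.3, 3.0, 6.0), (0.55, 4.0, 6.0), (0.8, 3.0, 6.0)])


@pytest.fixture(scope="session")
def defect_phantom(defect_spec):
    vol, truth = ph.build_phantom(defect_spec, 2.0)
    return ph.add_phase_fringes(vol), truth


def make_sphere_surface(radius: float = 25.0, center: float = 30.0,
                        n_theta: int = 60, n_phi: int = 120,
                        cap_only: bool = False) -> SurfaceModel:
    """Analytic sphere (or upper cap) point-set surface with exact normals."""
    t_hi = np.pi / 2 * 0.97 if cap_only else np.pi * 0.97
    th = np.linspace(0.03, t_hi, n_theta)
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    T, P = np.meshgrid(th, phi)
    nz = np.cos(T).ravel()
    ny = (np.sin(T) * np.sin(P)).ravel()
    nx = (np.sin(T) * np.cos(P)).ravel()
    nrm = np.stack([nz, ny, nx], axis=1)
    pos = nrm * radius + center
    size = int(2 * center)
    return SurfaceModel(pos, nrm, "OES", 1.0, (size, size, size))


def make_cylinder_surface(n_ridges: int = 0, amplitude: float = 1.5,
                          radius: float = 30.0, height: int = 60,
                          center: float = 40.0, n_theta: int = 720
                          ) -> SurfaceModel:
    """Vertical cylinder with optional angular ridges, exact normals."""
    zs = np.arange(height, dtype=float)
    th = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    Z, TH = np.meshgrid(zs, th, indexing="ij")
    if n_ridges:
        R = radius + amplitude * np.cos(n_ridges * TH)
        drdth = -amplitude * n_ridges * np.sin(n_ridges * TH)
        nt = -drdth / R
    else:
        R = np.full_like(TH, radius)
        nt = np.zeros_like(TH)
    y = center + R * np.sin(TH)
    x = center + R * np.cos(TH)
    ny = np.sin(TH) + nt * np.cos(TH)
    nx = np.cos(TH) - nt * np.sin(TH)
    pos = np.stack([Z.ravel(), y.ravel(), x.ravel()], axis=1)
    nrm = np.stack([np.zeros(TH.size), ny.ravel(), nx.ravel()], axis=1)
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    size = int(2 * center)
    return SurfaceModel(pos, nrm, "OES", 1.0, (height, size, size))
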