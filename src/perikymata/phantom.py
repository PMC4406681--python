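"""Synthetic tooth phantom with known ground truth.

The phantom is an axisymmetric crown cap: a dentine core bounded by the
enamel-dentine junction (EDJ), wrapped in an enamel shell bounded by the
outer enamel surface (OES).  Both surfaces are paraboloid-like radius
profiles of the distance ``d`` from the cusp tip measured along the crown
axis (the z axis of the grid, tip up).  Optional features:

* long-period incremental ridges on the OES at a fixed surface spacing
  (the synthetic analogue of perikymata), recorded in the ground truth;
* circumferential hypoplastic grooves at given crown heights, which also
  carry an internal density drop crossing the EDJ (accentuated stress
  lines), so that defects are visible both topographically and in the
  fringe-contrast "barcode" at the EDJ;
* internal long-period density modulation in the enamel, tilted so that
  the spacing measured along the growth direction equals the daily
  secretion rate times the periodicity;
* a thin demineralized (lower-density) layer at a controlled depth below
  the OES.  When phased at half the ridge period, the layer is interrupted
  by narrow protected bands midway between the true ridge crests; at full
  resolution it is invisible on the surface, but after partial-volume
  degradation the apparent surface bulges outward at the protected bands,
  splitting every period in two - the classic spurious "subdivision" of
  long-period ridges seen in demineralized fossil enamel imaged at
  insufficient resolution.

Density is in arbitrary units with air 0.0 < matrix 0.15 < dentine 0.55 <
enamel 1.0.  Propagation phase-contrast fringes are added separately by
:func:`add_phase_fringes` so tests can exercise pipelines with and without
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .volume_io import Volume

__all__ = [
    "Material",
    "AIR", "MATRIX", "DENTINE", "ENAMEL",
    "ToothPhantomSpec",
    "FringeModel",
    "GroundTruth",
    "build_phantom",
    "add_phase_fringes",
    "degrade_resolution",
    "add_noise",
]


@dataclass(frozen=True)
class Material:
    """A homogeneous tissue/medium with density and refractive terms.

    ``delta`` and ``beta`` are the phase-shift and attenuation decrements of
    the refractive index n = 1 - delta + i*beta; only their ordering (denser
    means larger delta) matters for the fringe polarity convention.
    """

    name: str
    density: float
    delta: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be non-negative")


AIR = Material("air", 0.0, 0.0, 0.0)
MATRIX = Material("matrix", 0.15, 1.5e-7, 1e-10)
DENTINE = Material("dentine", 0.55, 5.5e-7, 3e-10)
ENAMEL = Material("enamel", 1.0, 1.0e-6, 5e-10)

#: axial thickness (um) of a demineralized subsurface layer
DEMIN_LAYER_THICKNESS_UM = 5.0


@dataclass
class ToothPhantomSpec:
    """Parameters of the synthetic crown.

    Lengths in micrometres.  ``defects`` entries are
    ``(height_fraction, amplitude_um, width_um)``: a circumferential groove
    of the given radial depth centred at ``height_fraction`` of the crown
    height below the cusp tip, paired with an internal stress line whose
    density drop is proportional to the amplitude.  ``demineral_layers``
    entries are ``(depth_um, half_period_offset, density_drop_fraction)``.
    """

    crown_height_um: float = 240.0
    crown_radius_um: float = 100.0
    enamel_thickness_um: float = 45.0
    cuspal_thickness_um: float = 60.0
    edj_profile: float = 0.5          # radius ~ ((d-c)/(H-c))**edj_profile
    retzius_spacing_um: float = 24.0  # surface spacing of long-period ridges
    ridge_amplitude_um: float = 2.0
    periodicity_days: int = 8
    dsr_um_per_day: float = 3.57
    defects: Sequence[tuple[float, float, float]] = field(default_factory=list)
    demineral_layers: Sequence[tuple[float, bool, float]] = field(
        default_factory=list)
    crypt_matrix: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cuspal_thickness_um <= 3 * self.enamel_thickness_um:
            raise ValueError(
                "cuspal thickness must be in (0, 3 x enamel thickness]")
        if not 5 <= self.periodicity_days <= 12:
            raise ValueError("periodicity_days must lie in [5, 12]")
        for hf, amp, w in self.defects:
            if not 0 <= hf <= 1:
                raise ValueError("defect height_fraction must be in [0, 1]")
            if amp < 0 or w <= 0:
                raise ValueError("defect amplitude/width must be positive")
        for depth, _, drop in self.demineral_layers:
            if depth <= 0:
                raise ValueError("demineral layer depth must be positive")
            if not 0 <= drop <= 1:
                raise ValueError("density_drop_fraction must be in [0, 1]")
        if self.crown_height_um <= 0 or self.crown_radius_um <= 0:
            raise ValueError("crown height and radius must be positive")
        if self.retzius_spacing_um <= 0 or self.dsr_um_per_day <= 0:
            raise ValueError("spacing and secretion rate must be positive")


@dataclass(frozen=True)
class FringeModel:
    """Propagation phase-contrast double-fringe parameters.

    Each density step gains an antisymmetric bright/dark band pair of
    characteristic half-width ``width_px``, peak amplitude
    ``amplitude_fraction`` times the local density step, with the bright
    band on the denser side and the zero-crossing on the interface.
    """

    width_px: float = 2.0
    amplitude_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")
        if not 0 < self.amplitude_fraction <= 1:
            raise ValueError("amplitude_fraction must be in (0, 1]")


@dataclass
class GroundTruth:
    """Exact geometry of a generated phantom, for validation."""

    oes_mask: np.ndarray                 # bool, boundary shell of the tooth
    edj_mask: np.ndarray                 # bool, boundary shell of the dentine
    perikymata_positions_um: np.ndarray  # distance from cusp tip, increasing
    n_perikymata: int
    defect_positions_um: np.ndarray
    subdivision_positions_um: np.ndarray  # spurious half-period positions
    axis_yx_px: tuple[float, float]       # crown axis in (y, x) voxel coords
    tip_z_um: float                       # z position of the cusp tip
    crown_height_um: float
    ridge_spacing_um: float


def _radius_profiles(spec: ToothPhantomSpec, d_um: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Base OES radius, ridge/defect-modulated OES radius and EDJ radius."""
    H = spec.crown_height_um
    d = np.clip(d_um, 0.0, H)
    r_oes_base = spec.crown_radius_um * np.sqrt(d / H)
    s = spec.retzius_spacing_um
    relief = spec.ridge_amplitude_um * np.cos(2 * np.pi * (d - s / 2) / s)
    # fade the modulation over the first half period below the tip
    relief = relief * np.clip(d / (s / 2), 0.0, 1.0)
    r_oes = r_oes_base + relief
    for hf, amp, w in spec.defects:
        r_oes = r_oes - amp * np.exp(-0.5 * ((d - hf * H) / w) ** 2)
    c = spec.cuspal_thickness_um
    r_edj_cerv = max(spec.crown_radius_um - spec.enamel_thickness_um, 1.0)
    t = np.clip((d - c) / max(H - c, 1e-9), 0.0, None)
    r_edj = r_edj_cerv * t ** spec.edj_profile
    return r_oes_base, np.maximum(r_oes, 0.0), r_edj


def ridge_positions(spec: ToothPhantomSpec) -> np.ndarray:
    """Analytic crest positions (um from the cusp tip) of the OES ridges.

    Crests sit at (k + 1/2) x spacing; crests closer than a quarter period
    to the cervix are excluded since their circumferential expression is
    clipped by the crown base.
    """
    s = spec.retzius_spacing_um
    k = np.arange(0, int(np.ceil(spec.crown_height_um / s)) + 1)
    pos = (k + 0.5) * s
    return pos[pos <= spec.crown_height_um - 0.25 * s]


def _protection_profile(d_um: np.ndarray, spec: ToothPhantomSpec,
                        sigma_um: float = 2.5) -> np.ndarray:
    """Narrow protected (non-demineralized) bands midway between crests."""
    s = spec.retzius_spacing_um
    centers = np.arange(1, int(spec.crown_height_um / s) + 1) * s
    prof = np.zeros_like(d_um)
    for c in centers:
        prof += np.exp(-0.5 * ((d_um - c) / sigma_um) ** 2)
    return np.clip(prof, 0.0, 1.0)


def subdivision_positions(spec: ToothPhantomSpec) -> np.ndarray:
    """Positions where spurious ridge subdivisions appear after degradation."""
    s = spec.retzius_spacing_um
    k = np.arange(1, int(spec.crown_height_um / s) + 1)
    pos = k.astype(float) * s
    return pos[pos <= spec.crown_height_um - 0.25 * s]


def build_phantom(spec: ToothPhantomSpec, voxel_size_um: float
                  ) -> tuple[Volume, GroundTruth]:
    """Generate the phantom volume and its ground truth.

    The grid places the cervix plane on the bottom (z = 0) face so the
    dentine core never touches free background there, with a margin of
    background above the cusp tip and around the crown.  Material edges are
    anti-aliased over one voxel so interfaces are defined at sub-voxel
    precision.
    """
    vs = float(voxel_size_um)
    margin_px = 8
    H = spec.crown_height_um
    nz = int(np.ceil(H / vs)) + margin_px
    half = int(np.ceil(spec.crown_radius_um / vs)) + margin_px
    n_xy = 2 * half + 1
    if max(nz, n_xy) > 512:
        raise ValueError("phantom exceeds 512^3 voxels at this voxel size; "
                         "increase voxel_size_um or shrink the crown")

    tip_z_um = H  # z position (um) of the cusp tip; cervix at z = 0
    z_um = np.arange(nz) * vs
    d_um = tip_z_um - z_um                      # distance below the tip
    cy = cx = half
    yy, xx = np.mgrid[0:n_xy, 0:n_xy].astype(np.float32)
    r_yx = np.hypot(yy - cy, xx - cx) * vs      # radius map, um

    r_oes_base, r_oes, r_edj = _radius_profiles(spec, d_um)
    inside_crown = d_um >= 0

    w = vs  # anti-aliasing width
    occ_oes = np.zeros((nz, n_xy, n_xy), dtype=np.float32)
    occ_edj = np.zeros_like(occ_oes)
    for k in range(nz):
        if not inside_crown[k]:
            continue
        occ_oes[k] = np.clip(0.5 - (r_yx - r_oes[k]) / w, 0.0, 1.0)
        if r_edj[k] > 0:
            occ_edj[k] = np.clip(0.5 - (r_yx - r_edj[k]) / w, 0.0, 1.0)
    occ_edj = np.minimum(occ_edj, occ_oes)

    bg = MATRIX.density if spec.crypt_matrix else AIR.density
    enamel_w = occ_oes - occ_edj
    dens = (bg * (1.0 - occ_oes)
            + ENAMEL.density * enamel_w
            + DENTINE.density * occ_edj).astype(np.float32)

    # internal long-period lines in the enamel, tilted so the spacing along
    # the growth direction equals dsr x periodicity
    s = spec.retzius_spacing_um
    growth_spacing = spec.dsr_um_per_day * spec.periodicity_days
    ratio = s / max(growth_spacing, 1e-9)
    k_t = np.sqrt(max(ratio * ratio - 1.0, 0.0))
    line_amp = 0.01 * ENAMEL.density
    for k in range(nz):
        if not inside_crown[k]:
            continue
        depth = np.clip(r_oes_base[k] - r_yx, 0.0, None)
        g = d_um[k] + k_t * depth
        dens[k] += (line_amp * np.cos(2 * np.pi * (g - s / 2) / s)
                    * enamel_w[k]).astype(np.float32)

    # accentuated stress lines paired with the hypoplastic grooves: a
    # fractional (density-proportional) drop crossing both tissues, so the
    # enamel-dentine step itself - and hence the fringe contrast at the EDJ -
    # dips by an amount proportional to the groove amplitude
    stress_frac_per_um = 0.03
    tissue = (ENAMEL.density * enamel_w
              + DENTINE.density * occ_edj).astype(np.float32)
    for hf, amp, wdef in spec.defects:
        d0 = hf * H
        band = np.exp(-0.5 * ((d_um - d0) / wdef) ** 2).astype(np.float32)
        dens -= (stress_frac_per_um * amp) * band[:, None, None] * tissue

    # demineralized subsurface layers
    for depth0, half_offset, drop in spec.demineral_layers:
        if drop == 0:
            continue
        modulation = (1.0 - _protection_profile(d_um, spec)
                      if half_offset else np.ones_like(d_um))
        for k in range(nz):
            if not inside_crown[k]:
                continue
            t = r_oes[k] - r_yx  # depth below the (modulated) OES
            layer = (np.clip((t - depth0) / w + 0.5, 0, 1)
                     * np.clip((depth0 + DEMIN_LAYER_THICKNESS_UM - t) / w
                               + 0.5, 0, 1))
            dens[k] -= (drop * ENAMEL.density * modulation[k]
                        * layer * enamel_w[k]).astype(np.float32)

    vol = Volume(dens, voxel_size_um=vs, bit_depth=32)

    tooth = occ_oes > 0.5
    core = occ_edj > 0.5
    oes_mask = tooth & ~ndimage.binary_erosion(tooth)
    # exclude the bottom (cervix) face: it is a grid cut, not anatomy
    oes_mask[0] = False
    edj_mask = core & ~ndimage.binary_erosion(core)
    edj_mask[0] = False

    pos = ridge_positions(spec)
    has_half_offset = any(ho for _, ho, _ in spec.demineral_layers)
    truth = GroundTruth(
        oes_mask=oes_mask,
        edj_mask=edj_mask,
        perikymata_positions_um=pos,
        n_perikymata=len(pos),
        defect_positions_um=np.array([hf * H for hf, _, _ in spec.defects]),
        subdivision_positions_um=(subdivision_positions(spec)
                                  if has_half_offset else np.empty(0)),
        axis_yx_px=(float(cy), float(cx)),
        tip_z_um=tip_z_um,
        crown_height_um=H,
        ridge_spacing_um=s,
    )
    return vol, truth


def _dog_step_peak(sigma1: float, sigma2: float) -> float:
    """Peak magnitude of the band-pass response to a unit step."""
    x = np.linspace(0, 6 * sigma2, 2049)
    f = 0.5 * (erf(x / (np.sqrt(2) * sigma1))
               - erf(x / (np.sqrt(2) * sigma2)))
    return float(np.abs(f).max())


def add_phase_fringes(vol: Volume, fm: FringeModel = FringeModel()) -> Volume:
    """Add propagation phase-contrast double fringes at density steps.

    The fringe field is a band-pass (difference-of-Gaussians) filtered copy
    of the volume, normalized so a unit density step produces a fringe pair
    of peak amplitude ``amplitude_fraction``.  The response to a step is
    antisymmetric about the interface: bright on the denser side, dark on
    the other, zero-crossing exactly on the interface, and exactly
    mean-preserving.  By linearity, amplitudes scale with step heights.
    """
    s1 = fm.width_px / 2.0
    s2 = 2.0 * fm.width_px
    v = np.asarray(vol.voxels, dtype=np.float32)
    band = ndimage.gaussian_filter(v, s1) - ndimage.gaussian_filter(v, s2)
    gain = fm.amplitude_fraction / _dog_step_peak(s1, s2)
    out = v + gain * band
    return replace(vol, voxels=out, origin_um=vol.origin_um.copy())


def degrade_resolution(vol: Volume, target_voxel_um: float) -> Volume:
    """Emulate imaging at a coarser resolution (partial-volume effect).

    Isotropic Gaussian blur with FWHM equal to the target voxel size,
    followed by linear resampling onto the coarser grid.
    """
    if target_voxel_um <= vol.voxel_size_um:
        raise ValueError("target voxel size must exceed the source's")
    fwhm_px = target_voxel_um / vol.voxel_size_um
    sigma = fwhm_px / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    blurred = ndimage.gaussian_filter(
        np.asarray(vol.voxels, dtype=np.float32), sigma)
    zoom = vol.voxel_size_um / target_voxel_um
    resampled = ndimage.zoom(blurred, zoom, order=1, grid_mode=True,
                             mode="nearest")
    return replace(vol, voxels=resampled, voxel_size_um=float(target_voxel_um),
                   origin_um=vol.origin_um.copy())


def add_noise(vol: Volume, sigma: float, seed: int) -> Volume:
    """Additive Gaussian noise, reproducible under a fixed seed."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return vol.copy()
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=vol.shape).astype(np.float32)
    return replace(vol, voxels=np.asarray(vol.voxels, dtype=np.float32) + noise,
                   origin_um=vol.origin_um.copy())
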