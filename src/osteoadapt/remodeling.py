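"""Mechanostat-driven evolution of tissue mineral density (TMD).

The remodeling law is Frost's mechanostat in its linear, lazy-zone-free
form.  For every voxel carrying a mechanical stimulus U (strain energy
density, Pa) the tissue mineral density changes over one time step
(2 weeks, one scan interval) by

    dTMD = tau_a * (U - U_thr)   if U >= U_thr   (apposition)
    dTMD = -tau_r * (U_thr - U)  if U <  U_thr   (resorption)

with apposition rate ``tau_a`` and resorption rate ``tau_r`` in
mg/cc per Pa per 2 weeks and the setpoint ``U_thr`` in Pa.  The response is
continuous and piecewise linear in U, zero exactly at the setpoint.

The stimulus is defined on bone voxels (their element SED) and on background
voxels face-adjacent to the periosteal or endosteal surface, which take the
mean SED of their face-adjacent bone voxels — this one-voxel apposition front
is how new bone can form outside the current surface.  Updated TMD is
converted back to gray values to emit a pseudo micro-CT follow-up image; a
voxel whose gray value crosses the global segmentation threshold changes
bone/background status at the next iteration's binarization (no element
deletion mid-step).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import GrayImage
from .imageproc import (
    BinaryMask,
    SurfaceLabels,
    binarize,
    find_surfaces,
    select_global_threshold,
)
from .microfe import LoadCase, Material, SEDField, build_problem, element_sed, solve

__all__ = [
    "RemodelingParams",
    "Calibration",
    "VoxelSEDMap",
    "gray_to_tmd",
    "tmd_to_gray",
    "voxel_sed_map",
    "apply_mechanostat",
    "step",
    "StepInfo",
]

_FACE3D = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class RemodelingParams:
    """The three mechanoregulation parameters.

    apposition_rate, resorption_rate: mg/cc per Pa per 2-week step;
    sed_threshold: Pa.
    """

    apposition_rate: float
    resorption_rate: float
    sed_threshold: float

    def __post_init__(self) -> None:
        if self.apposition_rate < 0:
            raise ValueError("apposition_rate must be >= 0")
        if self.resorption_rate < 0:
            raise ValueError("resorption_rate must be >= 0")
        if self.sed_threshold < 0:
            raise ValueError("sed_threshold must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.apposition_rate, self.resorption_rate, self.sed_threshold])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "RemodelingParams":
        return cls(float(x[0]), float(x[1]), float(x[2]))


@dataclass(frozen=True)
class Calibration:
    """Linear gray-value to TMD calibration: TMD = slope * GV + intercept.

    ``tmd_max`` is the densitometric ceiling of the calibration wedge
    (default 1200 mgHA/cc); TMD values are clamped to [0, tmd_max].
    """

    slope: float = 4.0  # mgHA/cc per gray value
    intercept: float = -160.0  # mgHA/cc
    tmd_max: float = 1200.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be non-zero")
        if not self.tmd_max > 0:
            raise ValueError("tmd_max must be positive")

    @property
    def gray_max(self) -> float:
        """Gray value corresponding to tmd_max."""
        return (self.tmd_max - self.intercept) / self.slope


def gray_to_tmd(image: GrayImage | np.ndarray, calib: Calibration) -> np.ndarray:
    """TMD volume (mgHA/cc) from gray values, clamped to [0, tmd_max]."""
    gv = image.values if isinstance(image, GrayImage) else np.asarray(image, dtype=float)
    return np.clip(calib.slope * gv + calib.intercept, 0.0, calib.tmd_max)


def tmd_to_gray(tmd: np.ndarray, calib: Calibration, spacing: float = 10.4) -> GrayImage:
    """Inverse calibration on the unclamped range: GV = (TMD - b) / a."""
    gv = (np.asarray(tmd, dtype=float) - calib.intercept) / calib.slope
    return GrayImage(values=gv, spacing=spacing)


@dataclass(frozen=True)
class VoxelSEDMap:
    """Per-voxel stimulus (Pa) on bone voxels plus the one-voxel background
    rim adjacent to the periosteal/endosteal surfaces."""

    values: np.ndarray  # (nz, ny, nx), Pa; meaningful only on `support`
    support: np.ndarray  # bool


def voxel_sed_map(sed: SEDField, surfaces: SurfaceLabels) -> VoxelSEDMap:
    """Extend the element SED field onto the surface-adjacent background.

    Bone voxels take their own element SED.  Each background voxel with at
    least one face-adjacent bone voxel takes the mean SED of those neighbors;
    enclosed background with no bone neighbor carries no stimulus.
    """
    if sed.mask_shape != surfaces.labels.shape:
        raise ValueError("SED field and surface labels are on different grids")
    bone = sed.support
    vol = sed.as_volume(fill=0.0)

    neighbor_sum = np.zeros_like(vol)
    neighbor_cnt = np.zeros(vol.shape, dtype=np.int32)
    for ax in range(3):
        for sh in (1, -1):
            neighbor_sum += np.roll(vol, sh, axis=ax) * _shifted(bone, sh, ax)
            neighbor_cnt += _shifted(bone, sh, ax)
    bg_support = ~bone & (neighbor_cnt > 0)
    values = vol.copy()
    values[bg_support] = neighbor_sum[bg_support] / neighbor_cnt[bg_support]
    return VoxelSEDMap(values=values, support=bone | bg_support)


def _shifted(mask: np.ndarray, shift: int, axis: int) -> np.ndarray:
    """Mask shifted by one voxel with zero fill (no wrap-around)."""
    out = np.roll(mask, shift, axis=axis)
    idx = [slice(None)] * mask.ndim
    idx[axis] = 0 if shift == 1 else -1
    out[tuple(idx)] = False
    return out


def mechanostat_delta(u: np.ndarray, params: RemodelingParams) -> np.ndarray:
    """dTMD (mg/cc per step) of the linear lazy-zone-free mechanostat."""
    du = np.asarray(u, dtype=float) - params.sed_threshold
    return np.where(du >= 0, params.apposition_rate * du, params.resorption_rate * du)


def apply_mechanostat(
    tmd: np.ndarray,
    sedmap: VoxelSEDMap,
    params: RemodelingParams,
    calib: Calibration,
    smooth_box: int | None = None,
) -> np.ndarray:
    """One mechanostat update of the TMD volume.

    Applies dTMD on the stimulus support (all bone voxels and the
    surface-adjacent background rim) and clamps to [0, tmd_max].
    ``smooth_box`` optionally box-averages the stimulus over a cubic
    neighborhood of that many voxels per side before applying the law
    (off by default).
    """
    u = sedmap.values
    if smooth_box is not None and smooth_box > 1:
        u = ndimage.uniform_filter(u, size=smooth_box, mode="nearest")
    delta = mechanostat_delta(u, params)
    out = np.array(tmd, dtype=float, copy=True)
    out[sedmap.support] = np.clip(
        out[sedmap.support] + delta[sedmap.support], 0.0, calib.tmd_max
    )
    return out


@dataclass(frozen=True)
class StepInfo:
    """Diagnostics of one forward remodeling step."""

    threshold: float
    mask: BinaryMask
    surfaces: SurfaceLabels
    sed: SEDField
    sedmap: VoxelSEDMap
    solver_residual: float
    solver_iterations: int


def step(
    image: GrayImage,
    params: RemodelingParams,
    load: LoadCase,
    calib: Calibration,
    material: Material | None = None,
    threshold: float | None = None,
    smooth_box: int | None = None,
    sedmap: VoxelSEDMap | None = None,
    return_info: bool = False,
) -> GrayImage | tuple[GrayImage, StepInfo]:
    """One 2-week forward step: image -> pseudo micro-CT follow-up.

    Pipeline: global threshold -> binarize -> surface labels -> micro-FE
    solve -> voxel stimulus map -> mechanostat TMD update -> recalibrated
    pseudo-CT.  A precomputed ``sedmap`` (from an identical baseline, load
    and material) short-circuits the FE stages; this is exploited by the
    parameter fit, whose objective re-evaluates the mechanostat only.
    """
    material = material or Material()
    if threshold is None:
        threshold = select_global_threshold(image)
    mask = binarize(image, threshold)
    surfaces = find_surfaces(mask)
    if sedmap is None:
        try:
            problem = build_problem(mask, material, load)
            solution = solve(problem)
        except Exception as exc:  # add stage context
            raise RuntimeError(f"micro-FE stage failed: {exc}") from exc
        sed = element_sed(problem, solution)
        sedmap = voxel_sed_map(sed, surfaces)
        residual, iters = solution.residual, solution.iterations
    else:
        sed, residual, iters = None, float("nan"), 0

    tmd = gray_to_tmd(image, calib)
    tmd_new = apply_mechanostat(tmd, sedmap, params, calib, smooth_box=smooth_box)
    out = tmd_to_gray(tmd_new, calib, spacing=image.spacing)
    if not return_info:
        return out
    info = StepInfo(
        threshold=threshold,
        mask=mask,
        surfaces=surfaces,
        sed=sed,
        sedmap=sedmap,
        solver_residual=residual,
        solver_iterations=iters,
    )
    return out, info
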