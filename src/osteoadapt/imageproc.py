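"""Segmentation, cropping, alignment and surface labeling of gray-value volumes.

Cortical bone in a calibrated micro-CT volume separates from background as the
upper mode of a bimodal gray-value histogram.  Segmentation uses a single
global threshold placed midway between the two histogram peaks; the binarized
volume then supports surface extraction (periosteal = outer outline,
endosteal = medullary-facing outline), total-volume filling, and integer-voxel
centroid superposition of longitudinal scan pairs.

Connectivity conventions: cavity/exterior determination uses 4-connectivity
within each 2D slice (the outlines are per-slice curves); surface detection
uses face (6-) adjacency in 3D.  A bone voxel adjacent to both the exterior
and the medullary cavity is labeled periosteal — a deterministic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .image import GrayImage

__all__ = [
    "BinaryMask",
    "SurfaceLabels",
    "SurfaceClass",
    "select_global_threshold",
    "binarize",
    "crop_to_length",
    "align_by_centroid",
    "find_surfaces",
    "fill_periosteal",
]

# 6-connected (face) structuring element in 3D
_FACE3D = ndimage.generate_binary_structure(3, 1)
# 4-connected structuring element in 2D
_FACE2D = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class BinaryMask:
    """Bone segmentation on the grid of its source image (1 = bone)."""

    values: np.ndarray
    spacing: float = 10.4

    def __post_init__(self) -> None:
        v = np.asarray(self.values).astype(bool)
        if v.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={v.ndim}")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3 (spacing is in um)."""
        return float((self.spacing * 1e-3) ** 3)


class SurfaceClass(IntEnum):
    """Per-voxel surface label codes."""

    NON_SURFACE = 0  # background
    INTERIOR = 1  # bone, not on a surface
    PERIOSTEAL = 2  # bone facing the exterior
    ENDOSTEAL = 3  # bone facing the medullary cavity


@dataclass(frozen=True)
class SurfaceLabels:
    """Per-voxel surface classification of a binary mask.

    ``labels`` holds :class:`SurfaceClass` codes; ``exterior`` and
    ``medullary`` are the background partitions used to derive them (exposed
    because the remodeling stimulus map needs the medullary cavity).
    """

    labels: np.ndarray
    exterior: np.ndarray
    medullary: np.ndarray
    spacing: float = 10.4

    @property
    def periosteal(self) -> np.ndarray:
        return self.labels == SurfaceClass.PERIOSTEAL

    @property
    def endosteal(self) -> np.ndarray:
        return self.labels == SurfaceClass.ENDOSTEAL

    @property
    def surface(self) -> np.ndarray:
        return self.periosteal | self.endosteal


def _histogram(values: np.ndarray, smooth_window: int) -> tuple[np.ndarray, np.ndarray]:
    """Histogram with unit bins for near-integer data, else 256 bins; smoothed
    by a centered moving average."""
    flat = values.ravel()
    lo, hi = float(flat.min()), float(flat.max())
    if np.allclose(flat, np.round(flat)) and hi - lo < 4096:
        edges = np.arange(np.floor(lo) - 0.5, np.ceil(hi) + 1.5)
    else:
        edges = np.linspace(lo, hi, 257)
    counts, edges = np.histogram(flat, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        counts = np.convolve(counts.astype(float), kernel, mode="same")
    return counts.astype(float), centers


def select_global_threshold(image: GrayImage, smooth_window: int = 5) -> float:
    """Global segmentation threshold: midpoint of the two histogram peaks.

    The gray-value histogram of a cortical-bone scan is bimodal (background
    and bone modes); the threshold is placed equidistant between the two peak
    locations.  Peaks are detected on a moving-average-smoothed histogram
    (window ``smooth_window`` bins) as the two most prominent local maxima.

    Raises
    ------
    ValueError
        If fewer than two peaks are found (unimodal histogram).  Supply an
        explicit threshold to :func:`binarize` in that case.
    """
    counts, centers = _histogram(image.values, smooth_window)
    # pad so peaks at the histogram ends are detectable
    padded = np.concatenate([[0.0], counts, [0.0]])
    idx, props = find_peaks(padded, prominence=0.0)
    idx -= 1
    if len(idx) < 2:
        raise ValueError(
            "gray-value histogram is not bimodal; pass an explicit threshold "
            "to binarize() instead"
        )
    order = np.argsort(props["prominences"])[::-1]
    top2 = np.sort(idx[order[:2]])
    return float(0.5 * (centers[top2[0]] + centers[top2[1]]))


def binarize(image: GrayImage, threshold: float) -> BinaryMask:
    """Binarize at ``threshold``: bone where gray value >= threshold."""
    return BinaryMask(values=image.values >= threshold, spacing=image.spacing)


def crop_to_length(image: GrayImage, reference_slice: int, fraction: float) -> GrayImage:
    """Crop to ``fraction`` of the volume length, distal of ``reference_slice``.

    ``reference_slice`` is the most proximal slice retained (in the tibia,
    the slice below the proximal growth plate).  ``floor(fraction * n_slices)``
    slices are kept, extending from the reference toward the distal end
    (decreasing slice index); slice 0 of the output is still the most distal.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    nz = image.n_slices
    if not 0 <= reference_slice < nz:
        raise ValueError(f"reference_slice {reference_slice} outside [0, {nz})")
    n_keep = int(np.floor(fraction * nz))
    start = reference_slice - n_keep + 1
    if start < 0:
        raise ValueError(
            f"crop of {n_keep} slices extends below slice 0 from reference "
            f"{reference_slice}"
        )
    if n_keep < 10:
        raise ValueError(
            f"cropped length {n_keep} < 10 slices; cannot form 10 sections"
        )
    return image.with_values(image.values[start : reference_slice + 1])


def _centroid(mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        raise ValueError("empty mask has no centroid")
    return np.asarray(ndimage.center_of_mass(mask), dtype=float)


def align_by_centroid(
    reference: BinaryMask,
    moving_image: GrayImage,
    moving_mask: BinaryMask,
    reference_image: GrayImage | None = None,
) -> tuple[GrayImage, BinaryMask, tuple[int, int, int], slice]:
    """Superimpose two scans by aligning bone-mask volumetric centroids.

    The moving volume is translated by the integer voxel shift (rounded to
    nearest) that equalizes the two centroids; no interpolation is performed
    so voxelwise comparisons stay exact.  Both volumes must then be restricted
    to their overlapping extent: the returned ``slice`` is the z-crop to apply
    to the reference-side volumes, and the returned image/mask are the
    translated and cropped moving volumes.

    Returns
    -------
    (moving_image_aligned, moving_mask_aligned, shift_zyx, reference_z_slice)
    """
    if not reference.values.any() or not moving_mask.values.any():
        raise ValueError("centroid alignment requires non-empty masks")
    shift = _centroid(reference.values) - _centroid(moving_mask.values)
    shift_int = tuple(int(s) for s in np.round(shift))

    mv = moving_image.values
    mm = moving_mask.values
    shape = reference.values.shape
    if mv.shape != mm.shape:
        raise ValueError("moving image and mask grids differ")

    # overlap box of the shifted moving grid with the reference grid
    out_img = []
    src: list[slice] = []
    dst: list[slice] = []
    for ax, s in enumerate(shift_int):
        n_ref, n_mov = shape[ax], mv.shape[ax]
        d0 = max(0, s)
        d1 = min(n_ref, n_mov + s)
        if d1 <= d0:
            raise ValueError("no overlap between volumes after alignment")
        dst.append(slice(d0, d1))
        src.append(slice(d0 - s, d1 - s))
    img_al = mv[tuple(src)]
    mask_al = mm[tuple(src)]
    ref_z = dst[0]
    # in-plane extents must already agree for voxelwise comparison
    return (
        GrayImage(values=img_al, spacing=moving_image.spacing),
        BinaryMask(values=mask_al, spacing=moving_mask.spacing),
        shift_int,
        ref_z,
    )


def _exterior_and_medullary(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partition background into exterior (4-connected to the slice border,
    per slice) and enclosed medullary background."""
    bg = ~mask
    exterior = np.zeros_like(bg)
    border = np.zeros(mask.shape[1:], dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    for z in range(mask.shape[0]):
        seed = bg[z] & border
        exterior[z] = ndimage.binary_propagation(seed, mask=bg[z], structure=_FACE2D)
    medullary = bg & ~exterior
    return exterior, medullary


def find_surfaces(mask: BinaryMask) -> SurfaceLabels:
    """Label periosteal and endosteal surface voxels of a bone mask.

    Periosteal voxels are bone voxels with a face neighbor in the exterior
    background; endosteal voxels face the enclosed medullary cavity.  Voxels
    adjacent to both are labeled periosteal.
    """
    if not mask.values.any():
        raise ValueError("cannot label surfaces of an empty mask")
    bone = mask.values
    exterior, medullary = _exterior_and_medullary(bone)
    near_ext = ndimage.binary_dilation(exterior, structure=_FACE3D)
    near_med = ndimage.binary_dilation(medullary, structure=_FACE3D)
    labels = np.zeros(bone.shape, dtype=np.uint8)
    labels[bone] = SurfaceClass.INTERIOR
    labels[bone & near_med] = SurfaceClass.ENDOSTEAL
    labels[bone & near_ext] = SurfaceClass.PERIOSTEAL  # tie-break: periosteal wins
    return SurfaceLabels(labels=labels, exterior=exterior, medullary=medullary, spacing=mask.spacing)


def fill_periosteal(mask: BinaryMask) -> BinaryMask:
    """Total-volume mask: per slice, fill everything enclosed by the
    periosteal outline (bone plus medullary cavity)."""
    if not mask.values.any():
        return mask
    _, medullary = _exterior_and_medullary(mask.values)
    return BinaryMask(values=mask.values | medullary, spacing=mask.spacing)
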