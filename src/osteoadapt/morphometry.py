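"""Densitometric and geometric morphometry of cortical bone volumes.

Quantities follow standard micro-CT bone morphometry: bone volume BV (mm^3),
total volume TV (volume enclosed by the periosteal surface, mm^3), bone
volume fraction BV/TV, bone mineral content BMC (sum of TMD times voxel
volume, mgHA), and volumetric bone mineral density BMD = BMC/TV (mgHA/cc).
All are reported whole-bone and per 10 contiguous longitudinal sections
numbered 1 (distal) to 10 (proximal).

The volumetric second moments I_ML and I_AP are voxel-volume-weighted planar
second moments of the bone cross-section about each section's centroidal
axes (area moment integrated over the section length; units mm^5), a proxy
for bending resistance in the medial-lateral and anterior-posterior
directions.  Voxel coordinates are taken at voxel centers, consistent with
phantom membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image import GrayImage
from .imageproc import BinaryMask, fill_periosteal
from .remodeling import Calibration, gray_to_tmd

__all__ = [
    "SectionPartition",
    "make_partition",
    "densitometrics",
    "second_moments",
]


@dataclass(frozen=True)
class SectionPartition:
    """10 (or n) contiguous near-equal z-ranges, section 1 most distal.

    ``bounds[i]`` is the first slice of section i+1; section i+1 covers
    slices [bounds[i], bounds[i+1]).
    """

    bounds: tuple[int, ...]

    @property
    def n_sections(self) -> int:
        return len(self.bounds) - 1

    @property
    def n_slices(self) -> int:
        return self.bounds[-1]

    def section_slices(self, section: int) -> slice:
        """Slice range of 1-based section number."""
        if not 1 <= section <= self.n_sections:
            raise ValueError(f"section {section} outside 1..{self.n_sections}")
        return slice(self.bounds[section - 1], self.bounds[section])

    def __iter__(self):
        for s in range(1, self.n_sections + 1):
            yield s, self.section_slices(s)


def make_partition(n_slices: int, n_sections: int = 10) -> SectionPartition:
    """Partition ``n_slices`` into contiguous near-equal sections.

    Remainder slices are assigned to the most distal sections, so section
    lengths differ by at most one slice and are non-increasing from distal
    to proximal.
    """
    if n_slices < n_sections:
        raise ValueError(f"{n_slices} slices cannot form {n_sections} sections")
    base, rem = divmod(n_slices, n_sections)
    lengths = [base + (1 if i < rem else 0) for i in range(n_sections)]
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    return SectionPartition(bounds=tuple(int(b) for b in bounds))


def densitometrics(
    image: GrayImage,
    mask: BinaryMask,
    calib: Calibration,
    partition: SectionPartition | None = None,
) -> pd.DataFrame:
    """Densitometric summary per region.

    Returns a DataFrame indexed by region ("whole", then section numbers)
    with columns BV, TV (mm^3), BVTV, BMC (mgHA), BMD (mgHA/cc).  Regions
    with TV = 0 carry NaN ratios (flagged as undefined, never 0).
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask grids differ")
    vvox = mask.voxel_volume_mm3  # mm^3
    tmd = gray_to_tmd(image, calib)
    total = fill_periosteal(mask)

    bone_per_slice = mask.values.sum(axis=(1, 2)).astype(float)
    tv_per_slice = total.values.sum(axis=(1, 2)).astype(float)
    bmc_per_slice = (tmd * mask.values).sum(axis=(1, 2))  # mgHA/cc * voxel

    def _row(zs: slice) -> dict:
        bv = bone_per_slice[zs].sum() * vvox
        tv = tv_per_slice[zs].sum() * vvox
        bmc = bmc_per_slice[zs].sum() * vvox * 1e-3  # mm^3 * mgHA/cc -> mgHA
        return {
            "BV": bv,
            "TV": tv,
            "BVTV": bv / tv if tv > 0 else np.nan,
            "BMC": bmc,
            "BMD": bmc / (tv * 1e-3) if tv > 0 else np.nan,  # mgHA / cc
        }

    rows = {"whole": _row(slice(None))}
    if partition is not None:
        if partition.n_slices != mask.values.shape[0]:
            raise ValueError("partition does not cover the volume")
        for s, zs in partition:
            rows[s] = _row(zs)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "region"
    return df


def second_moments(
    mask: BinaryMask, partition: SectionPartition, allow_empty: bool = False
) -> pd.DataFrame:
    """Volumetric second moments per section (mm^5).

    I_ML(s) = sum_v V_vox (x_v - xbar_s)^2, I_AP(s) = sum_v V_vox
    (y_v - ybar_s)^2, with the centroid taken per section and coordinates at
    voxel centers.  Raises if a section contains no bone voxel, unless
    ``allow_empty`` is set, in which case an empty section reports zero
    moments (no bone, no bending resistance) — used inside the fit objective
    where extreme trial parameters may resorb whole sections.
    """
    if partition.n_slices != mask.values.shape[0]:
        raise ValueError("partition does not cover the volume")
    h_mm = mask.spacing * 1e-3
    vvox = mask.voxel_volume_mm3
    out = {}
    for s, zs in partition:
        sub = mask.values[zs]
        if not sub.any():
            if allow_empty:
                out[s] = {"I_ML": 0.0, "I_AP": 0.0}
                continue
            raise ValueError(f"section {s} contains no bone voxels")
        zz, yy, xx = np.nonzero(sub)
        x = (xx + 0.5) * h_mm
        y = (yy + 0.5) * h_mm
        i_ml = vvox * np.sum((x - x.mean()) ** 2)
        i_ap = vvox * np.sum((y - y.mean()) ** 2)
        out[s] = {"I_ML": i_ml, "I_AP": i_ap}
    df = pd.DataFrame.from_dict(out, orient="index")
    df.index.name = "section"
    return df
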