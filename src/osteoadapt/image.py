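"""Gray-value volume container and file I/O.

The common currency between phantom generation, image processing, remodeling
and morphometry is a 3D scalar volume with isotropic voxel spacing.  The axis
convention is fixed throughout the package:

* axis 0 — ``z``, longitudinal, slice 0 is the most **distal** slice,
* axis 1 — ``y``, anterior–posterior (AP),
* axis 2 — ``x``, medial–lateral (ML).

All indices are 0-based.  Voxel centers sit at ``(i + 0.5) * spacing`` along
each axis, which keeps voxel-membership and centroid computations exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GrayImage", "read_image", "write_image"]


@dataclass(frozen=True)
class GrayImage:
    """A 3D gray-value volume with isotropic spacing.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Gray values (arbitrary scanner units, calibrated to TMD elsewhere).
    spacing : float
        Isotropic voxel edge length in micrometres (default 10.4).
    """

    values: np.ndarray
    spacing: float = 10.4

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={v.ndim}")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray) -> "GrayImage":
        """Return a new image on the same grid with different values."""
        return GrayImage(values=values, spacing=self.spacing)

    def same_grid(self, other: "GrayImage") -> bool:
        return self.shape == other.shape and np.isclose(self.spacing, other.spacing)


def write_image(image: GrayImage | np.ndarray, path: str | Path, spacing: float | None = None) -> None:
    """Write a volume as MetaImage (.mha/.mhd), NIfTI (.nii/.nii.gz) or TIFF stack.

    Spacing is stored in millimetres in the image header (the ITK convention);
    TIFF stacks carry no spacing and rely on the JSON sidecars written by the
    pipeline.
    """
    path = Path(path)
    if isinstance(image, GrayImage):
        arr, sp = image.values, image.spacing
    else:
        arr, sp = np.asarray(image), (spacing if spacing is not None else 10.4)
    suffixes = "".join(path.suffixes)
    if path.suffix in {".mha", ".mhd", ".nii"} or suffixes.endswith(".nii.gz"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(arr, dtype=np.float32))
        img.SetSpacing((sp * 1e-3,) * 3)  # um -> mm
        sitk.WriteImage(img, str(path))
    elif path.suffix in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(
            str(path), np.asarray(arr, dtype=np.float32), photometric="minisblack"
        )
    else:
        raise ValueError(f"unsupported image format: {path.name}")


def read_image(path: str | Path, spacing: float | None = None) -> GrayImage:
    """Read a volume written by :func:`write_image`."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if path.suffix in {".mha", ".mhd", ".nii"} or suffixes.endswith(".nii.gz"):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)
        sp = img.GetSpacing()[0] * 1e3 if spacing is None else spacing
        return GrayImage(values=np.asarray(arr, dtype=np.float64), spacing=float(sp))
    if path.suffix in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(str(path))
        return GrayImage(values=np.asarray(arr, dtype=np.float64), spacing=spacing or 10.4)
    raise ValueError(f"unsupported image format: {path.name}")
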