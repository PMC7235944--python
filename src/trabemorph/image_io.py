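"""Reading, writing and cropping 3D voxel volumes.

The canonical in-memory representation is :class:`VoxelImage`: a 3D array
indexed ``(z, y, x)`` with a single isotropic voxel size in millimetres.
Micro-CT morphometry assumes isotropic voxels throughout, so anisotropic
spacing found in file metadata is rejected rather than silently resampled.

Supported on-disk formats are multi-page TIFF (ImageJ-style metadata carries
the spacing), MetaImage MHD+RAW, and NIfTI (``.nii``/``.nii.gz``).  Binary
masks are stored as 8-bit 0/255 and normalised to 0/1 in memory; on read,
values strictly greater than half the on-disk foreground value map to 1,
which guards against lossy intermediate formats.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .errors import BoundsError, FormatError, PreconditionError, UnsupportedGeometryError

__all__ = ["VoxelImage", "read_volume", "write_volume", "crop_roi"]

_ISO_RTOL = 1e-6


@dataclasses.dataclass
class VoxelImage:
    """A 3D scalar volume with isotropic voxel size.

    Parameters
    ----------
    data:
        3D array indexed ``(z, y, x)``.
    voxel_size:
        Isotropic voxel side length in mm; must be positive.
    is_binary:
        If true, every value must be exactly 0 (background) or 1 (bone).
    origin:
        Physical position of voxel (0, 0, 0) in mm, default zeros.
    flags:
        Advisory markers set by pipeline stages, e.g. ``"degenerate_mask"``.
    """

    data: np.ndarray
    voxel_size: float
    is_binary: bool = False
    origin: np.ndarray = None  # type: ignore[assignment]
    flags: tuple = ()

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise PreconditionError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise PreconditionError(f"all dimensions must be >= 1, got {self.data.shape}")
        if not (self.voxel_size > 0):
            raise PreconditionError(f"voxel_size must be > 0 mm, got {self.voxel_size}")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.is_binary:
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise PreconditionError("binary volume must contain only 0 and 1")
            self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def total_volume(self) -> float:
        """ROI volume in mm^3 (the cubical ROI is the total volume TV)."""
        return float(self.data.size) * self.voxel_size**3

    def foreground_mask(self) -> np.ndarray:
        if not self.is_binary:
            raise PreconditionError("foreground_mask requires a binary volume")
        return self.data.astype(bool)

    def complement(self) -> "VoxelImage":
        """Swap foreground and background (used for Tb.Sp. via Tb.Th.)."""
        if not self.is_binary:
            raise PreconditionError("complement requires a binary volume")
        return VoxelImage(1 - self.data, self.voxel_size, is_binary=True, origin=self.origin)


def _check_isotropic(spacing, path) -> float:
    spacing = np.asarray(spacing, dtype=float)
    if not np.allclose(spacing, spacing[0], rtol=_ISO_RTOL, atol=0.0):
        raise UnsupportedGeometryError(
            f"{path}: anisotropic voxel spacing {tuple(spacing)}; "
            "this toolkit assumes isotropic voxels — resample first or pass voxel_size"
        )
    return float(spacing[0])


def _normalise_binary(arr: np.ndarray, binary) -> tuple:
    """Map an on-disk mask to exact 0/1. ``binary=None`` auto-detects (<=2 levels)."""
    vals = np.unique(arr)
    if binary is None:
        # Auto-detection: integer data with at most two grey levels, lower one 0.
        # Float volumes (e.g. thickness maps) are never auto-binarised.
        binary = arr.dtype.kind in "uib" and len(vals) <= 2 and vals.min() == 0
    if binary:
        fg = float(vals.max())
        if fg <= 0:
            return np.zeros_like(arr, dtype=np.uint8), True
        return (arr > fg / 2).astype(np.uint8), True
    return arr, False


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "tiff_stack"
    name = path.name.lower()
    if name.endswith((".tif", ".tiff")):
        return "tiff_stack"
    if name.endswith(".mhd"):
        return "mhd"
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    raise FormatError(f"cannot infer volume format from {path}")


def read_volume(path, format: str = "auto", voxel_size: float | None = None,
                binary: bool | None = None) -> VoxelImage:
    """Read a 3D volume from disk into the canonical (z, y, x) layout.

    ``voxel_size`` overrides (or supplies, for spacing-less TIFFs) the voxel
    size in mm.  ``binary=None`` auto-detects two-level masks.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "auto":
        format = _infer_format(path)

    if format == "tiff_stack":
        arr, spacing = _read_tiff(path)
    elif format == "mhd":
        arr, spacing = _read_mhd(path)
    elif format == "nifti":
        arr, spacing = _read_nifti(path)
    else:
        raise FormatError(f"unknown format {format!r}")

    if voxel_size is not None:
        h = float(voxel_size)
    elif spacing is not None:
        h = _check_isotropic(spacing, path)
    else:
        raise FormatError(
            f"{path}: no voxel spacing in file metadata; pass voxel_size explicitly"
        )
    arr, is_binary = _normalise_binary(arr, binary)
    return VoxelImage(arr, h, is_binary=is_binary)


def write_volume(img: VoxelImage, path, format: str = "auto") -> Path:
    """Write a volume; binary masks go to disk as 0/255 uint8."""
    path = Path(path)
    if format == "auto":
        format = _infer_format(path)
    if img.is_binary:
        arr = (img.data.astype(np.uint8)) * 255
    else:
        arr = img.data
        if arr.dtype.kind == "f":
            arr = arr.astype(np.float32)
    if format == "tiff_stack":
        _write_tiff(arr, img.voxel_size, path)
    elif format == "mhd":
        _write_mhd(arr, img.voxel_size, path)
    elif format == "nifti":
        _write_nifti(arr, img.voxel_size, path)
    else:
        raise FormatError(f"unknown format {format!r}")
    return path


# ---------------------------------------------------------------- TIFF

def _read_tiff(path: Path):
    import tifffile

    if path.is_dir():
        slices = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not slices:
            raise FormatError(f"{path}: directory contains no TIFF slices")
        arr = np.stack([tifffile.imread(s) for s in slices], axis=0)
        return arr, None
    try:
        with tifffile.TiffFile(str(path)) as tf:
            arr = tf.asarray()
            spacing = None
            ij = tf.imagej_metadata
            if ij is not None and "spacing" in ij:
                dz = float(ij["spacing"])
                page = tf.pages[0]
                if "XResolution" in page.tags:
                    num, den = page.tags["XResolution"].value
                    dx = den / num
                else:
                    dx = dz
                if "YResolution" in page.tags:
                    num, den = page.tags["YResolution"].value
                    dy = den / num
                else:
                    dy = dz
                spacing = (dx, dy, dz)
    except Exception as exc:  # pragma: no cover - corrupt-file path
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path}: unreadable TIFF ({exc})") from exc
    if arr.ndim == 2:
        arr = arr[None]
    return arr, spacing


def _write_tiff(arr: np.ndarray, h: float, path: Path) -> None:
    import tifffile

    tifffile.imwrite(
        str(path),
        arr,
        imagej=True,
        resolution=(1.0 / h, 1.0 / h),
        metadata={"spacing": h, "unit": "mm", "axes": "ZYX"},
    )


# ---------------------------------------------------------------- MetaImage

def _read_mhd(path: Path):
    import SimpleITK as sitk

    try:
        im = sitk.ReadImage(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: unreadable MetaImage ({exc})") from exc
    arr = sitk.GetArrayFromImage(im)  # (z, y, x)
    return arr, im.GetSpacing()


def _write_mhd(arr: np.ndarray, h: float, path: Path) -> None:
    import SimpleITK as sitk

    im = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    im.SetSpacing((h, h, h))
    sitk.WriteImage(im, str(path))


# ---------------------------------------------------------------- NIfTI

def _read_nifti(path: Path):
    import nibabel as nib

    try:
        im = nib.load(str(path))
        arr = np.asanyarray(im.dataobj)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable NIfTI ({exc})") from exc
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected 3D NIfTI, got shape {arr.shape}")
    zooms = im.header.get_zooms()[:3]  # (x, y, z)
    return arr.transpose(2, 1, 0), (zooms[0], zooms[1], zooms[2])


def _write_nifti(arr: np.ndarray, h: float, path: Path) -> None:
    import nibabel as nib

    affine = np.diag([h, h, h, 1.0])
    nib.save(nib.Nifti1Image(np.ascontiguousarray(arr.transpose(2, 1, 0)), affine), str(path))


# ---------------------------------------------------------------- cropping

def crop_roi(img: VoxelImage, corner, shape) -> VoxelImage:
    """Extract a sub-volume of exactly ``shape`` voxels starting at ``corner``.

    ``corner``/``shape`` are (z, y, x) integer triples; voxel size is preserved.
    """
    corner = np.asarray(corner, dtype=int)
    shape = np.asarray(shape, dtype=int)
    if (corner < 0).any():
        raise BoundsError(f"corner must be non-negative, got {tuple(corner)}")
    if (shape < 1).any():
        raise BoundsError(f"shape must be >= 1, got {tuple(shape)}")
    if (corner + shape > np.array(img.shape)).any():
        raise BoundsError(
            f"requested ROI corner={tuple(corner)} shape={tuple(shape)} "
            f"exceeds volume shape {img.shape}"
        )
    sl = tuple(slice(c, c + s) for c, s in zip(corner, shape))
    new_origin = img.origin + corner[::-1] * img.voxel_size  # origin stored (x,y,z)-agnostic: mm offset
    return VoxelImage(img.data[sl].copy(), img.voxel_size, is_binary=img.is_binary,
                      origin=new_origin)
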