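"""Segmentation chain turning a grayscale scan into the binary bone mask.

Pipeline order: Gaussian smoothing -> single-level threshold -> removal of
unconnected foreground -> morphological closing -> opening.  Defaults mirror
typical micro-CT practice: sigma = 1.2 voxels with the kernel truncated at
2*sigma ("support = 2"), a 3x3x3 structuring element for closing/opening,
and 26-connectivity for component removal.

Binary inputs skip the smooth+threshold stage: a segmented mask is already
past that point of the pipeline, which also makes the chain idempotent.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .errors import PreconditionError
from .image_io import VoxelImage

__all__ = ["PreprocessConfig", "segment", "remove_unconnected"]


@dataclasses.dataclass
class PreprocessConfig:
    """Parameters of the segmentation chain.

    gauss_sigma/gauss_support are in voxels; ``gauss_support`` truncates the
    Gaussian kernel at ``support * sigma``.  ``morph_kernel`` is the side of
    the cubic (or, with ``morph_3d=False``, per-slice square) structuring
    element and must be odd.  ``threshold`` is in image grey-level units.
    """

    gauss_sigma: float = 1.2
    gauss_support: float = 2.0
    threshold: float = 0.5
    morph_kernel: int = 3
    keep_largest_component_only: bool = True
    connectivity: int = 26
    morph_3d: bool = True

    def __post_init__(self):
        if not self.gauss_sigma > 0:
            raise PreconditionError("gauss_sigma must be > 0")
        if not self.gauss_support >= 1:
            raise PreconditionError("gauss_support must be >= 1")
        if self.morph_kernel < 1 or self.morph_kernel % 2 == 0:
            raise PreconditionError("morph_kernel must be odd and >= 1")
        if self.connectivity not in (6, 26):
            raise PreconditionError("connectivity must be 6 or 26")


def _label_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    return ndimage.generate_binary_structure(3, 1)


def remove_unconnected(img: VoxelImage, connectivity: int = 26) -> VoxelImage:
    """Keep only the largest foreground connected component.

    Ties between equal-size components are broken in favour of the component
    whose lexicographically smallest (z, y, x) voxel comes first.  An empty
    image is returned unchanged carrying a ``degenerate_mask`` flag.
    """
    if not img.is_binary:
        raise PreconditionError("remove_unconnected requires a binary volume")
    mask = img.foreground_mask()
    if not mask.any():
        warnings.warn("remove_unconnected: empty foreground", stacklevel=2)
        return VoxelImage(img.data.copy(), img.voxel_size, is_binary=True,
                          origin=img.origin, flags=img.flags + ("degenerate_mask",))
    labels, n = ndimage.label(mask, structure=_label_structure(connectivity))
    if n == 1:
        return VoxelImage(mask.astype(np.uint8), img.voxel_size, is_binary=True,
                          origin=img.origin, flags=img.flags)
    flat = labels.ravel()
    sizes = np.bincount(flat)[1:]  # per label 1..n
    best_size = sizes.max()
    candidates = np.flatnonzero(sizes == best_size) + 1
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        # First flat (C-order) occurrence == lexicographically smallest (z,y,x).
        uniq, first = np.unique(flat, return_index=True)
        first_of = dict(zip(uniq.tolist(), first.tolist()))
        keep = min(candidates, key=lambda lab: first_of[lab])
    return VoxelImage((labels == keep).astype(np.uint8), img.voxel_size,
                      is_binary=True, origin=img.origin, flags=img.flags)


def _close_open(mask: np.ndarray, kernel: int, morph_3d: bool) -> np.ndarray:
    """Closing then opening with edge-replicate padding.

    Padding avoids the scipy border convention (outside treated as background)
    eroding foreground that legitimately touches the ROI face.
    """
    if kernel == 1:
        return mask
    pad = kernel // 2
    if morph_3d:
        structure = np.ones((kernel,) * 3, dtype=bool)
        padded = np.pad(mask, pad, mode="edge")
        out = ndimage.binary_opening(ndimage.binary_closing(padded, structure=structure),
                                     structure=structure)
        return out[pad:-pad, pad:-pad, pad:-pad]
    structure = np.ones((1, kernel, kernel), dtype=bool)
    padded = np.pad(mask, ((0, 0), (pad, pad), (pad, pad)), mode="edge")
    out = ndimage.binary_opening(ndimage.binary_closing(padded, structure=structure),
                                 structure=structure)
    return out[:, pad:-pad, pad:-pad]


def segment(img: VoxelImage, cfg: PreprocessConfig | None = None) -> VoxelImage:
    """Run the full segmentation chain and return a binary mask."""
    cfg = cfg or PreprocessConfig()
    if img.is_binary:
        mask = img.data >= cfg.threshold
    else:
        data = img.data.astype(np.float64)
        smoothed = ndimage.gaussian_filter(data, sigma=cfg.gauss_sigma,
                                           truncate=cfg.gauss_support, mode="mirror")
        if cfg.threshold <= smoothed.min() or cfg.threshold > smoothed.max():
            warnings.warn(
                f"threshold {cfg.threshold} outside smoothed image range "
                f"[{smoothed.min():.4g}, {smoothed.max():.4g}]: mask is empty or full",
                stacklevel=2,
            )
        mask = smoothed > cfg.threshold

    out = VoxelImage(mask.astype(np.uint8), img.voxel_size, is_binary=True,
                     origin=img.origin)
    if cfg.keep_largest_component_only and mask.any():
        out = remove_unconnected(out, connectivity=cfg.connectivity)
    cleaned = _close_open(out.foreground_mask(), cfg.morph_kernel, cfg.morph_3d)
    flags = out.flags
    if not cleaned.any():
        warnings.warn("segment: empty mask after pipeline", stacklevel=2)
        if "degenerate_mask" not in flags:
            flags = flags + ("degenerate_mask",)
    return VoxelImage(cleaned.astype(np.uint8), img.voxel_size, is_binary=True,
                      origin=img.origin, flags=flags)
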