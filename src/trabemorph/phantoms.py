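"""Binary test volumes with analytically known morphometry.

These phantoms stand in for real trabecular-bone scans: plates (parallel
slabs), rod arrays (parallel cylinders on a square lattice), spheres, solid
cubes, and an isotropic foam (thresholded Gaussian random field).  Each
generator returns the volume together with a :class:`GroundTruth` record
holding the closed-form values the geometry implies, so morphometry
algorithms can be validated without any external data.

Default extent is 128^3 voxels at 0.018 mm, echoing typical distal-radius
micro-CT resolution at a desk-scale volume.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .image_io import VoxelImage

__all__ = [
    "GroundTruth", "PhantomSpec", "make_phantom",
    "plate_stack", "rod_array", "sphere", "solid_cube", "isotropic_foam",
]

DEFAULT_DIMS = (128, 128, 128)
DEFAULT_VOXEL_SIZE = 0.018  # mm


@dataclasses.dataclass
class GroundTruth:
    """Analytic morphometry of a phantom; ``None`` marks undefined/unknown values.

    ``da_class`` is one of ``isotropic``, ``transversely_anisotropic``,
    ``orthotropic``; ``principal_axis`` is the array axis index (0=z, 1=y,
    2=x) of the distinguished direction, where one exists.
    """

    bvtv: float | None = None
    bs_mm2: float | None = None          # interior (non-boundary) surface
    tb_th_mm: float | None = None
    tb_sp_mm: float | None = None
    da_class: str = "isotropic"
    principal_axis: int | None = None
    notes: str = ""


@dataclasses.dataclass
class PhantomSpec:
    """Declarative phantom description; same spec + seed -> bit-identical volume."""

    kind: str
    dims: tuple = DEFAULT_DIMS
    voxel_size: float = DEFAULT_VOXEL_SIZE
    params: dict = dataclasses.field(default_factory=dict)
    seed: int = 0


def make_phantom(spec: PhantomSpec):
    """Dispatch a :class:`PhantomSpec` to its generator.

    Returns ``(VoxelImage, GroundTruth)``.
    """
    kinds = {
        "plate_stack": plate_stack,
        "rod_array": rod_array,
        "sphere": sphere,
        "solid_cube": solid_cube,
        "isotropic_foam": isotropic_foam,
    }
    if spec.kind not in kinds:
        raise GeometryError(f"unknown phantom kind {spec.kind!r}")
    fn = kinds[spec.kind]
    if spec.kind == "isotropic_foam":
        return fn(dims=spec.dims, voxel_size=spec.voxel_size, seed=spec.seed, **spec.params)
    return fn(dims=spec.dims, voxel_size=spec.voxel_size, **spec.params)


def _axis_view(mask: np.ndarray, axis: int) -> np.ndarray:
    """Move the distinguished axis to position 0 of a (z, y, x) volume."""
    return np.moveaxis(mask, 0, axis)


def plate_stack(t: int, g: int, dims=DEFAULT_DIMS, voxel_size: float = DEFAULT_VOXEL_SIZE,
                axis: int = 0):
    """Parallel full-extent plates of thickness ``t`` separated by gaps ``g`` (voxels).

    The pattern along ``axis`` starts with a plate; choosing the axis length
    as ``k*(t+g) + t`` makes both ends complete plates so every gap has the
    nominal width (the thickness/separation ground truth assumes this).
    """
    dims = tuple(int(d) for d in dims)
    n = dims[axis]
    if not (1 <= t < n and 1 <= g < n):
        raise GeometryError(f"plate t={t}, g={g} must be in [1, {n})")
    idx = np.arange(n)
    plate = (idx % (t + g)) < t
    shape = [1, 1, 1]
    shape[axis] = n
    mask = np.broadcast_to(plate.reshape(shape), dims).copy()
    h = voxel_size
    n_plate_layers = int(plate.sum())
    # Interior interfaces: layer pairs that differ along the axis.
    interfaces = int(np.count_nonzero(plate[:-1] != plate[1:]))
    inplane = np.prod([dims[a] for a in range(3) if a != axis])
    gt = GroundTruth(
        bvtv=n_plate_layers / n,
        bs_mm2=interfaces * float(inplane) * h * h,
        tb_th_mm=t * h,
        tb_sp_mm=g * h,
        da_class="transversely_anisotropic",
        principal_axis=axis,
        notes="plates normal to the given axis; MIL is smallest along that axis",
    )
    return VoxelImage(mask.astype(np.uint8), h, is_binary=True), gt


def rod_array(d: float, s: float | None = None, dims=DEFAULT_DIMS,
              voxel_size: float = DEFAULT_VOXEL_SIZE, axis: int = 0):
    """Parallel rods of diameter ``d`` voxels along ``axis`` on a square lattice of pitch ``s``.

    A voxel is bone when its centre lies within d/2 of a rod axis; the
    voxelisation error on the diameter is about one voxel.  ``s=None`` puts a
    single rod at the cross-section centre.
    """
    dims = tuple(int(d_) for d_ in dims)
    cross = [dims[a] for a in range(3) if a != axis]
    if not (1 <= d <= min(cross)):
        raise GeometryError(f"rod diameter {d} must be in [1, {min(cross)}]")
    if s is not None and s <= d:
        raise GeometryError(f"rod pitch {s} must exceed diameter {d}")
    u = np.arange(cross[0])[:, None]
    v = np.arange(cross[1])[None, :]
    if s is None:
        # axis through a voxel centre, so an odd diameter voxelises exactly
        centers = [((cross[0] - 1) // 2, (cross[1] - 1) // 2)]
    else:
        centers = [(s / 2.0 + i * s, s / 2.0 + j * s)
                   for i in range(int(math.ceil(cross[0] / s)))
                   for j in range(int(math.ceil(cross[1] / s)))
                   if s / 2.0 + i * s < cross[0] and s / 2.0 + j * s < cross[1]]
    r2 = (d / 2.0) ** 2
    section = np.zeros((cross[0], cross[1]), dtype=bool)
    for (cu, cv) in centers:
        section |= (u - cu) ** 2 + (v - cv) ** 2 <= r2
    mask = np.broadcast_to(section[None], (dims[axis], cross[0], cross[1])).copy()
    mask = np.moveaxis(mask, 0, axis)
    h = voxel_size
    gt = GroundTruth(
        bvtv=None,
        tb_th_mm=d * h,
        tb_sp_mm=(math.sqrt(2.0) * s - d) * h if s is not None else None,
        da_class="transversely_anisotropic",
        principal_axis=axis,
        notes="rods along the given axis; MIL is largest along that axis; "
              "tb_sp from the lattice-cell-centre inscribed sphere (approximate)",
    )
    return VoxelImage(mask.astype(np.uint8), h, is_binary=True), gt


def sphere(r: float, dims=DEFAULT_DIMS, voxel_size: float = DEFAULT_VOXEL_SIZE,
           center=None):
    """Solid ball of radius ``r`` voxels (voxel centres within ``r`` of the centre)."""
    dims = tuple(int(d) for d in dims)
    if not (1 <= r < min(dims) / 2):
        raise GeometryError(f"sphere radius {r} must be in [1, {min(dims) / 2})")
    if center is None:
        center = [(n - 1) / 2.0 for n in dims]
    zz, yy, xx = np.ogrid[: dims[0], : dims[1], : dims[2]]
    mask = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2) <= r * r
    h = voxel_size
    gt = GroundTruth(
        bvtv=(4.0 / 3.0) * math.pi * r**3 / float(np.prod(dims)),
        bs_mm2=4.0 * math.pi * (r * h) ** 2,
        tb_th_mm=2.0 * r * h,
        da_class="isotropic",
        notes="bvtv/bs analytic continuum values; voxelisation error O(1/r)",
    )
    return VoxelImage(mask.astype(np.uint8), h, is_binary=True), gt


def solid_cube(dims=DEFAULT_DIMS, voxel_size: float = DEFAULT_VOXEL_SIZE,
               side: int | None = None):
    """Solid cube: the full ROI by default, or a centred sub-cube of ``side`` voxels.

    The full-ROI case is degenerate: Tb.Sp. is undefined (no background) and
    the interior (non-boundary) bone surface is zero.
    """
    dims = tuple(int(d) for d in dims)
    h = voxel_size
    if side is None:
        mask = np.ones(dims, dtype=np.uint8)
        gt = GroundTruth(bvtv=1.0, bs_mm2=0.0, tb_sp_mm=None, da_class="isotropic",
                         notes="full-ROI solid; Tb.Sp. undefined, interior BS = 0")
        return VoxelImage(mask, h, is_binary=True), gt
    if not (1 <= side <= min(dims)):
        raise GeometryError(f"cube side {side} must be in [1, {min(dims)}]")
    mask = np.zeros(dims, dtype=np.uint8)
    sl = tuple(slice((n - side) // 2, (n - side) // 2 + side) for n in dims)
    mask[sl] = 1
    gt = GroundTruth(
        bvtv=side**3 / float(np.prod(dims)),
        bs_mm2=6.0 * (side * h) ** 2,
        tb_th_mm=side * h,
        da_class="isotropic",
    )
    return VoxelImage(mask, h, is_binary=True), gt


def isotropic_foam(bvtv: float = 0.25, corr_length: float = 4.0, dims=DEFAULT_DIMS,
                   voxel_size: float = DEFAULT_VOXEL_SIZE, seed: int = 0):
    """Isotropic foam: seeded Gaussian white noise smoothed at ``corr_length``
    voxels (periodic boundary keeps the field stationary) and thresholded at
    the quantile matching the target volume fraction.

    The realised BV/TV equals the target up to quantile ties; the structure is
    statistically isotropic, so its fabric tensor is spherical in expectation.
    """
    dims = tuple(int(d) for d in dims)
    if not (0.0 < bvtv < 1.0):
        raise GeometryError(f"target bvtv must be in (0, 1), got {bvtv}")
    if not (0 < corr_length < min(dims)):
        raise GeometryError(f"corr_length {corr_length} must be in (0, {min(dims)})")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(dims)
    field = ndimage.gaussian_filter(noise, sigma=corr_length, mode="wrap")
    thr = np.quantile(field, 1.0 - bvtv)
    mask = field > thr
    gt = GroundTruth(bvtv=bvtv, da_class="isotropic",
                     notes="thresholded Gaussian random field; realised bvtv "
                           "matches the target to within quantile ties")
    return VoxelImage(mask.astype(np.uint8), voxel_size, is_binary=True), gt
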