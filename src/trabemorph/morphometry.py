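"""Morphometric parameters of binary trabecular-bone volumes.

Implements the standard parameter set — BV/TV, bone surface (BS),
trabecular thickness (Tb.Th.) and separation (Tb.Sp.) — together with the
implementation variants known to drive disagreement between analysis tools:

* BV by voxel counting versus the volume enclosed by the triangulated surface;
* BS with the artificial ROI cut faces included or excluded;
* sphere-fitting local thickness with ROI-face voxels included in or excluded
  from the statistics.

Thickness follows the maximal-inscribed-sphere (model-independent) definition:
the local thickness at a voxel is the diameter of the largest sphere that lies
entirely inside the phase and covers the voxel.  It is computed from the exact
Euclidean distance transform via a pruned distance ridge and per-radius sphere
painting.  Radii are centre-to-centre distances with a one-voxel diameter
compensation, so an isolated voxel reports one voxel and an n-voxel slab
reports n voxels.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import DegeneratePhaseError, PreconditionError
from .image_io import VoxelImage, write_volume

__all__ = [
    "TriMesh", "ThicknessMap", "MorphometryResult",
    "bvtv_voxel", "triangulate", "bone_surface", "bvtv_mesh",
    "local_thickness", "tb_stats", "thickness_map_export", "analyze",
]

_PLANE_TOL = 1e-9  # mm; vertices on an ROI cut plane


# ====================================================================== mesh

@dataclasses.dataclass
class TriMesh:
    """Triangulated iso-surface with per-triangle ROI-boundary flags.

    ``vertices`` are in mm, voxel centres sitting at 0 .. (N-1)*h; the ROI cut
    planes are at -h/2 and (N-1/2)*h along each axis.  ``is_boundary`` marks
    cap triangles that lie entirely on a cut plane (artificial surface).
    """

    vertices: np.ndarray      # (nv, 3) float, (z, y, x) order, mm
    triangles: np.ndarray     # (nt, 3) int
    is_boundary: np.ndarray   # (nt,) bool
    roi_shape: tuple = ()
    voxel_size: float = 0.0

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        if self.n_triangles == 0:
            return np.zeros(0)
        v = self.vertices
        t = self.triangles
        cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def triangle_normals(self) -> np.ndarray:
        """Unit normals (orientation as produced by the extraction)."""
        v = self.vertices
        t = self.triangles
        cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        norm = np.linalg.norm(cross, axis=1)
        return cross / norm[:, None]

    def is_closed(self) -> bool:
        """True when every edge is shared by exactly two triangles."""
        if self.n_triangles == 0:
            return False
        t = self.triangles
        edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool((counts == 2).all())

    def enclosed_volume(self) -> float:
        """Volume in mm^3 by signed-tetrahedron summation (requires a closed mesh)."""
        v = self.vertices
        t = self.triangles
        if self.n_triangles == 0:
            return 0.0
        signed = np.einsum("ij,ij->i", v[t[:, 0]],
                           np.cross(v[t[:, 1]], v[t[:, 2]])) / 6.0
        return float(abs(signed.sum()))


def triangulate(img: VoxelImage, cap_boundary: bool = True) -> TriMesh:
    """Extract the bone/background iso-surface at level 0.5 (marching cubes).

    With ``cap_boundary=True`` the volume is conceptually padded by one layer
    of background, so foreground touching an ROI face is closed by cap
    triangles flagged ``is_boundary``; the mesh is then watertight.  With
    ``cap_boundary=False`` no caps are generated (a whole-ROI solid yields an
    empty mesh: all of its surface is artificial).
    """
    if not img.is_binary:
        raise PreconditionError("triangulate requires a binary volume")
    h = img.voxel_size
    mask = img.foreground_mask()
    if not mask.any():
        return TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int),
                       np.zeros(0, dtype=bool), img.shape, h)
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=(h, h, h))
    verts = verts - h  # voxel centres back at 0 .. (N-1)*h

    lo = -0.5 * h
    his = [(img.shape[a] - 0.5) * h for a in range(3)]
    # A vertex is on the ROI boundary if it lies on any cut plane; a triangle
    # is artificial when all three vertices do.  (Checking "all on the same
    # plane" would miss the chamfer triangles marching cubes emits along the
    # ROI edges and corners of the virtual background padding.)
    vertex_on = np.zeros(len(verts), dtype=bool)
    for a in range(3):
        vertex_on |= np.abs(verts[:, a] - lo) < _PLANE_TOL
        vertex_on |= np.abs(verts[:, a] - his[a]) < _PLANE_TOL
    boundary = vertex_on[faces].all(axis=1)

    areas_ok = _triangle_areas(verts, faces) > 0
    faces, boundary = faces[areas_ok], boundary[areas_ok]
    if not cap_boundary:
        faces = faces[~boundary]
        boundary = np.zeros(len(faces), dtype=bool)
    return TriMesh(verts, faces, boundary, img.shape, h)


def _triangle_areas(verts, faces):
    if len(faces) == 0:
        return np.zeros(0)
    cross = np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                     verts[faces[:, 2]] - verts[faces[:, 0]])
    return 0.5 * np.linalg.norm(cross, axis=1)


def bone_surface(mesh: TriMesh, include_boundary: bool = True) -> float:
    """Total triangle area in mm^2; optionally excluding ROI cap triangles.

    Excluding caps reproduces the convention that artificial cut surfaces are
    not part of the bone surface.
    """
    areas = mesh.triangle_areas()
    if len(areas) == 0:
        return 0.0
    if include_boundary:
        return float(areas.sum())
    return float(areas[~mesh.is_boundary].sum())


def bvtv_mesh(mesh: TriMesh, img: VoxelImage) -> float:
    """BV/TV from the volume enclosed by the (capped, closed) surface mesh."""
    if mesh.n_triangles == 0 or not mesh.is_closed():
        raise PreconditionError(
            "bvtv_mesh requires a closed mesh: triangulate with cap_boundary=True"
        )
    return mesh.enclosed_volume() / img.total_volume


# ====================================================================== BV/TV

def bvtv_voxel(img: VoxelImage) -> float:
    """Bone volume fraction by voxel counting: foreground voxels / ROI voxels."""
    if not img.is_binary:
        raise PreconditionError("bvtv_voxel requires a binary volume")
    return float(np.count_nonzero(img.data)) / float(img.data.size)


# =============================================================== thickness

@dataclasses.dataclass
class ThicknessMap:
    """Per-voxel local thickness (mm) of one phase.

    ``values`` is zero outside the evaluated phase; inside it every value is
    at least one voxel size (a single voxel has thickness one voxel diameter).
    ``excluded`` marks voxels whose assigned maximal sphere is truncated by an
    ROI face under ``edge_policy='exclude_edge_voxels'``; those are omitted
    from thickness statistics.
    """

    values: np.ndarray
    phase: str
    edge_policy: str
    voxel_size: float
    excluded: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.excluded is None:
            self.excluded = np.zeros(self.values.shape, dtype=bool)


def _prune_to_ridge(edt: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Drop voxels whose inscribed sphere is contained in a neighbour's sphere.

    Keeps a superset of the exact distance ridge (containment is only checked
    over the 26-neighbourhood), which is sufficient: painting from any
    superset of the ridge reproduces the exact thickness field.
    """
    contained = np.zeros(edt.shape, dtype=bool)
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                dist = np.sqrt(dz * dz + dy * dy + dx * dx)
                shifted = np.full_like(edt, -np.inf)
                src = tuple(slice(max(d, 0), s + min(d, 0))
                            for d, s in zip((dz, dy, dx), edt.shape))
                dst = tuple(slice(max(-d, 0), s + min(-d, 0))
                            for d, s in zip((dz, dy, dx), edt.shape))
                shifted[dst] = edt[src]
                contained |= shifted >= edt + dist - 1e-9
    return mask & ~contained


def local_thickness(img: VoxelImage, phase: str = "foreground",
                    edge_policy: str = "include_edges") -> ThicknessMap:
    """Maximal-inscribed-sphere local thickness of a phase, in mm.

    ``phase='background'`` evaluates the complement (this is how Tb.Sp. is
    obtained from the Tb.Th. algorithm).  ``edge_policy``:

    * ``include_edges`` — ROI faces act as phase boundary: spheres cannot
      extend past a face, and every phase voxel gets a value.
    * ``exclude_edge_voxels`` — spheres ignore ROI faces (only real interface
      limits them); voxels covered only by spheres truncated at a face are
      flagged ``excluded`` and skipped by the statistics.
    """
    if not img.is_binary:
        raise PreconditionError("local_thickness requires a binary volume")
    if phase not in ("foreground", "background"):
        raise PreconditionError(f"unknown phase {phase!r}")
    if edge_policy not in ("include_edges", "exclude_edge_voxels"):
        raise PreconditionError(f"unknown edge_policy {edge_policy!r}")
    mask = img.foreground_mask() if phase == "foreground" else ~img.foreground_mask()
    if not mask.any():
        raise DegeneratePhaseError(f"{phase} phase is empty")
    h = img.voxel_size

    if edge_policy == "include_edges":
        edt = ndimage.distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1, 1:-1]
    else:
        if mask.all():
            raise DegeneratePhaseError(
                f"{phase} fills the volume: thickness is unbounded under "
                "exclude_edge_voxels (no real interface)"
            )
        edt = ndimage.distance_transform_edt(mask)

    seed_mask = _prune_to_ridge(edt, mask)
    out = np.zeros(mask.shape)
    excluded = np.zeros(mask.shape, dtype=bool)

    if edge_policy == "exclude_edge_voxels":
        zz, yy, xx = np.indices(mask.shape, sparse=True)
        shape = mask.shape
        face_dist = np.minimum.reduce([
            np.broadcast_to(np.minimum(zz, shape[0] - 1 - zz) + 0.5, shape),
            np.broadcast_to(np.minimum(yy, shape[1] - 1 - yy) + 0.5, shape),
            np.broadcast_to(np.minimum(xx, shape[2] - 1 - xx) + 0.5, shape),
        ])
        truncated_seed = (edt - 0.5) > face_dist + 1e-9
    else:
        truncated_seed = np.zeros(mask.shape, dtype=bool)

    radii = np.unique(edt[seed_mask])[::-1]
    unassigned = mask.copy()
    for rad in radii:
        seeds = seed_mask & (edt == rad)
        thick = (2.0 * rad - 1.0) * h
        cov_ok = _covered(seeds & ~truncated_seed, rad)
        if truncated_seed.any():
            cov_tr = _covered(seeds & truncated_seed, rad)
        else:
            cov_tr = np.zeros(mask.shape, dtype=bool)
        newly = unassigned & (cov_ok | cov_tr)
        out[newly] = thick
        excluded[newly & ~cov_ok] = True
        unassigned &= ~newly
        if not unassigned.any():
            break
    return ThicknessMap(out, phase, edge_policy, h, excluded)


def _covered(seeds: np.ndarray, rad: float) -> np.ndarray:
    """Voxels strictly inside a sphere of radius ``rad`` centred on any seed."""
    if not seeds.any():
        return np.zeros(seeds.shape, dtype=bool)
    if rad <= 1.0:
        return seeds.copy()
    dt = ndimage.distance_transform_edt(~seeds)
    return dt < rad - 1e-9


def tb_stats(tmap: ThicknessMap, ddof: int = 1) -> tuple:
    """Mean and SD (mm) of the thickness field over evaluated, non-excluded voxels."""
    sel = (tmap.values > 0) & ~tmap.excluded
    vals = tmap.values[sel]
    if vals.size == 0:
        raise DegeneratePhaseError(
            f"no {tmap.phase} voxels left after edge policy {tmap.edge_policy!r}"
        )
    sd = float(vals.std(ddof=ddof)) if vals.size > ddof else 0.0
    return float(vals.mean()), sd


def thickness_map_export(tmap: ThicknessMap, path, format: str = "auto"):
    """Write the thickness field as a scalar volume (MHD/NIfTI/TIFF)."""
    img = VoxelImage(tmap.values.astype(np.float32), tmap.voxel_size, is_binary=False)
    return write_volume(img, path, format=format)


# ================================================================ top level

@dataclasses.dataclass
class MorphometryResult:
    """The five-parameter result of one volume, with variant provenance.

    ``variant_labels`` records which algorithm/policy produced each value so
    downstream comparisons can pair variants explicitly.
    """

    bvtv: float
    bs: float
    bs_excl_boundary: float
    tb_th_mean: float
    tb_th_sd: float
    tb_sp_mean: float
    tb_sp_sd: float
    da: float | None
    variant_labels: dict

    def to_rows(self, sample: str) -> list:
        """Long-format rows: (sample, parameter, value, units, variant_label)."""
        rows = [
            (sample, "bvtv", self.bvtv, "1", self.variant_labels["bvtv"]),
            (sample, "bs", self.bs, "mm^2", self.variant_labels["bs"]),
            (sample, "bs_excl_boundary", self.bs_excl_boundary, "mm^2",
             self.variant_labels["bs_excl_boundary"]),
            (sample, "tb_th_mean", self.tb_th_mean, "mm", self.variant_labels["tb_th"]),
            (sample, "tb_th_sd", self.tb_th_sd, "mm", self.variant_labels["tb_th"]),
            (sample, "tb_sp_mean", self.tb_sp_mean, "mm", self.variant_labels["tb_sp"]),
            (sample, "tb_sp_sd", self.tb_sp_sd, "mm", self.variant_labels["tb_sp"]),
        ]
        if self.da is not None:
            rows.append((sample, "da", self.da, "1", self.variant_labels["da"]))
        return rows


def analyze(img: VoxelImage,
            th_edges: str = "include_edges", bv_method: str = "voxel",
            da_method: str = "test_lines", da_convention: str = "eigen_ratio",
            n_directions: int = 128, line_spacing: float = 1.0,
            seed: int = 0, compute_da: bool = True) -> MorphometryResult:
    """Compute the full parameter set for one binary volume.

    Thin orchestration over the individual operations; every value is tagged
    with the variant that produced it.
    """
    from . import anisotropy  # deferred: avoids a cycle at import time

    mesh = triangulate(img, cap_boundary=True)
    bs_inc = bone_surface(mesh, include_boundary=True)
    bs_exc = bone_surface(mesh, include_boundary=False)
    bvtv = bvtv_mesh(mesh, img) if bv_method == "mesh" else bvtv_voxel(img)

    th = local_thickness(img, "foreground", th_edges)
    th_mean, th_sd = tb_stats(th)
    sp = local_thickness(img, "background", th_edges)
    sp_mean, sp_sd = tb_stats(sp)

    da_val = None
    if compute_da:
        if da_method == "test_lines":
            dist = anisotropy.mil_test_lines(img, n_directions=n_directions,
                                             line_spacing=line_spacing, seed=seed)
        else:
            dist = anisotropy.mil_surface_projection(img, mesh=mesh,
                                                     n_directions=n_directions)
        fab = anisotropy.fit_mil_ellipsoid(dist)
        da_val = anisotropy.degree_of_anisotropy(fab, convention=da_convention).da

    labels = {
        "bvtv": f"bv_{bv_method}",
        "bs": "mc_area_include_boundary",
        "bs_excl_boundary": "mc_area_exclude_boundary",
        "tb_th": f"maxsphere_{th_edges}",
        "tb_sp": f"maxsphere_{th_edges}",
        "da": f"mil_{da_method}_{da_convention}",
    }
    return MorphometryResult(
        bvtv=bvtv,
        bs=bs_inc,
        bs_excl_boundary=bs_exc,
        tb_th_mean=th_mean, tb_th_sd=th_sd,
        tb_sp_mean=sp_mean, tb_sp_sd=sp_sd,
        da=da_val, variant_labels=labels,
    )
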