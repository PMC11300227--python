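"""Voxel volumes and the density → mesh homogenization pipeline.

The pipeline mirrors the standard QCT-to-FE chain: resample the density
volume to the working resolution, convert HU to calibrated bone mineral
density (BMD, mgHA/cm³), threshold to a bone mask, mesh the mask with a
structured tetrahedral decomposition, and map a local bone volume
fraction (BV/TV) onto every element by trilinear interpolation.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mesh import TetMesh, structured_tet_mesh

#: default segmentation threshold for calibrated BMD volumes (mgHA/cm³)
BMD_THRESHOLD = 390.0

#: fully mineralized tissue density used for BMD → BV/TV (mgHA/cm³)
RHO_TISSUE = 1200.0

#: floor applied to element BV/TV so no element is void of stiffness
BVTV_MIN = 0.01

SEMANTICS = ("HU", "BMD", "BVTV", "MASK")


@dataclass
class VoxelVolume:
    """3-D scalar grid with voxel-center origin convention.

    ``values`` is indexed (x, y, z) with z the craniocaudal axis;
    ``spacing`` per-axis voxel size (mm); ``origin`` the physical
    position of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    semantics: str = "BMD"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.broadcast_to(np.asarray(self.origin, dtype=float), (3,)).copy()
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on all axes")
        if self.semantics not in SEMANTICS:
            raise ValueError(f"unknown semantics {self.semantics!r}")
        if self.semantics == "BVTV":
            v = self.values
            if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
                raise ValueError("BVTV values must lie in [0, 1]")

    @property
    def shape(self):
        return self.values.shape

    def physical_extent(self) -> np.ndarray:
        """Edge-to-edge physical size (mm) under the voxel-center convention."""
        return np.asarray(self.shape) * self.spacing

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]


# ----------------------------------------------------------------------
# pipeline operations
# ----------------------------------------------------------------------

def resample(volume: VoxelVolume, target_spacing) -> VoxelVolume:
    """Trilinear resample onto an isotropic (or per-axis) target spacing.

    The physical extent is preserved to within one voxel; semantics are
    unchanged.  Resampling at the native spacing is the identity.
    """
    if volume.values.size == 0:
        raise ValueError("cannot resample an empty volume")
    target = np.broadcast_to(np.asarray(target_spacing, dtype=float), (3,))
    if np.any(target <= 0):
        raise ValueError("target spacing must be positive")
    if np.allclose(target, volume.spacing):
        return VoxelVolume(volume.values.copy(), volume.spacing.copy(),
                           volume.origin.copy(), volume.semantics)
    extent = volume.physical_extent()
    new_shape = np.maximum(1, np.round(extent / target)).astype(int)
    # sample at new voxel centers, expressed in old voxel index coordinates
    grids = []
    for ax in range(3):
        centers = volume.origin[ax] + (np.arange(new_shape[ax]) + 0.5) * target[ax] \
            - 0.5 * volume.spacing[ax]
        grids.append((centers - volume.origin[ax]) / volume.spacing[ax])
    idx = np.meshgrid(*grids, indexing="ij")
    vals = ndimage.map_coordinates(volume.values.astype(float), np.array(idx),
                                   order=1, mode="nearest")
    new_origin = volume.origin - 0.5 * volume.spacing + 0.5 * target
    return VoxelVolume(vals, target.copy(), new_origin, volume.semantics)


def hu_to_bmd(volume: VoxelVolume, slope: float, intercept: float) -> VoxelVolume:
    """Affine HU → BMD conversion, ``bmd = slope * HU + intercept``."""
    if volume.semantics != "HU":
        raise ValueError(f"expected HU volume, got {volume.semantics}")
    vals = volume.values.astype(float) * slope + intercept
    return VoxelVolume(vals, volume.spacing.copy(), volume.origin.copy(), "BMD")


def threshold_mask(volume: VoxelVolume, threshold: float = BMD_THRESHOLD
                   ) -> tuple[VoxelVolume, dict]:
    """Segment bone: voxel kept iff BMD >= threshold (inclusive).

    Returns the 8-bit mask volume and a summary with the voxel count.
    """
    if volume.semantics != "BMD":
        raise ValueError(f"expected BMD volume, got {volume.semantics}")
    mask = (volume.values >= threshold).astype(np.uint8)
    summary = {"threshold": float(threshold), "n_voxels": int(mask.sum()),
               "fraction": float(mask.mean()) if mask.size else 0.0}
    return VoxelVolume(mask, volume.spacing.copy(), volume.origin.copy(), "MASK"), summary


def bvtv_field(bmd_volume: VoxelVolume, mask: VoxelVolume | None = None,
               rho_tissue: float = RHO_TISSUE) -> VoxelVolume:
    """BV/TV = clamp(BMD / rho_tissue, 0, 1) inside the mask, 0 outside."""
    if bmd_volume.semantics != "BMD":
        raise ValueError(f"expected BMD volume, got {bmd_volume.semantics}")
    if rho_tissue <= 0:
        raise ValueError("rho_tissue must be positive")
    b = np.clip(bmd_volume.values.astype(float) / rho_tissue, 0.0, 1.0)
    if mask is not None:
        b = np.where(mask.values > 0, b, 0.0)
    return VoxelVolume(b, bmd_volume.spacing.copy(), bmd_volume.origin.copy(), "BVTV")


def build_tet_mesh(mask: VoxelVolume, element_size: float = 1.0,
                   occupancy: float = 0.5) -> TetMesh:
    """Structured tet mesh of a mask: cubic cells of edge ``element_size``
    split into 6 tets each; cells below the occupancy cutoff dropped."""
    if mask.semantics != "MASK":
        raise ValueError(f"expected MASK volume, got {mask.semantics}")
    vals = mask.values > 0
    if not vals.any():
        raise ValueError("mask is empty")
    lo = mask.origin - 0.5 * mask.spacing
    extent = mask.physical_extent()
    n_cells = np.maximum(1, np.ceil(extent / element_size - 1e-9)).astype(int)

    # voxel centers → owning cell
    occ_sum = np.zeros(tuple(n_cells))
    occ_cnt = np.zeros(tuple(n_cells))
    idx = []
    for ax in range(3):
        centers = mask.voxel_centers(ax)
        cells = np.clip(((centers - lo[ax]) / element_size).astype(int), 0,
                        n_cells[ax] - 1)
        idx.append(cells)
    ii, jj, kk = np.meshgrid(*idx, indexing="ij")
    np.add.at(occ_sum, (ii, jj, kk), vals.astype(float))
    np.add.at(occ_cnt, (ii, jj, kk), 1.0)
    with np.errstate(invalid="ignore"):
        frac = np.where(occ_cnt > 0, occ_sum / np.maximum(occ_cnt, 1), 0.0)
    keep = frac >= occupancy
    if not keep.any():
        raise ValueError("no cell reaches the occupancy cutoff")
    if np.ptp(np.argwhere(keep)[:, 2]) + 1 < 1:
        raise ValueError("degenerate geometry in z")
    return structured_tet_mesh(keep, element_size, origin=tuple(lo))


def assign_element_bvtv(mesh: TetMesh, bvtv_volume: VoxelVolume,
                        bvtv_min: float = BVTV_MIN) -> TetMesh:
    """Map a local BV/TV onto every element by interpolating the masked
    density image.

    Each tet is probed at five points (centroid and vertex midpoints) by
    trilinear interpolation; the element value is the mean over the
    probes that land on bone (BV/TV > 0), clamped to [bvtv_min, 1].
    Restricting the mean to bone probes mirrors interpolation of a
    segmented-and-masked image: a coarse boundary element draws its
    density from the bone it overlaps — including a thin cortical shell
    — rather than being diluted by background, which is what makes
    coarse meshes act cortically thickened.  For a field linear in
    space the probe mean equals the centroid value exactly.
    """
    if bvtv_volume.semantics != "BVTV":
        raise ValueError(f"expected BVTV volume, got {bvtv_volume.semantics}")
    cen = mesh.centroids()
    lo = bvtv_volume.origin - 0.5 * bvtv_volume.spacing
    hi = lo + bvtv_volume.physical_extent()
    # boundary cells of a coarse structured mesh may overhang the voxel
    # grid by up to half a cell; anything further out is a user error
    h_el = float(np.cbrt(6.0 * np.abs(mesh.volumes()).max()))
    margin = 0.51 * h_el
    if np.any(cen < lo - margin) or np.any(cen > hi + margin):
        raise ValueError("mesh extends outside the BV/TV volume bounds")
    verts = mesh.nodes[mesh.elements]                       # (m, 4, 3)
    probes = np.concatenate([cen[:, None, :],
                             0.5 * (verts + cen[:, None, :])], axis=1)
    coords = (probes - bvtv_volume.origin) / bvtv_volume.spacing
    flat = coords.reshape(-1, 3).T
    vals = ndimage.map_coordinates(bvtv_volume.values.astype(float), flat,
                                   order=1, mode="nearest").reshape(-1, 5)
    bone = vals > 0.0
    n_bone = bone.sum(axis=1)
    mean_bone = np.where(n_bone > 0,
                         (vals * bone).sum(axis=1) / np.maximum(n_bone, 1),
                         0.0)
    mesh.element_bvtv = np.clip(mean_bone, bvtv_min, 1.0)
    return mesh


# ----------------------------------------------------------------------
# voxel I/O
# ----------------------------------------------------------------------

def read_volume(path, semantics: str = "BMD") -> VoxelVolume:
    """Read NIfTI (.nii/.nii.gz) via nibabel or MHD/MHA via SimpleITK."""
    path = pathlib.Path(path)
    if path.suffix in (".nii",) or str(path).endswith(".nii.gz"):
        import nibabel as nib
        img = nib.load(str(path))
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        return VoxelVolume(np.asanyarray(img.dataobj), spacing, origin, semantics)
    import SimpleITK as sitk
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # zyx -> xyz
    return VoxelVolume(arr, np.asarray(img.GetSpacing()),
                       np.asarray(img.GetOrigin()), semantics)


def write_volume(volume: VoxelVolume, path) -> None:
    path = pathlib.Path(path)
    vals = volume.values
    if volume.semantics == "MASK":
        vals = vals.astype(np.uint8)
    if path.suffix in (".nii",) or str(path).endswith(".nii.gz"):
        import nibabel as nib
        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(np.asarray(vals), affine), str(path))
        return
    import SimpleITK as sitk
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.asarray(vals).transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, str(path))
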