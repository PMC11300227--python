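"""Synthetic vertebra phantoms with known ground truth.

A phantom is an elliptic-cylindrical vertebral-body section (plane-
parallel end surfaces, as in cadaver compression tests) consisting of a
dense cortical shell and a trabecular interior whose BV/TV is a
correlated Gaussian random field.  Metastatic lesion morphologies are
carved into the interior:

* ``L`` (osteolytic): connected low-density "moth-eaten" voids;
* ``S`` (osteosclerotic): dense plate-like regions with BV/TV
  approaching solid tissue;
* ``M`` (mixed): lytic and sclerotic patterns in disjoint halves.

The generator emulates micro-CT-derived sections already resampled to
the homogenized working resolution and calibrated to BMD (mgHA/cm³);
it does not model raw-scan noise structure, endplate curvature or
posterior elements.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from . import image as im
from .experiment import LoadDisplacementCurve, extract_stiffness, extract_strength
from .mesh import TetMesh, structured_tet_mesh
from .parameters import MaterialParameters
from .solver import LoadProtocol, solve_quasi_static

#: BMD threshold separating phantom bone from background when meshing a
#: homogenized (continuum BV/TV) volume; well below any trabecular mean.
GEOMETRY_THRESHOLD = 30.0

LESION_BVTV = {"L": 0.02, "S": 0.85}


@dataclass
class PhantomSpec:
    """Geometry, texture and lesion description of one phantom."""

    half_axes: tuple = (4.2, 3.0)
    height: float = 10.0
    cortex_thickness: float = 0.8
    cortex_bvtv: float = 0.8
    trabecular_bvtv_mean: float = 0.10
    trabecular_bvtv_sd: float = 0.03
    lesion_type: str = "none"
    lesion_fraction: float = 0.3
    lesion_bvtv: float | None = None
    correlation_length: float = 2.0
    noise_sd: float = 5.0
    spacing: float = 0.5
    rho_tissue: float = im.RHO_TISSUE
    seed: int = 0

    def __post_init__(self):
        if min(self.half_axes) <= 0 or self.height <= 0 or self.spacing <= 0:
            raise ValueError("geometric fields must be positive")
        if self.lesion_type not in ("none", "L", "S", "M"):
            raise ValueError("lesion_type must be one of none/L/S/M")
        if not (0.0 <= self.lesion_fraction <= 1.0):
            raise ValueError("lesion_fraction must lie in [0, 1]")
        if self.cortex_thickness >= min(self.half_axes):
            raise ValueError("cortex thicker than the body half-axis")

    def to_dict(self) -> dict:
        return asdict(self)


def _gaussian_field(rng, shape, sigma_vox, region=None):
    """Correlated Gaussian texture, standardized to mean 0 / SD 1 over
    ``region`` (or the whole grid) so that target BV/TV statistics are
    met exactly on the compartment they describe."""
    field = rng.standard_normal(shape)
    if sigma_vox > 0:
        field = ndimage.gaussian_filter(field, sigma_vox)
    ref = field[region] if region is not None else field
    sd = ref.std()
    if sd > 0:
        field = (field - ref.mean()) / sd
    return field


def make_phantom(spec: PhantomSpec) -> im.VoxelVolume:
    """Generate the BMD voxel volume of a phantom (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    a, b = spec.half_axes
    h = spec.spacing
    nx = int(np.ceil(2 * a / h)) + 2
    ny = int(np.ceil(2 * b / h)) + 2
    nz = int(np.round(spec.height / h))
    if nz < 1:
        raise ValueError("phantom height below one voxel")
    x = (np.arange(nx) - (nx - 1) / 2) * h
    y = (np.arange(ny) - (ny - 1) / 2) * h
    X, Y = np.meshgrid(x, y, indexing="ij")

    interior2d = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
    at, bt = a - spec.cortex_thickness, b - spec.cortex_thickness
    trabecular2d = (X / at) ** 2 + (Y / bt) ** 2 <= 1.0
    cortex2d = interior2d & ~trabecular2d

    interior = np.repeat(interior2d[:, :, None], nz, axis=2)
    trabecular = np.repeat(trabecular2d[:, :, None], nz, axis=2)
    cortex = np.repeat(cortex2d[:, :, None], nz, axis=2)

    sigma_vox = spec.correlation_length / h
    texture = _gaussian_field(rng, (nx, ny, nz), sigma_vox, region=trabecular)
    bvtv = np.zeros((nx, ny, nz))
    bvtv[trabecular] = np.clip(
        spec.trabecular_bvtv_mean + spec.trabecular_bvtv_sd * texture[trabecular],
        0.005, 0.95)
    bvtv[cortex] = spec.cortex_bvtv

    if spec.lesion_type != "none" and spec.lesion_fraction > 0:
        lesion_field = _gaussian_field(rng, (nx, ny, nz), sigma_vox)
        if spec.lesion_type in ("L", "S"):
            _carve(bvtv, trabecular, lesion_field, spec.lesion_fraction,
                   spec.lesion_bvtv if spec.lesion_bvtv is not None
                   else LESION_BVTV[spec.lesion_type])
        else:  # mixed: lytic anterior half, sclerotic posterior half
            front = np.zeros_like(trabecular)
            front[:, : ny // 2, :] = True
            _carve(bvtv, trabecular & front, lesion_field, spec.lesion_fraction,
                   LESION_BVTV["L"])
            _carve(bvtv, trabecular & ~front, lesion_field, spec.lesion_fraction,
                   LESION_BVTV["S"])

    bmd = bvtv * spec.rho_tissue
    if spec.noise_sd > 0:
        bmd = bmd + rng.normal(0.0, spec.noise_sd, bmd.shape)
    bmd = np.where(interior, np.clip(bmd, 0.0, None), 0.0)

    origin = np.array([x[0], y[0], 0.5 * h])
    return im.VoxelVolume(bmd, np.array([h, h, h]), origin, "BMD")


def _carve(bvtv, region, field, fraction, target):
    """Set the top `fraction` of the correlated field inside `region` to
    the lesion BV/TV (connected blobs by construction of the field)."""
    vals = field[region]
    if vals.size == 0:
        raise ValueError("lesion region is empty for this geometry")
    thresh = np.quantile(vals, 1.0 - fraction) if fraction < 1 else -np.inf
    lesion = region & (field >= thresh)
    bvtv[lesion] = target


# ----------------------------------------------------------------------
# phantom → model and synthetic experiments
# ----------------------------------------------------------------------

def phantom_to_mesh(volume: im.VoxelVolume, element_size: float = 1.0,
                    rho_tissue: float = im.RHO_TISSUE,
                    geometry_threshold: float = GEOMETRY_THRESHOLD) -> TetMesh:
    """Mask, BV/TV-map and mesh a homogenized phantom volume."""
    mask, _ = im.threshold_mask(volume, geometry_threshold)
    bvtv = im.bvtv_field(volume, mask, rho_tissue)
    mesh = im.build_tet_mesh(mask, element_size)
    return im.assign_element_bvtv(mesh, bvtv)


def make_reference_curve(spec: PhantomSpec, true_params: MaterialParameters,
                         protocol: LoadProtocol, noise_sd_kN: float = 0.0,
                         seed: int = 0, element_size: float = 1.0):
    """Synthetic "experiment": full pipeline at known parameters.

    Returns ``(curve, ground_truth)`` where ground truth records the
    noiseless strength and stiffness alongside the generating spec.
    """
    mesh = phantom_to_mesh(make_phantom(spec), element_size)
    result = solve_quasi_static(mesh, true_params, protocol, record_fields=False)
    curve = result.curve
    truth = {"strength_kN": extract_strength(curve),
             "stiffness_kN_per_mm": extract_stiffness(curve),
             "stop_reason": result.stop_reason,
             "spec": spec.to_dict()}
    if noise_sd_kN > 0:
        rng = np.random.default_rng(seed)
        noisy = curve.force + rng.normal(0.0, noise_sd_kN, len(curve.force))
        noisy[0] = 0.0
        curve = LoadDisplacementCurve(curve.displacement, noisy)
    return curve, truth


# ----------------------------------------------------------------------
# deterministic test fixtures
# ----------------------------------------------------------------------

def fixture_suite() -> dict:
    """Small deterministic meshes/specs used across the test-suite and docs.

    ``prism_10mm`` is a 4 x 4 x 10 mm column at 1 mm elements with
    uniform BV/TV 0.3; with nu = 0 its small-strain stiffness has the
    closed form  K = TF(0.3) * E00 * A / L  (TF the tissue function).
    """
    single = TetMesh(
        nodes=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]]),
        elements=np.array([[0, 1, 2, 3]]),
        element_bvtv=np.array([1.0]),
        cranial_nodes=np.array([3]),
        caudal_nodes=np.array([0, 1, 2]),
    )

    cube = structured_tet_mesh(np.ones((1, 1, 1), dtype=bool), 1.0)
    cube.element_bvtv = np.full(cube.n_elements, 1.0)

    prism = structured_tet_mesh(np.ones((4, 4, 10), dtype=bool), 1.0)
    prism.element_bvtv = np.full(prism.n_elements, 0.3)

    mini = {
        t: PhantomSpec(lesion_type=t, seed=3)
        for t in ("L", "S", "M")
    }
    return {
        "single_tet": single,
        "cube_6tet": cube,
        "prism_10mm": prism,
        "mini_vertebra_L": mini["L"],
        "mini_vertebra_S": mini["S"],
        "mini_vertebra_M": mini["M"],
    }
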