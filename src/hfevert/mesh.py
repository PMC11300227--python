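"""Tetrahedral meshes with per-element bone volume fraction.

The structured mesher decomposes each kept cubic cell into six tet4
elements along the cell's main diagonal (Kuhn subdivision), which is
conforming across neighbouring cells and volume-exact.  Unstructured
meshes produced elsewhere can be imported through the VTK reader.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import numpy as np

# six tets per cube along the (0,0,0)-(1,1,1) diagonal; vertices encoded
# by their (i,j,k) offset bits.  Each row: four corner offsets.
_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


@dataclass
class TetMesh:
    """Nodes (mm), tet4 connectivity, per-element BV/TV, boundary sets."""

    nodes: np.ndarray
    elements: np.ndarray
    element_bvtv: np.ndarray | None = None
    cranial_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    caudal_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.elements.ndim != 2 or self.elements.shape[1] != 4:
            raise ValueError("elements must be (n, 4)")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def volumes(self) -> np.ndarray:
        X = self.nodes[self.elements]
        d = X[:, 1:] - X[:, :1]
        return np.linalg.det(d) / 6.0

    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def validate(self) -> None:
        vols = self.volumes()
        if np.any(vols <= 0):
            bad = int(np.argmin(vols))
            raise ValueError(f"non-positive element volume at element {bad}")
        if len(self.cranial_nodes) and len(self.caudal_nodes):
            if np.intersect1d(self.cranial_nodes, self.caudal_nodes).size:
                raise ValueError("cranial and caudal node sets overlap")


def fix_orientation(elements: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Swap two local nodes wherever an element has negative volume."""
    X = nodes[elements]
    vols = np.linalg.det(X[:, 1:] - X[:, :1]) / 6.0
    out = elements.copy()
    flip = vols < 0
    out[flip, 2], out[flip, 3] = elements[flip, 3], elements[flip, 2]
    return out


def structured_tet_mesh(keep: np.ndarray, cell_size: float, origin=(0.0, 0.0, 0.0)
                        ) -> TetMesh:
    """Mesh the True cells of a 3-D boolean grid with 6 tets per cell.

    ``origin`` is the physical position of the (0,0,0) cell's minimum
    corner.  Cranial/caudal node sets are the nodes on the top / bottom
    z-planes of the generated mesh.
    """
    keep = np.asarray(keep, dtype=bool)
    if keep.ndim != 3 or not keep.any():
        raise ValueError("keep must be a non-empty 3-D boolean grid")

    nx, ny, nz = keep.shape
    # global corner-node lattice, compressed to used nodes
    node_id = -np.ones((nx + 1, ny + 1, nz + 1), dtype=np.int64)
    ci, cj, ck = np.nonzero(keep)
    corners = np.empty((len(ci), 8, 3), dtype=np.int64)
    # corner b of a cell carries offset bits (b&1, b>>1&1, b>>2&1)
    offs = np.array([[(b >> 0) & 1, (b >> 1) & 1, (b >> 2) & 1] for b in range(8)])
    for b, (oi, oj, ok) in enumerate(offs):
        corners[:, b, 0] = ci + oi
        corners[:, b, 1] = cj + oj
        corners[:, b, 2] = ck + ok
    flat = corners.reshape(-1, 3)
    node_id[flat[:, 0], flat[:, 1], flat[:, 2]] = 0
    used = np.argwhere(node_id == 0)
    node_id[used[:, 0], used[:, 1], used[:, 2]] = np.arange(len(used))
    nodes = used * cell_size + np.asarray(origin)

    elems = []
    for perm in _KUHN_PERMS:
        v = 0
        verts = [0]
        for ax in perm:
            v |= 1 << ax
            verts.append(v)
        elems.append(verts)  # corner bit-codes of one tet
    elems = np.asarray(elems)  # (6, 4)

    cell_corner_ids = node_id[corners[..., 0], corners[..., 1], corners[..., 2]]
    elements = cell_corner_ids[:, elems].reshape(-1, 4)
    elements = fix_orientation(elements, nodes)

    z = nodes[:, 2]
    tol = 1e-9 * max(1.0, cell_size)
    cranial = np.nonzero(z >= z.max() - tol)[0]
    caudal = np.nonzero(z <= z.min() + tol)[0]
    mesh = TetMesh(nodes=nodes, elements=elements,
                   cranial_nodes=cranial, caudal_nodes=caudal)
    mesh.validate()
    return mesh


# ----------------------------------------------------------------------
# quality metrics
# ----------------------------------------------------------------------

def mesh_quality(mesh: TetMesh) -> dict:
    """Deterministic quality report for a tet mesh.

    Aspect ratio is longest-edge / (2 sqrt(6) inradius), equal to 1 for
    the regular tetrahedron.  Degenerate (non-positive-volume) elements
    are listed by index instead of poisoning the metrics.
    """
    X = mesh.nodes[mesh.elements]
    vols = np.linalg.det(X[:, 1:] - X[:, :1]) / 6.0
    degenerate = np.nonzero(vols <= 0)[0]
    ok = vols > 0

    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    edges = np.stack([np.linalg.norm(X[:, a] - X[:, b], axis=1) for a, b in pairs],
                     axis=1)
    lmax = edges.max(axis=1)

    # total face area -> inradius r = 3V / A_total
    faces = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]
    area = np.zeros(len(X))
    for a, b, c in faces:
        n = np.cross(X[:, b] - X[:, a], X[:, c] - X[:, a])
        area += 0.5 * np.linalg.norm(n, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_in = 3.0 * np.abs(vols) / area
        aspect = lmax / (2.0 * np.sqrt(6.0) * r_in)

    dihedral_min = _min_dihedral(X[ok]) if ok.any() else np.nan
    asp = aspect[ok]
    return {
        "n_elements": mesh.n_elements,
        "min_aspect": float(asp.min()) if asp.size else np.nan,
        "mean_aspect": float(asp.mean()) if asp.size else np.nan,
        "min_dihedral_deg": float(dihedral_min),
        "degenerate_elements": degenerate.tolist(),
    }


def _min_dihedral(X: np.ndarray) -> float:
    faces = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]
    normals = []
    for a, b, c in faces:
        n = np.cross(X[:, b] - X[:, a], X[:, c] - X[:, a])
        normals.append(n / np.linalg.norm(n, axis=1, keepdims=True))
    # outward-orient: flip so each normal points away from opposite vertex
    for idx, (a, b, c) in enumerate(faces):
        opp = X[:, idx]
        d = np.einsum("ij,ij->i", normals[idx], opp - X[:, a])
        normals[idx][d > 0] *= -1
    best = np.inf
    for i in range(4):
        for j in range(i + 1, 4):
            cosang = np.clip(-np.einsum("ij,ij->i", normals[i], normals[j]), -1, 1)
            ang = np.degrees(np.arccos(cosang))
            best = min(best, float(ang.min()))
    return best


# ----------------------------------------------------------------------
# I/O: legacy VTK (read/write), Abaqus INP and CSV node sets (write)
# ----------------------------------------------------------------------

def write_vtk(mesh: TetMesh, path, cell_data: dict | None = None) -> None:
    """Legacy ASCII VTK unstructured grid with optional per-cell scalars."""
    path = pathlib.Path(path)
    cell_data = dict(cell_data or {})
    if mesh.element_bvtv is not None and "bvtv" not in cell_data:
        cell_data["bvtv"] = mesh.element_bvtv
    lines = ["# vtk DataFile Version 3.0", "hfevert tetrahedral mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {mesh.n_nodes} double"]
    lines += [" ".join(f"{v:.10g}" for v in p) for p in mesh.nodes]
    m = mesh.n_elements
    lines.append(f"CELLS {m} {5 * m}")
    lines += ["4 " + " ".join(str(i) for i in e) for e in mesh.elements]
    lines.append(f"CELL_TYPES {m}")
    lines += ["10"] * m
    if cell_data:
        lines.append(f"CELL_DATA {m}")
        for name, values in cell_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.10g}" for v in np.asarray(values, dtype=float)]
    path.write_text("\n".join(lines) + "\n")


def read_vtk(path) -> TetMesh:
    """Read a legacy ASCII VTK unstructured tet mesh written by `write_vtk`."""
    tokens = pathlib.Path(path).read_text().split("\n")
    nodes = elements = None
    cell_data = {}
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vals = " ".join(tokens[i + 1:i + 1 + n]).split()
            nodes = np.array(vals, dtype=float).reshape(n, 3)
            i += n
        elif line.startswith("CELLS"):
            m = int(line.split()[1])
            rows = [tokens[i + 1 + k].split() for k in range(m)]
            elements = np.array([[int(x) for x in r[1:5]] for r in rows])
            i += m
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            m = len(elements)
            vals = np.array(" ".join(tokens[i + 2:i + 2 + m]).split(), dtype=float)
            cell_data[name] = vals
            i += m + 1
        i += 1
    mesh = TetMesh(nodes=nodes, elements=elements,
                   element_bvtv=cell_data.get("bvtv"))
    z = mesh.nodes[:, 2]
    tol = 1e-9 * max(1.0, float(z.max() - z.min()))
    mesh.cranial_nodes = np.nonzero(z >= z.max() - tol)[0]
    mesh.caudal_nodes = np.nonzero(z <= z.min() + tol)[0]
    return mesh


def write_abaqus_inp(mesh: TetMesh, path) -> None:
    """Abaqus INP export (C3D4) with BV/TV as a distribution table and the
    cranial/caudal boundary node sets."""
    path = pathlib.Path(path)
    out = ["*HEADING", "hfevert tetrahedral mesh", "*NODE"]
    out += [f"{i + 1}, {x:.10g}, {y:.10g}, {z:.10g}"
            for i, (x, y, z) in enumerate(mesh.nodes)]
    out.append("*ELEMENT, TYPE=C3D4, ELSET=BONE")
    out += [f"{i + 1}, " + ", ".join(str(n + 1) for n in e)
            for i, e in enumerate(mesh.elements)]
    for name, nset in (("CRANIAL", mesh.cranial_nodes), ("CAUDAL", mesh.caudal_nodes)):
        out.append(f"*NSET, NSET={name}")
        ids = [str(n + 1) for n in nset]
        out += [", ".join(ids[k:k + 10]) for k in range(0, len(ids), 10)]
    if mesh.element_bvtv is not None:
        out.append("*DISTRIBUTION TABLE, NAME=BVTV_TABLE")
        out.append("BVTV")
        out.append("*DISTRIBUTION, NAME=BVTV, LOCATION=ELEMENT, TABLE=BVTV_TABLE")
        out += [f"{i + 1}, {v:.6g}" for i, v in enumerate(mesh.element_bvtv)]
    path.write_text("\n".join(out) + "\n")


def write_node_sets_csv(mesh: TetMesh, path) -> None:
    path = pathlib.Path(path)
    lines = ["set,node_index"]
    lines += [f"cranial,{i}" for i in mesh.cranial_nodes]
    lines += [f"caudal,{i}" for i in mesh.caudal_nodes]
    path.write_text("\n".join(lines) + "\n")
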