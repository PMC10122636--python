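"""Linear-elastic voxel FE with 8-node trilinear hexahedral elements.

Units are fixed to mm-N-MPa, so strain energy density comes out in MPa
(= mJ/mm^3).  Strain/stress use Voigt order (11, 22, 33, 23, 13, 12) with
engineering shear strains.  Per-element quantities are evaluated at the
element centroid; stiffness uses 2x2x2 Gauss integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import cg, splu

from boneibr.image import VoxelImage

__all__ = [
    "Material",
    "HexMesh",
    "LoadCase",
    "FESolution",
    "isotropic_stiffness",
    "orthotropic_stiffness",
    "image_to_mesh",
    "hex_stiffness",
    "solve",
    "canonical_section_loadcases",
]

# VTK hexahedron corner order in natural coordinates.
_NAT_COORDS = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)

_VOIGT_PAIRS = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]

# Direct solver below this many free DOFs; diagonally preconditioned CG
# above (factorization fill-in dominates beyond this size on voxel meshes).
_DIRECT_DOF_LIMIT = 25_000
_CG_RTOL = 1e-9


def isotropic_stiffness(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic stiffness in Voigt notation (engineering shear)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.diag_indices(3)] += 2 * mu
    C[3, 3] = C[4, 4] = C[5, 5] = mu
    return C


def orthotropic_stiffness(
    E: np.ndarray, G: np.ndarray, nu: np.ndarray
) -> np.ndarray:
    """6x6 orthotropic stiffness from engineering constants in material axes.

    Parameters are ``E = (E1, E2, E3)``, ``G = (G23, G13, G12)`` and
    ``nu = (nu23, nu13, nu12)`` with the convention ``nu_ij / E_i = nu_ji / E_j``.
    """
    E1, E2, E3 = E
    G23, G13, G12 = G
    nu23, nu13, nu12 = nu
    S = np.zeros((6, 6))
    S[0, 0], S[1, 1], S[2, 2] = 1 / E1, 1 / E2, 1 / E3
    S[0, 1] = S[1, 0] = -nu12 / E1
    S[0, 2] = S[2, 0] = -nu13 / E1
    S[1, 2] = S[2, 1] = -nu23 / E2
    S[3, 3], S[4, 4], S[5, 5] = 1 / G23, 1 / G13, 1 / G12
    return np.linalg.inv(S)


def _bond_matrix(R: np.ndarray) -> np.ndarray:
    """6x6 Voigt (Bond) stress-transformation matrix for rotation ``R``.

    ``R`` has the material axes as columns; ``C_global = M C_local M^T``.
    """
    M = np.zeros((6, 6))
    for I, (i, j) in enumerate(_VOIGT_PAIRS):
        for J, (k, l) in enumerate(_VOIGT_PAIRS):
            if k == l:
                M[I, J] = R[i, k] * R[j, k]
            else:
                M[I, J] = R[i, k] * R[j, l] + R[i, l] * R[j, k]
    return M


@dataclass
class Material:
    """Linear-elastic material: isotropic or orthotropic.

    For orthotropic materials the engineering constants live in the material
    eigenbasis given by ``axes`` (orthonormal columns); the global stiffness
    is obtained by a Bond transformation.
    """

    kind: str = "isotropic"
    E: float = 12_000.0
    nu: float = 0.3
    E3: np.ndarray | None = None  # (E1, E2, E3)
    G3: np.ndarray | None = None  # (G23, G13, G12)
    nu3: np.ndarray | None = None  # (nu23, nu13, nu12)
    axes: np.ndarray | None = None  # 3x3, columns = material axes

    def stiffness(self) -> np.ndarray:
        """Global-frame 6x6 stiffness; raises if not positive definite."""
        if self.kind == "isotropic":
            C = isotropic_stiffness(self.E, self.nu)
        elif self.kind == "orthotropic":
            C = orthotropic_stiffness(self.E3, self.G3, self.nu3)
            if self.axes is not None:
                M = _bond_matrix(np.asarray(self.axes, dtype=float))
                C = M @ C @ M.T
        else:
            raise ValueError(f"unknown material kind {self.kind!r}")
        eigvals = np.linalg.eigvalsh(0.5 * (C + C.T))
        if eigvals.min() <= 0:
            raise ValueError(
                f"material stiffness not positive definite (min eig {eigvals.min():g})"
            )
        return 0.5 * (C + C.T)


@dataclass
class HexMesh:
    """8-node hexahedral mesh on a regular grid.

    ``materials`` is either a single :class:`Material` shared by all
    elements or a list with one entry per element.
    """

    node_coords: np.ndarray  # (n_nodes, 3) mm
    elements: np.ndarray  # (n_elements, 8) int
    materials: Material | list[Material]
    element_volume: np.ndarray  # (n_elements,) mm^3
    edge_lengths: np.ndarray  # (3,) mm, uniform over the regular grid
    element_density: np.ndarray | None = None  # per-element relative density

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def material_list(self) -> list[Material]:
        if isinstance(self.materials, Material):
            return [self.materials] * self.n_elements
        return list(self.materials)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.node_coords.min(axis=0), self.node_coords.max(axis=0)


@dataclass
class LoadCase:
    """Displacement-controlled load case.

    ``prescribed`` maps node index -> (mask, value) where ``mask`` selects
    which of the three components are constrained and ``value`` holds the
    prescribed displacement for those components (mm).  ``reaction_nodes``
    names the node set over which the reaction force is reported.
    """

    name: str
    prescribed: dict[int, tuple[np.ndarray, np.ndarray]]
    reaction_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    macroscopic_strain: np.ndarray | None = None  # set for KUBC cases

    def dof_arrays(self, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (constrained dof indices, prescribed values)."""
        dofs, values = [], []
        for node, (mask, value) in self.prescribed.items():
            for c in range(3):
                if mask[c]:
                    dofs.append(3 * node + c)
                    values.append(value[c])
        dofs = np.asarray(dofs, dtype=int)
        order = np.argsort(dofs)
        return dofs[order], np.asarray(values, dtype=float)[order]


@dataclass
class FESolution:
    """Solved state for one load case."""

    load_case: str
    displacements: np.ndarray  # (n_nodes, 3) mm
    strain: np.ndarray  # (n_elements, 6) Voigt, engineering shear
    stress: np.ndarray  # (n_elements, 6) MPa
    sed: np.ndarray  # (n_elements,) MPa
    reaction: np.ndarray  # (3,) N, summed over the reaction node set
    nodal_forces: np.ndarray  # (n_nodes, 3) N, internal forces K u


def image_to_mesh(
    image: VoxelImage,
    material: Material | None = None,
    threshold: float = 0.5,
) -> HexMesh:
    """Convert a binary voxel image to a hexahedral mesh, one element per
    bone voxel, sharing nodes between adjacent elements."""
    bone = np.asarray(image.values) >= threshold
    idx = np.argwhere(bone)
    if idx.size == 0:
        raise ValueError("empty mesh: image contains no bone voxels")
    shape = image.shape
    nx, ny, nz = shape[0] + 1, shape[1] + 1, shape[2] + 1

    # Grid-node linear ids for the 8 corners of each voxel.
    def nid(i, j, k):
        return (i * ny + j) * nz + k

    i, j, k = idx[:, 0], idx[:, 1], idx[:, 2]
    corners = np.stack(
        [
            nid(i, j, k),
            nid(i + 1, j, k),
            nid(i + 1, j + 1, k),
            nid(i, j + 1, k),
            nid(i, j, k + 1),
            nid(i + 1, j, k + 1),
            nid(i + 1, j + 1, k + 1),
            nid(i, j + 1, k + 1),
        ],
        axis=1,
    )
    used, elements = np.unique(corners, return_inverse=True)
    elements = elements.reshape(corners.shape).astype(np.int64)
    gi, rem = np.divmod(used, ny * nz)
    gj, gk = np.divmod(rem, nz)
    node_coords = np.stack([gi, gj, gk], axis=1) * image.spacing + image.origin

    h = image.spacing
    n_el = elements.shape[0]
    return HexMesh(
        node_coords=node_coords.astype(float),
        elements=elements,
        materials=material if material is not None else Material(),
        element_volume=np.full(n_el, h**3),
        edge_lengths=np.array([h, h, h]),
    )


def _shape_gradients(edge_lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """B matrices (6x24) at the 2x2x2 Gauss points and at the centroid."""
    a, b, c = edge_lengths
    scale = np.array([2 / a, 2 / b, 2 / c])
    g = 1 / np.sqrt(3.0)
    gauss = _NAT_COORDS * g

    def b_at(xi):
        dN = np.empty((8, 3))
        for n in range(8):
            s = _NAT_COORDS[n]
            dN[n, 0] = 0.125 * s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2])
            dN[n, 1] = 0.125 * s[1] * (1 + s[0] * xi[0]) * (1 + s[2] * xi[2])
            dN[n, 2] = 0.125 * s[2] * (1 + s[0] * xi[0]) * (1 + s[1] * xi[1])
        dN *= scale
        B = np.zeros((6, 24))
        for n in range(8):
            col = 3 * n
            B[0, col] = dN[n, 0]
            B[1, col + 1] = dN[n, 1]
            B[2, col + 2] = dN[n, 2]
            B[3, col + 1] = dN[n, 2]
            B[3, col + 2] = dN[n, 1]
            B[4, col] = dN[n, 2]
            B[4, col + 2] = dN[n, 0]
            B[5, col] = dN[n, 1]
            B[5, col + 1] = dN[n, 0]
        return B

    B_gauss = np.stack([b_at(xi) for xi in gauss])
    B_centroid = b_at(np.zeros(3))
    det_j = a * b * c / 8.0
    return B_gauss, B_centroid, det_j


def hex_stiffness(material: Material, edge_lengths: np.ndarray) -> np.ndarray:
    """24x24 element stiffness of a rectangular trilinear hexahedron."""
    edge_lengths = np.asarray(edge_lengths, dtype=float)
    if np.any(edge_lengths <= 0):
        raise ValueError("edge lengths must be positive")
    C = material.stiffness()
    B, _, det_j = _shape_gradients(edge_lengths)
    K = np.einsum("gki,kl,glj->ij", B, C, B) * det_j
    return 0.5 * (K + K.T)


def _element_stiffnesses(mesh: HexMesh) -> np.ndarray:
    """(n_el, 24, 24) stack; shares memory for a single-material mesh."""
    B, _, det_j = _shape_gradients(mesh.edge_lengths)
    if isinstance(mesh.materials, Material):
        K = np.einsum("gki,kl,glj->ij", B, mesh.materials.stiffness(), B) * det_j
        return np.broadcast_to(K, (mesh.n_elements, 24, 24))
    C = np.stack([m.stiffness() for m in mesh.material_list()])
    K = np.einsum("gki,ekl,glj->eij", B, C, B) * det_j
    return K


def _assemble_cached(mesh: HexMesh) -> sparse.csr_matrix:
    """Assembled global stiffness, cached on the mesh object (meshes are
    treated as immutable once solved)."""
    cached = getattr(mesh, "_assembled_stiffness", None)
    if cached is None:
        cached = _assemble(mesh)
        mesh._assembled_stiffness = cached
    return cached


def _factorize_cached(mesh: HexMesh, Kff, pres_dofs: np.ndarray):
    key = pres_dofs.tobytes()
    cache = getattr(mesh, "_factor_cache", None)
    if cache is None:
        cache = {}
        mesh._factor_cache = cache
    if key not in cache:
        cache[key] = splu(Kff.tocsc())
    return cache[key]


def _assemble(mesh: HexMesh) -> sparse.csr_matrix:
    Ke = _element_stiffnesses(mesh)
    dofs = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(mesh.n_elements, 24)
    rows = np.repeat(dofs, 24, axis=1).ravel()
    cols = np.tile(dofs, (1, 24)).ravel()
    n_dof = 3 * mesh.n_nodes
    K = sparse.coo_matrix(
        (np.ascontiguousarray(Ke).ravel(), (rows, cols)), shape=(n_dof, n_dof)
    )
    return K.tocsr()


def _check_connected(mesh: HexMesh, constrained_nodes: np.ndarray) -> None:
    """Every element component must contain a constrained node, else the
    reduced system is singular (floating region)."""
    el = mesh.elements
    rows = np.repeat(np.arange(mesh.n_elements), 8)
    adj = sparse.coo_matrix(
        (np.ones(rows.size), (rows, el.ravel())),
        shape=(mesh.n_elements, mesh.n_nodes),
    ).tocsr()
    graph = adj @ adj.T
    n_comp, labels = csgraph.connected_components(graph, directed=False)
    if n_comp == 1:
        return
    node_labels = np.full(mesh.n_nodes, -1)
    node_labels[el.ravel()] = np.repeat(labels, 8)
    anchored = set(node_labels[constrained_nodes]) - {-1}
    floating = sorted(set(range(n_comp)) - anchored)
    if floating:
        sizes = np.bincount(labels, minlength=n_comp)
        raise ValueError(
            f"singular system: {len(floating)} floating component(s) without "
            f"constraints, e.g. component {floating[0]} with {sizes[floating[0]]} "
            "element(s)"
        )


def solve(mesh: HexMesh, lc: LoadCase) -> FESolution:
    """Solve the displacement-controlled linear system and post-process.

    Uses a sparse direct factorization for small systems and diagonally
    preconditioned conjugate gradients (relative residual <= 1e-8) above
    ``_DIRECT_DOF_LIMIT`` free DOFs.
    """
    n_dof = 3 * mesh.n_nodes
    pres_dofs, pres_vals = lc.dof_arrays(mesh.n_nodes)
    if pres_dofs.size < 9:
        raise ValueError("load case must constrain at least 3 nodes (9 DOFs)")
    constrained_nodes = np.unique(pres_dofs // 3)
    _check_connected(mesh, constrained_nodes)

    K = _assemble_cached(mesh)
    free = np.ones(n_dof, dtype=bool)
    free[pres_dofs] = False
    free_idx = np.flatnonzero(free)

    u = np.zeros(n_dof)
    u[pres_dofs] = pres_vals

    if free_idx.size:
        Kff = K[free_idx][:, free_idx]
        rhs = -K[free_idx][:, pres_dofs] @ pres_vals
        if np.any(pres_vals) and free_idx.size:
            if free_idx.size <= _DIRECT_DOF_LIMIT:
                u[free_idx] = _factorize_cached(mesh, Kff, pres_dofs).solve(rhs)
            else:
                M = sparse.diags(1.0 / Kff.diagonal())
                uf, info = cg(Kff, rhs, M=M, rtol=_CG_RTOL, atol=0.0, maxiter=20_000)
                if info != 0:
                    res = np.linalg.norm(Kff @ uf - rhs) / np.linalg.norm(rhs)
                    raise RuntimeError(
                        f"CG did not converge (info={info}, rel. residual {res:.2e})"
                    )
                u[free_idx] = uf

    nodal_forces = (K @ u).reshape(-1, 3)

    _, B0, _ = _shape_gradients(mesh.edge_lengths)
    u_el = u.reshape(-1, 3)[mesh.elements].reshape(mesh.n_elements, 24)
    strain = u_el @ B0.T
    if isinstance(mesh.materials, Material):
        stress = strain @ mesh.materials.stiffness().T
    else:
        C = np.stack([m.stiffness() for m in mesh.material_list()])
        stress = np.einsum("eij,ej->ei", C, strain)
    sed = 0.5 * np.einsum("ei,ei->e", stress, strain)
    sed = np.maximum(sed, 0.0)  # guard tiny negative round-off

    if lc.reaction_nodes.size:
        reaction = nodal_forces[lc.reaction_nodes].sum(axis=0)
    else:
        reaction = np.zeros(3)

    return FESolution(
        load_case=lc.name,
        displacements=u.reshape(-1, 3),
        strain=strain,
        stress=stress,
        sed=sed,
        reaction=reaction,
        nodal_forces=nodal_forces,
    )


def _plane_nodes(mesh: HexMesh, axis: int, value: float, tol: float) -> np.ndarray:
    return np.flatnonzero(np.abs(mesh.node_coords[:, axis] - value) < tol)


def canonical_section_loadcases(
    mesh: HexMesh,
    magnitude: float = 0.01,
    fully_prescribed: bool = False,
) -> list[LoadCase]:
    """Three displacement load cases on a section between two axis-3 planes.

    LC1/LC2 shear the distal (max-3) plane by ``magnitude`` mm along +1/+2;
    LC3 compresses it by ``magnitude`` mm along -3.  Proximal (min-3) nodes
    are fixed in all components.  By default the distal nodes are
    constrained only along the load direction; ``fully_prescribed`` pins
    all three components of the distal nodes instead.
    """
    lo, hi = mesh.bounding_box()
    tol = 1e-6 * max(mesh.edge_lengths.max(), 1.0)
    proximal = _plane_nodes(mesh, 2, lo[2], tol)
    distal = _plane_nodes(mesh, 2, hi[2], tol)
    if proximal.size == 0 or distal.size == 0:
        raise ValueError("could not identify proximal/distal node planes")

    vectors = {
        "shear-1": np.array([magnitude, 0.0, 0.0]),
        "shear-2": np.array([0.0, magnitude, 0.0]),
        "compression-3": np.array([0.0, 0.0, -magnitude]),
    }
    all_fixed = np.ones(3, dtype=bool)
    cases = []
    for name, vec in vectors.items():
        mask = all_fixed if fully_prescribed else vec != 0.0
        # magnitude 0 still needs an anchored load direction
        if not mask.any():
            mask = np.array([name == "shear-1", name == "shear-2", "3" in name])
        prescribed: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for node in proximal:
            prescribed[int(node)] = (all_fixed, np.zeros(3))
        for node in distal:
            if int(node) in prescribed:
                raise ValueError("distal and proximal planes overlap")
            prescribed[int(node)] = (mask, vec)
        cases.append(LoadCase(name=name, prescribed=prescribed, reaction_nodes=distal))
    return cases
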