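"""Density/fabric material mapping for homogenized FE models.

Relative density is sampled with spheres centered at element centroids;
materials follow power laws in density (isotropic) or density and fabric
eigenvalues (orthotropic, Zysset-Curnier family).  Fabric is estimated from
binary images by the mean intercept length (MIL) method with an ellipsoid
fit; eigenvalues are normalized to determinant one (m1 m2 m3 = 1).

The standard compliance-based Zysset-Curnier parameterization is used:
E_i = E0 rho^k m_i^(2l), G_ij = mu0 rho^k m_i^l m_j^l,
nu_ij = nu0 m_i^l / m_j^l.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from boneibr.fesolver import HexMesh, Material
from boneibr.image import VoxelImage

__all__ = [
    "BaseConstants",
    "FabricTensor",
    "TRABECULAR_FABRIC",
    "TRABECULAR_DENSITY",
    "CORTICAL_DENSITY",
    "sample_density",
    "density_material",
    "zysset_curnier_material",
    "mil_fabric",
    "build_hfe_model",
]

DEFAULT_DENSITY_THRESHOLD = 0.01


@dataclass(frozen=True)
class BaseConstants:
    """Elastic base constants of a power-law material mapping.

    ``E0``/``mu0`` in MPa, ``k`` the density exponent; ``nu0`` and the
    fabric exponent ``l`` are present only for the density+fabric model.
    For density-only mappings the Poisson ratio is implied:
    ``nu = E0 / (2 mu0) - 1``.
    """

    name: str
    E0: float
    mu0: float
    k: float
    nu0: float | None = None
    l: float | None = None

    def __post_init__(self) -> None:
        if self.E0 <= 0 or self.mu0 <= 0 or self.k <= 0:
            raise ValueError("E0, mu0, k must be positive")

    @property
    def implied_nu(self) -> float:
        return self.E0 / (2 * self.mu0) - 1


TRABECULAR_FABRIC = BaseConstants(
    name="trabecular-fabric", E0=10_320.4, mu0=3470.7, nu0=0.2278, k=1.62, l=1.1
)
TRABECULAR_DENSITY = BaseConstants(name="trabecular-density", E0=8812.8, mu0=3536.0, k=1.63)
CORTICAL_DENSITY = BaseConstants(name="cortical-density", E0=12_000.0, mu0=4615.4, k=1.63)


@dataclass
class FabricTensor:
    """Symmetric positive-definite fabric with determinant-one eigenvalues."""

    eigenvalues: np.ndarray  # (3,) descending not required; m1 m2 m3 = 1
    eigenvectors: np.ndarray  # 3x3, columns = principal directions

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if np.any(self.eigenvalues <= 0):
            raise ValueError("fabric eigenvalues must be positive")
        if not np.allclose(np.prod(self.eigenvalues), 1.0, rtol=1e-6):
            raise ValueError("fabric eigenvalues must have product 1")
        if not np.allclose(
            self.eigenvectors.T @ self.eigenvectors, np.eye(3), atol=1e-8
        ):
            raise ValueError("fabric eigenvectors must be orthonormal")

    @classmethod
    def isotropic(cls) -> "FabricTensor":
        return cls(eigenvalues=np.ones(3), eigenvectors=np.eye(3))

    def as_matrix(self) -> np.ndarray:
        return self.eigenvectors @ np.diag(self.eigenvalues) @ self.eigenvectors.T

    @property
    def degree_of_anisotropy(self) -> float:
        return float(self.eigenvalues.max() / self.eigenvalues.min())


def sample_density(
    binary: VoxelImage,
    centroids: np.ndarray,
    sphere_diameter: float,
) -> np.ndarray:
    """Bone volume fraction inside a sphere around each centroid (mm).

    A voxel belongs to the sphere when its center lies within the radius of
    the (continuous) centroid position.  The sphere is clipped to the image
    domain; centroids whose sphere does not overlap the image are an error.
    """
    values = np.asarray(binary.values)
    radius_vox = 0.5 * sphere_diameter / binary.spacing
    if radius_vox < 0.5:
        raise ValueError("sphere_diameter must exceed the voxel size")
    r_int = int(np.ceil(radius_vox))
    box = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1, -r_int : r_int + 1]
    box = box.reshape(3, -1).T
    # voxel-center coordinates in voxel units: i + 0.5 - origin-offset
    centers_vox = (np.atleast_2d(centroids) - binary.origin) / binary.spacing - 0.5
    shape = np.array(values.shape)
    rho = np.empty(centers_vox.shape[0])
    for e, c in enumerate(centers_vox):
        vox = np.rint(c).astype(int) + box
        d2 = np.einsum("ij,ij->i", vox - c, vox - c)
        in_sphere = d2 <= radius_vox**2
        inside = in_sphere & np.all((vox >= 0) & (vox < shape), axis=1)
        if not inside.any():
            raise ValueError(f"sampling sphere at {centroids[e]} lies outside the image")
        sel = vox[inside]
        rho[e] = values[sel[:, 0], sel[:, 1], sel[:, 2]].mean()
    return np.clip(rho, 0.0, 1.0)


def density_material(rho: float, constants: BaseConstants) -> Material:
    """Isotropic power-law material ``E = E0 rho^k`` with the implied
    constant Poisson ratio ``nu = E0 / (2 mu0) - 1``."""
    if not 0 < rho <= 1:
        raise ValueError("rho must be in (0, 1]; drop empty elements")
    return Material(kind="isotropic", E=constants.E0 * rho**constants.k, nu=constants.implied_nu)


def zysset_curnier_material(
    rho: float, fabric: FabricTensor, constants: BaseConstants
) -> Material:
    """Orthotropic density+fabric material in the fabric eigenbasis."""
    if not 0 < rho <= 1:
        raise ValueError("rho must be in (0, 1]")
    if constants.nu0 is None or constants.l is None:
        raise ValueError(f"constants {constants.name!r} lack nu0/l for the fabric model")
    m = fabric.eigenvalues
    l, k = constants.l, constants.k
    scale = rho**k
    E = constants.E0 * scale * m ** (2 * l)
    ml = m**l
    G = constants.mu0 * scale * np.array([ml[1] * ml[2], ml[0] * ml[2], ml[0] * ml[1]])
    nu = constants.nu0 * np.array([ml[1] / ml[2], ml[0] / ml[2], ml[0] / ml[1]])
    mat = Material(kind="orthotropic", E3=E, G3=G, nu3=nu, axes=fabric.eigenvectors)
    mat.stiffness()  # raises if the resulting stiffness is not SPD
    return mat


# integer lattice offset families, unbiased and symmetric under axis
# permutation/reflection (one representative per +/- pair)
_OFFSET_FAMILIES = [
    [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    [(1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1)],
    [(1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1)],
    [
        (2, 1, 0), (2, -1, 0), (1, 2, 0), (1, -2, 0),
        (2, 0, 1), (2, 0, -1), (1, 0, 2), (1, 0, -2),
        (0, 2, 1), (0, 2, -1), (0, 1, 2), (0, 1, -2),
    ],
    [
        (2, 1, 1), (2, 1, -1), (2, -1, 1), (2, -1, -1),
        (1, 2, 1), (1, 2, -1), (-1, 2, 1), (-1, 2, -1),
        (1, 1, 2), (1, -1, 2), (-1, 1, 2), (-1, -1, 2),
    ],
]


def _lattice_directions(n_directions: int) -> list[tuple[int, int, int]]:
    offsets: list[tuple[int, int, int]] = []
    for family in _OFFSET_FAMILIES:
        offsets.extend(family)
        if len(offsets) >= n_directions:
            break
    return offsets


def _shifted_overlap(values: np.ndarray, offset: tuple[int, int, int]):
    """Views of ``values`` and its copy shifted by an integer offset."""
    src, dst = [], []
    for d, n in zip(offset, values.shape):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    return values[tuple(src)], values[tuple(dst)]


def mil_fabric(
    binary: VoxelImage,
    region: tuple[slice, slice, slice] | None = None,
    n_directions: int = 13,
) -> FabricTensor:
    """MIL fabric tensor of a binary region.

    For each lattice direction, the expected number of phase changes per
    unit length is estimated by comparing the image against a copy shifted
    by an exact integer offset; the mean intercept length is
    ``2 rho / changes-per-length``.  ``MIL(n)`` is fitted by an ellipsoid
    ``n^T H n = 1 / MIL^2`` and the fabric is ``H^(-1/2)`` normalized to
    determinant one.  Deterministic for a fixed direction count.
    """
    if n_directions < 9:
        raise ValueError("need at least 9 directions for the ellipsoid fit")
    values = np.asarray(binary.values) >= 0.5
    if region is not None:
        values = values[region]
    rho = values.mean()
    if rho == 0.0 or rho == 1.0:
        raise ValueError("fabric undefined: region contains a single phase")

    offsets = _lattice_directions(n_directions)
    mil_cap = max(values.shape) * binary.spacing
    directions, mil = [], []
    for off in offsets:
        length = float(np.linalg.norm(off)) * binary.spacing
        a, b = _shifted_overlap(values, off)
        changes = np.mean(a != b) / length
        mil.append(2.0 * rho / changes if changes > 0 else mil_cap)
        directions.append(np.asarray(off, dtype=float) / np.linalg.norm(off))
    directions = np.stack(directions)
    mil = np.minimum(np.asarray(mil), mil_cap)

    # ellipsoid fit n^T H n = 1 / MIL^2
    n1, n2, n3 = directions.T
    A = np.stack([n1**2, n2**2, n3**2, 2 * n2 * n3, 2 * n1 * n3, 2 * n1 * n2], axis=1)
    h, *_ = np.linalg.lstsq(A, 1.0 / mil**2, rcond=None)
    H = np.array(
        [
            [h[0], h[5], h[4]],
            [h[5], h[1], h[3]],
            [h[4], h[3], h[2]],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(H)
    if eigvals.max() <= 0:
        raise ValueError("MIL ellipsoid fit is not positive definite")
    # extreme structures (e.g. ideal plate stacks) give a nearly singular
    # ellipsoid; floor the eigenvalues to keep the fabric finite
    eigvals = np.maximum(eigvals, 1e-4 * eigvals.max())
    m = 1.0 / np.sqrt(eigvals)
    m /= np.prod(m) ** (1.0 / 3.0)
    return FabricTensor(eigenvalues=m, eigenvectors=eigvecs)


def build_hfe_model(
    image: VoxelImage,
    element_size: float,
    mapping: str = "density",
    constants: BaseConstants | None = None,
    cortex_mask: np.ndarray | None = None,
    cortex_constants: BaseConstants = CORTICAL_DENSITY,
    sphere_diameter: float | None = None,
    density_threshold: float = DEFAULT_DENSITY_THRESHOLD,
) -> HexMesh:
    """Coarse regular hex grid over the image with mapped materials.

    Per-element density comes from sphere sampling at the centroid; elements
    below ``density_threshold`` are dropped.  ``mapping`` is ``"density"``
    (isotropic power law) or ``"density+fabric"`` (Zysset-Curnier with local
    MIL fabric).  ``cortex_mask`` flags coarse-grid cells (same grid layout)
    to be mapped with the cortical constants instead.
    """
    if mapping not in ("density", "density+fabric"):
        raise ValueError(f"unknown mapping {mapping!r}")
    if constants is None:
        constants = TRABECULAR_FABRIC if mapping == "density+fabric" else TRABECULAR_DENSITY
    if element_size <= 2 * image.spacing:
        raise ValueError("element_size must be much larger than the voxel spacing")
    if sphere_diameter is None:
        sphere_diameter = 2.0 * element_size

    extent = image.physical_extent()
    n_el = np.maximum(np.round(extent / element_size).astype(int), 1)
    edges = extent / n_el

    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in n_el), indexing="ij")
    cells = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    centroids = (cells + 0.5) * edges + image.origin
    rho = sample_density(image, centroids, sphere_diameter)

    keep = rho >= density_threshold
    if not keep.any():
        raise ValueError("all elements below the density threshold")
    cells, centroids, rho = cells[keep], centroids[keep], rho[keep]
    is_cortex = np.zeros(len(cells), dtype=bool)
    if cortex_mask is not None:
        is_cortex = np.asarray(cortex_mask).reshape(tuple(n_el))[
            cells[:, 0], cells[:, 1], cells[:, 2]
        ]

    rho_mat = np.minimum(rho, 1.0)
    materials: list[Material] = []
    for e in range(len(cells)):
        consts = cortex_constants if is_cortex[e] else constants
        if mapping == "density" or is_cortex[e]:
            materials.append(density_material(rho_mat[e], consts))
        else:
            materials.append(
                zysset_curnier_material(rho_mat[e], _local_fabric(image, centroids[e], sphere_diameter), consts)
            )

    # shared nodes on the coarse grid
    grid_n = n_el + 1

    def nid(c):
        return (c[:, 0] * grid_n[1] + c[:, 1]) * grid_n[2] + c[:, 2]

    corner_offsets = np.array(
        [
            [0, 0, 0],
            [1, 0, 0],
            [1, 1, 0],
            [0, 1, 0],
            [0, 0, 1],
            [1, 0, 1],
            [1, 1, 1],
            [0, 1, 1],
        ]
    )
    corners = np.stack([nid(cells + off) for off in corner_offsets], axis=1)
    used, elements = np.unique(corners, return_inverse=True)
    elements = elements.reshape(corners.shape).astype(np.int64)
    gi, rem = np.divmod(used, grid_n[1] * grid_n[2])
    gj, gk = np.divmod(rem, grid_n[2])
    node_coords = np.stack([gi, gj, gk], axis=1) * edges + image.origin

    return HexMesh(
        node_coords=node_coords.astype(float),
        elements=elements,
        materials=materials,
        element_volume=np.full(len(cells), float(np.prod(edges))),
        edge_lengths=edges,
        element_density=rho_mat,
    )


def _local_fabric(image: VoxelImage, centroid: np.ndarray, diameter: float) -> FabricTensor:
    """MIL fabric of the cubic neighbourhood around a centroid; isotropic
    fallback when the neighbourhood holds a single phase."""
    half = int(np.ceil(0.5 * diameter / image.spacing))
    c = np.rint((centroid - image.origin) / image.spacing - 0.5).astype(int)
    lo = np.maximum(c - half, 0)
    hi = np.minimum(c + half + 1, np.array(image.shape))
    region = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    try:
        return mil_fabric(image, region=region)
    except ValueError:
        return FabricTensor.isotropic()
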