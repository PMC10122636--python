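"""KUBC homogenization of microstructure cubes.

Affine displacements ``u = E_bar x`` are prescribed on every bone-phase node
on the cube boundary.  Apparent stress is averaged over the TOTAL cube
volume (pores contribute zero stress), which makes ``<sigma>:<eps>`` the
apparent continuum energy consistent with relative density as BV/TV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from boneibr.fesolver import FESolution, HexMesh, LoadCase

__all__ = [
    "CubeHomogenizationResult",
    "kubc_loadcases",
    "apparent_quantities",
    "optimized_continuum_stimulus",
    "apparent_stiffness",
]

# load-case order: three uniaxial (11, 22, 33), three shear (23, 13, 12)
_SHEAR_PAIRS = [(1, 2), (0, 2), (0, 1)]


@dataclass
class CubeHomogenizationResult:
    """Per-cube homogenization and IBR summary."""

    density: float  # BV/TV
    mean_stress: np.ndarray  # (6, 3, 3) volume-averaged stress per case, MPa
    mean_strain: np.ndarray  # (6, 3, 3) applied macroscopic strain per case
    mean_tissue_sed: np.ndarray  # (6,) bone-phase mean SED per case, MPa
    scales: np.ndarray | None = None  # IBR scale factors s_i
    u_opt: float | None = None  # optimized continuum stimulus, MPa
    cv_before: float | None = None
    cv_after: float | None = None


def _macroscopic_strains(displacement: float, edge: float, tensor_shear: bool = True):
    """Six canonical macroscopic strain tensors for face displacement ``d``.

    Uniaxial case k: ``E_kk = d / L``; shear case (k, l): tensor shear
    ``E_kl = d / (2 L)`` so the face tangential displacement magnitude is
    ``|d|`` (set ``tensor_shear=False`` for ``E_kl = d / L``).
    """
    eps = displacement / edge
    strains = []
    for k in range(3):
        E = np.zeros((3, 3))
        E[k, k] = eps
        strains.append(E)
    shear = eps / 2 if tensor_shear else eps
    for k, l in _SHEAR_PAIRS:
        E = np.zeros((3, 3))
        E[k, l] = E[l, k] = shear
        strains.append(E)
    return strains


def kubc_loadcases(
    mesh: HexMesh,
    face_displacement: float = -0.001,
    tensor_shear: bool = True,
) -> list[LoadCase]:
    """Six canonical KUBC load cases (three uniaxial, three shear).

    Every bone-phase node on the bounding-cube boundary (faces, edges and
    corners) is prescribed ``u = E_bar x``.  The domain must be cubic.
    """
    lo, hi = mesh.bounding_box()
    extent = hi - lo
    if not np.allclose(extent, extent[0], rtol=1e-9):
        raise ValueError(f"non-cubic mesh: extents {extent}")
    L = float(extent[0])
    tol = 1e-9 * max(L, 1.0)
    x = mesh.node_coords
    on_boundary = np.zeros(mesh.n_nodes, dtype=bool)
    for axis in range(3):
        on_boundary |= np.abs(x[:, axis] - lo[axis]) < tol
        on_boundary |= np.abs(x[:, axis] - hi[axis]) < tol
    boundary = np.flatnonzero(on_boundary)

    names = ["uniaxial-11", "uniaxial-22", "uniaxial-33", "shear-23", "shear-13", "shear-12"]
    all_fixed = np.ones(3, dtype=bool)
    cases = []
    for name, E_bar in zip(names, _macroscopic_strains(face_displacement, L, tensor_shear)):
        u_affine = (x[boundary] - lo) @ E_bar.T
        prescribed = {
            int(n): (all_fixed, u_affine[i]) for i, n in enumerate(boundary)
        }
        cases.append(
            LoadCase(
                name=name,
                prescribed=prescribed,
                reaction_nodes=boundary,
                macroscopic_strain=E_bar,
            )
        )
    return cases


def apparent_quantities(
    solutions: list[FESolution],
    strains: list[np.ndarray],
    mesh: HexMesh,
    total_volume: float,
) -> CubeHomogenizationResult:
    """Volume-averaged stress, a-priori strain, density and tissue SED.

    ``strains`` are the applied macroscopic strain tensors (exact averages
    under KUBC); ``total_volume`` is the full cube volume including pores.
    """
    if total_volume <= 0:
        raise ValueError("total_volume must be positive")
    if len(solutions) != len(strains):
        raise ValueError("need one macroscopic strain per solution")
    V = mesh.element_volume
    rho = float(V.sum() / total_volume)
    mean_stress, mean_sed = [], []
    for sol in solutions:
        sig = V @ sol.stress / total_volume  # Voigt, over total volume
        mean_stress.append(_voigt_to_tensor(sig))
        mean_sed.append(float(V @ sol.sed / V.sum()))
    return CubeHomogenizationResult(
        density=rho,
        mean_stress=np.stack(mean_stress) if mean_stress else np.zeros((0, 3, 3)),
        mean_strain=(
            np.stack([np.asarray(E) for E in strains])
            if strains
            else np.zeros((0, 3, 3))
        ),
        mean_tissue_sed=np.array(mean_sed),
    )


def optimized_continuum_stimulus(
    scales: np.ndarray,
    mean_stress: np.ndarray,
    mean_strain: np.ndarray,
) -> float:
    """``0.5 * sum_i s_i <sigma_i> : <eps_i>`` in MPa."""
    scales = np.asarray(scales, dtype=float)
    mean_stress = np.asarray(mean_stress, dtype=float)
    mean_strain = np.asarray(mean_strain, dtype=float)
    if not (len(scales) == len(mean_stress) == len(mean_strain)):
        raise ValueError("scales, stresses and strains must have equal length")
    if np.any(scales < 0):
        raise ValueError("scale factors must be non-negative")
    contraction = np.einsum("ikl,ikl->i", mean_stress, mean_strain)
    return float(0.5 * scales @ contraction)


def apparent_stiffness(result: CubeHomogenizationResult) -> np.ndarray:
    """6x6 apparent stiffness in Voigt notation from the six KUBC cases.

    Column j is the Voigt stress response divided by the applied strain
    amplitude (engineering shear for the shear columns).
    """
    C = np.zeros((6, 6))
    for j in range(6):
        E = result.mean_strain[j]
        sig = _tensor_to_voigt(result.mean_stress[j])
        if j < 3:
            amp = E[j, j]
        else:
            k, l = _SHEAR_PAIRS[j - 3]
            amp = 2 * E[k, l]  # engineering shear
        C[:, j] = sig / amp
    return C


def _voigt_to_tensor(v: np.ndarray) -> np.ndarray:
    return np.array(
        [
            [v[0], v[5], v[4]],
            [v[5], v[1], v[3]],
            [v[4], v[3], v[2]],
        ]
    )


def _tensor_to_voigt(t: np.ndarray) -> np.ndarray:
    return np.array([t[0, 0], t[1, 1], t[2, 2], t[1, 2], t[0, 2], t[0, 1]])
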