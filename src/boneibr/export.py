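"""Text exports: legacy-VTK unstructured grids, Abaqus INP, CSV tables."""

from __future__ import annotations

import json
import os

import numpy as np

from boneibr.fesolver import FESolution, HexMesh

__all__ = ["write_vtk", "write_inp", "write_solution_csv", "write_reaction_json"]


def write_vtk(
    mesh: HexMesh,
    path: str | os.PathLike,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Legacy ASCII VTK unstructured grid with optional per-cell scalars."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nboneibr mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.node_coords:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"CELLS {mesh.n_elements} {mesh.n_elements * 9}\n")
        for el in mesh.elements:
            fh.write("8 " + " ".join(str(int(n)) for n in el) + "\n")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        fh.write("12\n" * mesh.n_elements)  # VTK_HEXAHEDRON
        if cell_data:
            fh.write(f"CELL_DATA {mesh.n_elements}\n")
            for name, values in cell_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(values, dtype=float):
                    fh.write(f"{v:.9g}\n")


def write_inp(mesh: HexMesh, path: str | os.PathLike, rho_bin: float = 0.01) -> None:
    """Abaqus INP dialect: C3D8 elements, 1-based ids, one isotropic material
    card per density bucket (densities binned at ``rho_bin`` resolution)."""
    materials = mesh.material_list()
    rho = mesh.element_density
    if rho is None:
        rho = np.ones(mesh.n_elements)
    buckets = np.round(rho / rho_bin).astype(int)
    with open(path, "w") as fh:
        fh.write("*HEADING\nboneibr hexahedral mesh\n*NODE\n")
        for i, p in enumerate(mesh.node_coords, start=1):
            fh.write(f"{i}, {p[0]:.9g}, {p[1]:.9g}, {p[2]:.9g}\n")
        for b in np.unique(buckets):
            sel = np.flatnonzero(buckets == b)
            fh.write(f"*ELEMENT, TYPE=C3D8, ELSET=RHO{b}\n")
            for e in sel:
                nodes = ", ".join(str(int(n) + 1) for n in mesh.elements[e])
                fh.write(f"{e + 1}, {nodes}\n")
        for b in np.unique(buckets):
            e0 = int(np.flatnonzero(buckets == b)[0])
            mat = materials[e0]
            fh.write(f"*MATERIAL, NAME=MAT_RHO{b}\n*ELASTIC\n")
            if mat.kind == "isotropic":
                fh.write(f"{mat.E:.9g}, {mat.nu:.9g}\n")
            else:
                # engineering constants line for *ELASTIC, TYPE=ENGINEERING CONSTANTS
                E1, E2, E3 = mat.E3
                G23, G13, G12 = mat.G3
                nu23, nu13, nu12 = mat.nu3
                fh.write(
                    f"{E1:.9g}, {E2:.9g}, {E3:.9g}, {nu12:.9g}, {nu13:.9g}, "
                    f"{nu23:.9g}, {G12:.9g}, {G13:.9g}\n{G23:.9g}\n"
                )
            fh.write(f"*SOLID SECTION, ELSET=RHO{b}, MATERIAL=MAT_RHO{b}\n")


def write_solution_csv(
    mesh: HexMesh, solution: FESolution, path: str | os.PathLike
) -> None:
    """Per-element table: id, density, SED, stress and strain components."""
    import pandas as pd

    rho = mesh.element_density
    if rho is None:
        rho = np.ones(mesh.n_elements)
    cols = {"element": np.arange(mesh.n_elements), "rho": rho, "sed": solution.sed}
    names = ["11", "22", "33", "23", "13", "12"]
    for i, n in enumerate(names):
        cols[f"stress_{n}"] = solution.stress[:, i]
    for i, n in enumerate(names):
        cols[f"strain_{n}"] = solution.strain[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_reaction_json(solutions: list[FESolution], path: str | os.PathLike) -> None:
    payload = {
        sol.load_case: {"reaction_N": [float(v) for v in sol.reaction]}
        for sol in solutions
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
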