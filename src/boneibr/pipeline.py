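"""End-to-end drivers: cube calibration study and section comparison study.

Workflow A (cubes): microstructure cube -> 6 KUBC micro-FE solves ->
tissue-level IBR -> optimized continuum stimulus per cube -> power-law
exponent calibration over the cube set.

Workflow B (sections): one phantom -> micro-FE model (tissue target) and
coarse homogenized model (continuum target) -> 3 canonical load cases each
-> optimally scaled reaction forces -> comparison metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from boneibr.fesolver import Material, canonical_section_loadcases, image_to_mesh, solve
from boneibr.homogenize import (
    CubeHomogenizationResult,
    apparent_quantities,
    kubc_loadcases,
    optimized_continuum_stimulus,
)
from boneibr.ibr import (
    DEFAULT_TISSUE_STIMULUS,
    IBRProblem,
    IBRResult,
    StimulusModel,
    calibrate_exponent,
    continuum_target,
    ibr_solve,
    tissue_target,
)
from boneibr.matmap import TRABECULAR_DENSITY, TRABECULAR_FABRIC, build_hfe_model
from boneibr.metrics import angle_score, magnitude_score, off_axis_angle
from boneibr.synth import PhantomSpec, generate_grf_cube, generate_section_phantom

__all__ = ["StudyConfig", "run_cube_study", "run_section_study", "section_ibr"]


@dataclass
class StudyConfig:
    """Numerical parameters of the two study workflows."""

    tissue_modulus: float = 12_000.0  # MPa, micro-FE tissue material
    tissue_poisson: float = 0.3
    tissue_stimulus: float = DEFAULT_TISSUE_STIMULUS  # MPa
    kubc_displacement: float = -0.001  # mm
    section_displacement: float = 0.01  # mm
    exponent: float | None = None  # None -> calibrate or use default 1.19
    hfe_element_size: float = 1.0  # mm
    hfe_mapping: str = "density"  # or "density+fabric"

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        return cls(**json.loads(text))


def _tissue_material(config: StudyConfig) -> Material:
    return Material(kind="isotropic", E=config.tissue_modulus, nu=config.tissue_poisson)


def homogenize_cube(
    spec: PhantomSpec, config: StudyConfig
) -> CubeHomogenizationResult:
    """Generate one cube, run the six KUBC cases and tissue-level IBR."""
    image = generate_grf_cube(spec)
    mesh = image_to_mesh(image, material=_tissue_material(config))
    cases = kubc_loadcases(mesh, face_displacement=config.kubc_displacement)
    solutions = [solve(mesh, lc) for lc in cases]
    total_volume = float(np.prod(image.physical_extent()))
    result = apparent_quantities(
        solutions, [lc.macroscopic_strain for lc in cases], mesh, total_volume
    )
    problem = IBRProblem(
        sed=np.stack([sol.sed for sol in solutions]),
        volumes=mesh.element_volume,
        target=tissue_target(mesh.n_elements, config.tissue_stimulus),
    )
    ibr = ibr_solve(problem)
    result.scales = ibr.scales
    result.u_opt = optimized_continuum_stimulus(
        ibr.scales, result.mean_stress, result.mean_strain
    )
    result.cv_before = ibr.cv_before
    result.cv_after = ibr.cv_after
    return result


def run_cube_study(
    specs: list[PhantomSpec], config: StudyConfig | None = None
) -> tuple[StimulusModel, list[CubeHomogenizationResult]]:
    """Calibrate the continuum stimulus exponent over a set of cubes."""
    config = config or StudyConfig()
    results = [homogenize_cube(spec, config) for spec in specs]
    model = calibrate_exponent(
        np.array([r.density for r in results]),
        np.array([r.u_opt for r in results]),
        stimulus=config.tissue_stimulus,
    )
    return model, results


def section_ibr(mesh, config: StudyConfig, level: str) -> IBRResult:
    """Run the three canonical load cases and IBR on a section mesh.

    ``level`` is ``"tissue"`` (constant target, micro-FE) or ``"continuum"``
    (density-dependent target and density-normalized CV, homogenized FE).
    """
    cases = canonical_section_loadcases(mesh, magnitude=config.section_displacement)
    solutions = [solve(mesh, lc) for lc in cases]
    sed = np.stack([sol.sed for sol in solutions])
    forces = np.stack([sol.reaction for sol in solutions])
    if level == "tissue":
        target = tissue_target(mesh.n_elements, config.tissue_stimulus)
        normalizer = None
    elif level == "continuum":
        model = StimulusModel(
            stimulus=config.tissue_stimulus,
            exponent=config.exponent if config.exponent is not None else 1.19,
        )
        rho = np.minimum(mesh.element_density, 1.0)
        target = continuum_target(rho, model)
        normalizer = rho**model.exponent
    else:
        raise ValueError(f"unknown IBR level {level!r}")
    problem = IBRProblem(sed=sed, volumes=mesh.element_volume, target=target)
    return ibr_solve(problem, forces=forces, cv_normalizer=normalizer)


def run_section_study(
    spec: PhantomSpec, config: StudyConfig | None = None
) -> dict:
    """Compare micro-FE IBR against homogenized-FE IBR on one phantom.

    Returns a JSON-serializable report with per-model forces, angles and
    the pairwise similarity scores.
    """
    config = config or StudyConfig()
    image = generate_section_phantom(spec)

    micro_mesh = image_to_mesh(image, material=_tissue_material(config))
    micro = section_ibr(micro_mesh, config, level="tissue")

    hfe_mesh = build_hfe_model(
        image,
        element_size=config.hfe_element_size,
        mapping=config.hfe_mapping,
        constants=TRABECULAR_FABRIC if config.hfe_mapping == "density+fabric" else TRABECULAR_DENSITY,
    )
    hfe = section_ibr(hfe_mesh, config, level="continuum")

    report = {
        "config": asdict(config),
        "micro_fe": _ibr_report(micro),
        "hfe": _ibr_report(hfe),
        "comparison": {
            "angle_score_unit": angle_score(micro.f_unit, hfe.f_unit),
            "magnitude_score_unit": magnitude_score(micro.f_unit, hfe.f_unit),
            "angle_score_opt": _safe_angle_score(micro.f_opt, hfe.f_opt),
            "magnitude_score_opt": magnitude_score(micro.f_opt, hfe.f_opt),
        },
    }
    return report


def _safe_angle_score(a, b) -> float | None:
    try:
        return angle_score(a, b)
    except ValueError:
        return None


def _ibr_report(result: IBRResult) -> dict:
    f_opt = result.f_opt
    return {
        "scales": [float(s) for s in result.scales],
        "alphas": [float(a) for a in result.alphas],
        "residual": float(result.residual),
        "cv_before": float(result.cv_before),
        "cv_after": float(result.cv_after),
        "f_unit_N": [float(v) for v in result.f_unit],
        "f_opt_N": [float(v) for v in f_opt],
        "off_axis_angle_unit_deg": off_axis_angle(result.f_unit),
        "off_axis_angle_opt_deg": (
            off_axis_angle(f_opt) if np.linalg.norm(f_opt) > 0 else None
        ),
    }
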