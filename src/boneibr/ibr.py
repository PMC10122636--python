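"""Inverse bone (re)modeling optimization core.

Given per-element strain energy densities ``U_ie`` of ``n`` unit load cases,
find non-negative scale factors ``s_i`` minimizing the volume-weighted
squared deviation from a target stimulus:

    r(s) = sum_e V_e (sum_i s_i U_ie - U_target_e)^2

This is a non-negative least squares problem on the system with row ``e``
scaled by ``sqrt(V_e)``.  Load scale factors follow as ``alpha_i =
sqrt(n s_i)``.  The target is either a constant tissue stimulus or the
density-dependent continuum stimulus ``U0 * rho^d``; the exponent ``d`` is
calibrated from (density, optimized stimulus) pairs by 1D least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar, nnls

__all__ = [
    "IBRProblem",
    "IBRResult",
    "StimulusModel",
    "tissue_target",
    "continuum_target",
    "ibr_solve",
    "scaled_sed",
    "coefficient_of_variation",
    "scale_forces",
    "calibrate_exponent",
    "effective_strain",
]

DEFAULT_TISSUE_STIMULUS = 0.02  # MPa
DEFAULT_EXPONENT = 1.19


@dataclass
class StimulusModel:
    """Continuum target stimulus ``U0 * rho^d``.

    ``stimulus`` (U0, MPa) equals the tissue-level target so the model is
    compatible with the tissue stimulus at full density; ``exponent`` (d)
    is dimensionless.
    """

    stimulus: float = DEFAULT_TISSUE_STIMULUS
    exponent: float = DEFAULT_EXPONENT
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if not self.stimulus > 0:
            raise ValueError("stimulus must be positive")

    def target(self, density: np.ndarray) -> np.ndarray:
        return continuum_target(density, self)


@dataclass
class IBRProblem:
    """Discrete optimization inputs: ``sed[i, e]`` per load case and element,
    element volumes and the per-element target stimulus (all MPa / mm^3)."""

    sed: np.ndarray  # (n_cases, n_elements), >= 0
    volumes: np.ndarray  # (n_elements,), > 0
    target: np.ndarray  # (n_elements,), >= 0

    def __post_init__(self) -> None:
        self.sed = np.atleast_2d(np.asarray(self.sed, dtype=float))
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        n, m = self.sed.shape
        if self.volumes.shape != (m,) or self.target.shape != (m,):
            raise ValueError("inconsistent problem dimensions")
        if np.any(self.sed < 0) or np.any(self.volumes <= 0) or np.any(self.target < 0):
            raise ValueError("sed/target must be >= 0 and volumes > 0")

    @property
    def n_cases(self) -> int:
        return self.sed.shape[0]

    def residual(self, scales: np.ndarray) -> float:
        """r(s) = sum_e V_e (sum_i s_i U_ie - target_e)^2."""
        misfit = np.asarray(scales) @ self.sed - self.target
        return float(self.volumes @ misfit**2)


@dataclass
class IBRResult:
    """Optimized scale factors and derived quantities."""

    scales: np.ndarray  # s_i >= 0
    alphas: np.ndarray  # alpha_i = sqrt(n s_i)
    residual: float
    cv_before: float
    cv_after: float
    f_unit: np.ndarray | None = None  # (3,) N
    f_opt: np.ndarray | None = None  # (3,) N


def tissue_target(n_elements: int, stimulus: float = DEFAULT_TISSUE_STIMULUS) -> np.ndarray:
    """Constant tissue-level target stimulus vector (MPa)."""
    if not stimulus > 0:
        raise ValueError("tissue stimulus must be positive")
    return np.full(n_elements, float(stimulus))


def continuum_target(density: np.ndarray, model: StimulusModel) -> np.ndarray:
    """Density-dependent continuum target ``U0 * rho^d`` per element.

    Densities above 1 (possible from sampling-sphere mapping near the
    cortex) are clamped to 1 with a warning; non-positive densities are an
    error because such elements should not exist.
    """
    rho = np.asarray(density, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("element density must be positive")
    if np.any(rho > 1):
        warnings.warn("densities > 1 clamped to 1 for the continuum target")
        rho = np.minimum(rho, 1.0)
    return model.stimulus * rho**model.exponent


def ibr_solve(
    problem: IBRProblem,
    forces: np.ndarray | None = None,
    cv_normalizer: np.ndarray | None = None,
) -> IBRResult:
    """Solve the volume-weighted NNLS problem (Lawson-Hanson active set).

    ``forces`` (n_cases, 3) are optional per-case reaction forces used to
    report unit-scaled and optimally scaled force sums.  ``cv_normalizer``
    divides the scaled SED before computing the CV (used at the continuum
    level with ``rho^d``).
    """
    n, m = problem.sed.shape
    if m < n:
        raise ValueError("need at least as many elements as load cases")
    if not np.any(problem.sed > 0):
        raise ValueError("no load case stimulates the structure")
    w = np.sqrt(problem.volumes)
    A = (problem.sed * w).T  # (m, n)
    b = problem.target * w
    scales, _ = nnls(A, b)
    alphas = np.sqrt(n * scales)

    cv_before = coefficient_of_variation(
        scaled_sed(problem, np.ones(n)), problem.volumes, cv_normalizer
    )
    cv_after = coefficient_of_variation(
        scaled_sed(problem, scales), problem.volumes, cv_normalizer
    )
    f_unit = f_opt = None
    if forces is not None:
        f_unit, f_opt = scale_forces(forces, alphas)
    return IBRResult(
        scales=scales,
        alphas=alphas,
        residual=problem.residual(scales),
        cv_before=cv_before,
        cv_after=cv_after,
        f_unit=f_unit,
        f_opt=f_opt,
    )


def scaled_sed(problem: IBRProblem, scales: np.ndarray) -> np.ndarray:
    """Per-element scaled SED ``sum_i s_i U_ie``.

    This is the method's definition of the combined stimulus -- a linear
    combination of per-case SED fields, NOT the SED of the superposed
    displacement field (cross terms are deliberately ignored).
    """
    return np.asarray(scales, dtype=float) @ problem.sed


def coefficient_of_variation(
    values: np.ndarray,
    volumes: np.ndarray,
    normalizer: np.ndarray | None = None,
) -> float:
    """Volume-weighted population CV = weighted std / weighted mean.

    With ``normalizer`` (e.g. ``rho^d``), the CV is computed on
    ``values / normalizer`` so that "homogeneous" means "at target
    everywhere" for heterogeneous density.
    """
    values = np.asarray(values, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if values.size < 2:
        raise ValueError("CV needs at least 2 elements")
    if normalizer is not None:
        values = values / np.asarray(normalizer, dtype=float)
    wsum = volumes.sum()
    mean = values @ volumes / wsum
    if mean == 0:
        return 0.0
    var = volumes @ (values - mean) ** 2 / wsum
    return float(np.sqrt(var) / mean)


def scale_forces(forces: np.ndarray, alphas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-scaled and optimally scaled reaction force sums.

    ``F_unit = sum_i F_i`` and ``F_opt = sum_i alpha_i F_i``.
    """
    forces = np.atleast_2d(np.asarray(forces, dtype=float))
    alphas = np.asarray(alphas, dtype=float)
    if forces.shape[0] != alphas.shape[0]:
        raise ValueError("one alpha per force required")
    return forces.sum(axis=0), alphas @ forces


def calibrate_exponent(
    densities: np.ndarray,
    stimuli: np.ndarray,
    stimulus: float = DEFAULT_TISSUE_STIMULUS,
    bounds: tuple[float, float] = (0.0, 5.0),
) -> StimulusModel:
    """Fit the density exponent ``d`` of ``U0 * rho^d`` to (rho, U_opt) data.

    ``U0`` is fixed to the tissue stimulus (compatibility at rho = 1); only
    ``d`` is fitted, by bounded 1D least squares with a Newton polish when
    the minimum is interior.  Also reports the coefficient of determination.
    """
    rho = np.asarray(densities, dtype=float)
    u = np.asarray(stimuli, dtype=float)
    if rho.size < 2 or np.unique(rho).size < 2:
        raise ValueError("exponent unidentifiable: need >= 2 distinct densities")
    if np.any(rho <= 0) or np.any(rho > 1):
        raise ValueError("densities must lie in (0, 1]")
    log_rho = np.log(rho)

    def sse(d: float) -> float:
        return float(np.sum((u - stimulus * rho**d) ** 2))

    res = minimize_scalar(sse, bounds=bounds, method="bounded", options={"xatol": 1e-10})
    d = float(res.x)
    lo, hi = bounds
    if sse(lo) <= sse(d):
        d = lo
    elif sse(hi) <= sse(d):
        d = hi
    if lo < d < hi:
        # Newton polish on the stationarity condition of the SSE
        for _ in range(20):
            p = stimulus * rho**d
            r = u - p
            g = -2 * np.sum(r * p * log_rho)
            h = 2 * np.sum(p * log_rho**2 * (2 * p - u))
            if h <= 0 or not np.isfinite(h):
                break
            step = g / h
            d_new = min(max(d - step, lo), hi)
            if abs(d_new - d) < 1e-14:
                d = d_new
                break
            d = d_new

    prediction = stimulus * rho**d
    ss_res = float(np.sum((u - prediction) ** 2))
    ss_tot = float(np.sum((u - u.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return StimulusModel(stimulus=stimulus, exponent=d, r_squared=r2)


def effective_strain(stimulus: float, modulus: float) -> float:
    """Uniaxial strain whose energy density ``0.5 E eps^2`` equals the
    stimulus: ``eps = sqrt(2 U / E)`` (dimensionless; x1e6 = microstrain)."""
    if stimulus < 0 or modulus <= 0:
        raise ValueError("stimulus must be >= 0 and modulus > 0")
    return float(np.sqrt(2.0 * stimulus / modulus))
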