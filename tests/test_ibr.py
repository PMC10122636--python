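import numpy as np
import pytest

from boneibr.ibr import (
    IBRProblem,
    StimulusModel,
    calibrate_exponent,
    coefficient_of_variation,
    continuum_target,
    effective_strain,
    ibr_solve,
    scale_forces,
    scaled_sed,
    tissue_target,
)


def nnls_oracle(A, b):
    """Enumerate all active sets of the NNLS problem min |As - b|, s >= 0.

    Independent of the production path: for every subset of variables
    allowed to be positive, solve the unconstrained least squares problem
    and keep the best feasible candidate.
    """
    n = A.shape[1]
    best, best_res = np.zeros(n), float(np.dot(b, b))
    for mask in range(1, 2**n):
        idx = [i for i in range(n) if mask >> i & 1]
        s_sub, *_ = np.linalg.lstsq(A[:, idx], b, rcond=None)
        if np.any(s_sub < -1e-12):
            continue
        s = np.zeros(n)
        s[idx] = np.maximum(s_sub, 0.0)
        res = float(np.sum((A @ s - b) ** 2))
        if res < best_res:
            best, best_res = s, res
    return best, best_res


class TestTargets:
    def test_tissue_target(self):
        np.testing.assert_allclose(tissue_target(3, 0.02), [0.02, 0.02, 0.02])

    def test_tissue_target_rejects_zero(self):
        with pytest.raises(ValueError):
            tissue_target(3, 0.0)

    def test_tissue_target_empty(self):
        assert tissue_target(0, 0.02).size == 0

    def test_continuum_full_density(self):
        model = StimulusModel(stimulus=0.02, exponent=1.19)
        assert continuum_target(np.array([1.0]), model)[0] == pytest.approx(0.02)

    def test_continuum_power_law(self):
        model = StimulusModel(stimulus=0.02, exponent=1.19)
        expected = 0.02 * 0.25**1.19
        assert continuum_target(np.array([0.25]), model)[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.841e-3, rel=1e-3)

    def test_continuum_d_zero_reduces_to_tissue(self, rng):
        rho = rng.uniform(0.05, 1.0, 20)
        model = StimulusModel(stimulus=0.02, exponent=0.0)
        np.testing.assert_array_equal(continuum_target(rho, model), tissue_target(20, 0.02))

    def test_continuum_rejects_nonpositive(self):
        model = StimulusModel()
        with pytest.raises(ValueError):
            continuum_target(np.array([0.0]), model)

    def test_continuum_clamps_above_one(self):
        model = StimulusModel(stimulus=0.02, exponent=1.19)
        with pytest.warns(UserWarning, match="clamped"):
            out = continuum_target(np.array([1.4]), model)
        assert out[0] == pytest.approx(0.02)


class TestIbrSolve:
    def test_single_uniform_case(self):
        problem = IBRProblem(
            sed=np.full((1, 5), 0.004), volumes=np.ones(5), target=np.full(5, 0.02)
        )
        result = ibr_solve(problem)
        assert result.scales[0] == pytest.approx(5.0, rel=1e-12)
        assert result.residual == pytest.approx(0.0, abs=1e-20)
        assert result.alphas[0] == pytest.approx(np.sqrt(5.0), rel=1e-12)

    def test_duplicated_case_degenerate(self):
        u = np.full(6, 0.004)
        problem = IBRProblem(
            sed=np.stack([u, u]), volumes=np.ones(6), target=np.full(6, 0.02)
        )
        result = ibr_solve(problem)
        assert result.scales.sum() == pytest.approx(5.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 3, 12
        A_raw = rng.uniform(0, 1, (n, m))
        V = rng.uniform(0.5, 2.0, m)
        target = np.full(m, 0.02)
        # make some problems unbalanced so zero scales appear
        A_raw[0] *= rng.uniform(0.5, 20)
        problem = IBRProblem(sed=A_raw, volumes=V, target=target)
        result = ibr_solve(problem)
        w = np.sqrt(V)
        _, res_oracle = nnls_oracle((A_raw * w).T, target * w)
        assert problem.residual(result.scales) <= res_oracle + 1e-6 * max(res_oracle, 1e-12)

    def test_kkt_conditions(self, rng):
        n, m = 4, 30
        problem = IBRProblem(
            sed=rng.uniform(0, 1, (n, m)) * rng.uniform(0.1, 10, (n, 1)),
            volumes=rng.uniform(0.5, 2.0, m),
            target=np.full(m, 0.02),
        )
        result = ibr_solve(problem)
        w = problem.volumes
        grad = 2 * (problem.sed * w) @ (result.scales @ problem.sed - problem.target)
        # scale from the problem data, not the (possibly ~zero) gradient
        scale = 2 * np.abs((problem.sed * w) @ problem.target).max()
        active = result.scales > 1e-12
        assert np.all(np.abs(grad[active]) <= 1e-6 * scale)
        assert np.all(grad[~active] >= -1e-6 * scale)

    def test_never_worse_than_unit(self, rng):
        for _ in range(20):
            n = rng.integers(1, 5)
            m = rng.integers(n, 50)
            problem = IBRProblem(
                sed=rng.uniform(0, 0.01, (n, m)),
                volumes=rng.uniform(0.1, 3.0, m),
                target=np.full(m, 0.02),
            )
            result = ibr_solve(problem)
            assert result.residual <= problem.residual(np.ones(n)) + 1e-15

    def test_optimality_probing(self, rng):
        problem = IBRProblem(
            sed=rng.uniform(0, 0.01, (3, 20)),
            volumes=rng.uniform(0.1, 3.0, 20),
            target=np.full(20, 0.02),
        )
        result = ibr_solve(problem)
        for _ in range(1000):
            probe = np.abs(result.scales + rng.normal(0, 0.1, 3))
            assert problem.residual(probe) >= result.residual - 1e-12

    def test_all_zero_sed_error(self):
        problem = IBRProblem(
            sed=np.zeros((2, 5)), volumes=np.ones(5), target=np.full(5, 0.02)
        )
        with pytest.raises(ValueError, match="no load case stimulates"):
            ibr_solve(problem)

    def test_alpha_roundtrip(self, rng):
        n = 4
        problem = IBRProblem(
            sed=rng.uniform(0, 0.01, (n, 20)),
            volumes=np.ones(20),
            target=np.full(20, 0.02),
        )
        result = ibr_solve(problem)
        np.testing.assert_allclose(result.alphas**2 / n, result.scales, rtol=1e-14)

    def test_volume_weighting_split_elements(self, rng):
        # duplicating an element as two half-volume copies leaves s unchanged
        n, m = 3, 10
        sed = rng.uniform(0, 0.01, (n, m))
        V = rng.uniform(0.5, 2.0, m)
        target = rng.uniform(0.01, 0.03, m)
        split_sed = np.concatenate([sed, sed[:, :1]], axis=1)
        split_V = np.concatenate([V, [V[0] / 2]])
        split_V[0] /= 2
        split_target = np.concatenate([target, target[:1]])
        r1 = ibr_solve(IBRProblem(sed=sed, volumes=V, target=target))
        r2 = ibr_solve(IBRProblem(sed=split_sed, volumes=split_V, target=split_target))
        np.testing.assert_allclose(r1.scales, r2.scales, rtol=1e-9, atol=1e-12)

    def test_continuum_d0_bitwise_equals_tissue(self, rng):
        sed = rng.uniform(0, 0.01, (3, 15))
        V = rng.uniform(0.5, 2.0, 15)
        rho = rng.uniform(0.1, 1.0, 15)
        t_tissue = tissue_target(15, 0.02)
        t_cont = continuum_target(rho, StimulusModel(stimulus=0.02, exponent=0.0))
        r1 = ibr_solve(IBRProblem(sed=sed, volumes=V, target=t_tissue))
        r2 = ibr_solve(IBRProblem(sed=sed, volumes=V, target=t_cont))
        assert (r1.scales == r2.scales).all()


class TestScaledSedAndCV:
    def test_unit_scales(self, rng):
        sed = rng.uniform(0, 1, (3, 8))
        problem = IBRProblem(sed=sed, volumes=np.ones(8), target=np.full(8, 0.02))
        np.testing.assert_allclose(scaled_sed(problem, np.ones(3)), sed.sum(axis=0))
        np.testing.assert_allclose(scaled_sed(problem, np.zeros(3)), 0.0)
        np.testing.assert_allclose(
            scaled_sed(problem, 2 * np.ones(3)), 2 * sed.sum(axis=0)
        )

    def test_cv_uniform_zero(self):
        assert coefficient_of_variation(np.full(5, 3.0), np.ones(5)) == 0.0

    def test_cv_hand_computed(self):
        # two equal-volume elements, U = (1, 3): mean 2, population sd 1
        assert coefficient_of_variation(np.array([1.0, 3.0]), np.ones(2)) == pytest.approx(0.5)

    def test_cv_scale_invariant(self, rng):
        u = rng.uniform(0.1, 1, 30)
        v = rng.uniform(0.5, 2, 30)
        assert coefficient_of_variation(u, v) == pytest.approx(
            coefficient_of_variation(7.3 * u, v), rel=1e-12
        )

    def test_cv_normalizer(self, rng):
        u = rng.uniform(0.1, 1, 30)
        rho = rng.uniform(0.2, 1, 30)
        v = np.ones(30)
        direct = coefficient_of_variation(u / rho**1.19, v)
        assert coefficient_of_variation(u, v, normalizer=rho**1.19) == pytest.approx(direct)

    def test_cv_needs_two_elements(self):
        with pytest.raises(ValueError):
            coefficient_of_variation(np.array([1.0]), np.array([1.0]))


class TestScaleForces:
    def test_unit_alphas(self, rng):
        F = rng.normal(size=(3, 3))
        f_unit, f_opt = scale_forces(F, np.ones(3))
        np.testing.assert_allclose(f_unit, f_opt)

    def test_zero_alphas(self, rng):
        F = rng.normal(size=(3, 3))
        _, f_opt = scale_forces(F, np.zeros(3))
        np.testing.assert_allclose(f_opt, 0.0)

    def test_arithmetic(self):
        F = np.array([[1, 0, 0], [0, 2, 0], [0, 0, 3]], dtype=float)
        f_unit, f_opt = scale_forces(F, np.array([2.0, 1.0, 0.0]))
        np.testing.assert_allclose(f_unit, [1, 2, 3])
        np.testing.assert_allclose(f_opt, [2, 2, 0])

    def test_mismatch(self):
        with pytest.raises(ValueError):
            scale_forces(np.zeros((3, 3)), np.ones(2))


class TestCalibrateExponent:
    def test_noiseless_recovery(self):
        rho = np.linspace(0.1, 0.6, 12)
        model = calibrate_exponent(rho, 0.02 * rho**1.5, stimulus=0.02)
        assert model.exponent == pytest.approx(1.5, abs=1e-6)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(42)
        rho = rng.uniform(0.05, 0.6, 200)
        u = 0.02 * rho**1.19 * np.exp(rng.normal(0.0, 0.05, 200))
        model = calibrate_exponent(rho, u, stimulus=0.02)
        assert model.exponent == pytest.approx(1.19, abs=0.05)

    def test_constant_data_gives_zero(self):
        rho = np.linspace(0.2, 0.8, 10)
        model = calibrate_exponent(rho, np.full(10, 0.02), stimulus=0.02)
        assert model.exponent == pytest.approx(0.0, abs=1e-6)

    def test_identical_densities_error(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            calibrate_exponent(np.full(5, 0.3), np.linspace(0.001, 0.01, 5))

    def test_default_printed_exponent(self):
        # the shipped default continuum model
        model = StimulusModel()
        assert model.exponent == pytest.approx(1.19)
        assert model.stimulus == pytest.approx(0.02)


class TestEffectiveStrain:
    def test_tissue_stimulus_microstrain(self):
        eps = effective_strain(0.02, 12_000.0)
        assert round(eps * 1e6) == 1826

    def test_inverse(self):
        eps = effective_strain(0.01, 6800.0)
        assert 0.5 * 6800.0 * eps**2 == pytest.approx(0.01, rel=1e-12)

    def test_invalid(self):
        with pytest.raises(ValueError):
            effective_strain(0.02, 0.0)
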