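import numpy as np
import pytest

from corehole2 import (
    DFTensors,
    ScalingSpec,
    SolverOptions,
    build_effective_matrix,
    cis_d_ionization,
    generate_fixture,
    sigma_apply,
    solve_adc2,
)
from corehole2.exceptions import ConvergenceError


def toy_fixed_point_by_bisection(tol=1e-13):
    """Independent scalar oracle for the toy system: solve
    omega = 10 + s / (omega - 11) by bisection, where
    s = 2(V1^2 + V2^2 - V1 V2) = 0.0152 is the hand-contracted numerator."""
    s = 0.0152

    def f(w):
        return w - (10.0 + s / (w - 11.0))

    lo, hi = 9.5, 10.5
    assert f(lo) * f(hi) < 0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestSigmaApply:
    def test_zero_couplings_reduce_to_koopmans_diagonal(self):
        df = DFTensors(
            J_CC=np.zeros((2, 2, 2)),
            J_CO=np.zeros((2, 2, 3)),
            J_CV=np.zeros((2, 2, 4)),
            J_OV=np.zeros((2, 3, 4)),
        )
        eps_c = np.array([-10.0, -9.9])
        sigma = sigma_apply(
            np.array([1.0, 0.0]), 10.0, df, eps_c,
            np.linspace(-1, -0.4, 3), np.linspace(0.3, 1.5, 4), ScalingSpec(1, 1),
        )
        np.testing.assert_allclose(sigma, [10.0, 0.0], atol=1e-15)

    def test_toy_sigma_matches_perturbative_contraction(self, toy_t1):
        """For one core orbital, sigma at fixed omega is the Koopmans term
        plus the perturbative correction at that same omega."""
        _, _, df = toy_t1
        sigma = sigma_apply(
            np.array([1.0]), 10.0, df,
            np.array([-10.0]), np.array([-0.5]), np.array([0.5]), ScalingSpec(1, 1),
        )
        assert sigma[0] == pytest.approx(10.0 - 0.0152, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_folded_jacobian_is_symmetric_bilinear_form(self, seed):
        """c1 . sigma(c2) == c2 . sigma(c1) at fixed omega."""
        system = generate_fixture((3, 5, 5, 7), seed=seed)
        rng = np.random.default_rng(seed + 500)
        c1, c2 = rng.standard_normal((2, 3))
        args = (system.df, system.eps_core, system.eps_inact, system.eps_virt,
                ScalingSpec(1, 1))
        omega = -float(np.mean(system.eps_core))
        s2 = sigma_apply(c2, omega, *args)
        s1 = sigma_apply(c1, omega, *args)
        assert abs(c1 @ s2 - c2 @ s1) < 1e-10


class TestEffectiveMatrix:
    def test_koopmans_limit_is_diagonal(self):
        system = generate_fixture((3, 4, 4, 5), seed=0)
        eff = build_effective_matrix(
            10.0, system.df, system.eps_core, system.eps_inact, system.eps_virt,
            ScalingSpec(0, 0),
        )
        np.testing.assert_allclose(eff.M, np.diag(-system.eps_core), atol=1e-15)

    def test_toy_matrix_is_the_folded_scalar(self, toy_t1):
        _, _, df = toy_t1
        eff = build_effective_matrix(
            10.0, df, np.array([-10.0]), np.array([-0.5]), np.array([0.5]),
            ScalingSpec(1, 1),
        )
        assert eff.M[0, 0] == pytest.approx(9.9848, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 3, 8])
    def test_multicore_matrix_symmetric(self, seed):
        system = generate_fixture((2, 5, 4, 6), seed=seed)
        eff = build_effective_matrix(
            9.8, system.df, system.eps_core, system.eps_inact, system.eps_virt,
            ScalingSpec(1, 1),
        )
        assert np.max(np.abs(eff.M - eff.M.T)) < 1e-10


class TestSolveAdc2:
    def test_koopmans_limit_converges_in_one_iteration(self, toy_t1):
        ref, partition, df = toy_t1
        (state,) = solve_adc2(ref, partition, df, ScalingSpec(0, 0))
        assert state.omega == -ref.orbital_energies[0]
        assert state.iterations == 1

    def test_toy_fixed_point_matches_bisection_oracle(self, toy_t1):
        ref, partition, df = toy_t1
        (state,) = solve_adc2(
            ref, partition, df, ScalingSpec(1, 1), SolverOptions(omega_tol=1e-12)
        )
        assert state.omega == pytest.approx(toy_fixed_point_by_bisection(), abs=1e-9)
        assert state.omega == pytest.approx(9.98502, abs=1e-5)
        assert state.converged

    def test_fixed_point_independent_of_damping(self, toy_t1):
        ref, partition, df = toy_t1
        tol = 1e-9
        a = solve_adc2(
            ref, partition, df, ScalingSpec(1, 1),
            SolverOptions(omega_tol=tol, damping=0.0),
        )[0].omega
        b = solve_adc2(
            ref, partition, df, ScalingSpec(1, 1),
            SolverOptions(omega_tol=tol, damping=0.3, max_macro_iterations=200),
        )[0].omega
        assert abs(a - b) < 10 * tol

    def test_single_macro_step_reproduces_cis_d(self, toy_t1):
        """Freezing the fold-in energy at -eps_K for exactly one evaluation
        recovers the perturbative result for a single-core system."""
        ref, partition, df = toy_t1
        eff = build_effective_matrix(
            -ref.orbital_energies[0], df,
            np.array([-10.0]), np.array([-0.5]), np.array([0.5]), ScalingSpec(1, 1),
        )
        cisd = cis_d_ionization(ref, partition, df, ScalingSpec(1, 1))[0].omega
        assert eff.M[0, 0] == pytest.approx(cisd, abs=1e-14)

    def test_nonconvergence_raises_with_diagnostics(self, toy_t1):
        ref, partition, df = toy_t1
        with pytest.raises(ConvergenceError):
            solve_adc2(
                ref, partition, df, ScalingSpec(1, 1),
                SolverOptions(omega_tol=1e-14, max_macro_iterations=2),
            )
        results = solve_adc2(
            ref, partition, df, ScalingSpec(1, 1),
            SolverOptions(
                omega_tol=1e-14, max_macro_iterations=2, raise_on_nonconvergence=False
            ),
        )
        assert not results[0].converged

    @pytest.mark.parametrize("seed", [1, 4])
    def test_invariant_under_aux_and_inactive_reordering(self, seed):
        """Permuting the auxiliary channels and the inactive-orbital ordering
        (consistently across energies and J blocks) leaves omega unchanged."""
        system = generate_fixture((2, 5, 4, 6), seed=seed)
        ref, part = system.reference(), system.partition()
        opts = SolverOptions(omega_tol=1e-10)
        base = [s.omega for s in solve_adc2(ref, part, system.df, ScalingSpec(1, 1), opts)]

        rng = np.random.default_rng(seed)
        p_aux = rng.permutation(system.df.n_aux)
        p_in = rng.permutation(system.df.n_inact)
        df2 = DFTensors(
            J_CC=system.df.J_CC[p_aux],
            J_CO=system.df.J_CO[p_aux][:, :, p_in],
            J_CV=system.df.J_CV[p_aux],
            J_OV=system.df.J_OV[p_aux][:, p_in, :],
        )
        eps = np.concatenate(
            [system.eps_core, system.eps_inact[p_in], system.eps_virt]
        )
        from corehole2 import OrbitalPartition, ScfReference

        ref2 = ScfReference(orbital_energies=eps, n_occupied=ref.n_occupied)
        part2 = OrbitalPartition(
            frozen=(),
            active_core=part.active_core,
            inactive_occ=part.inactive_occ,
            virtual=part.virtual,
        )
        permuted = [s.omega for s in solve_adc2(ref2, part2, df2, ScalingSpec(1, 1), opts)]
        np.testing.assert_allclose(permuted, base, atol=1e-8)
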