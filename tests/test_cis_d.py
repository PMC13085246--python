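import numpy as np
import pytest

from corehole2 import (
    DFTensors,
    ScalingSpec,
    ScfReference,
    build_v_perturbative,
    cis_d_ionization,
    d_correction,
    doubles_coefficients,
    ip_cis,
)
from corehole2.exceptions import PartitionError, SingularDenominatorError

EPS = dict(eps_core=np.array([-10.0]), eps_inact=np.array([-0.5]), eps_virt=np.array([0.5]))


class TestIpCis:
    def test_koopmans_sign_flip(self, toy_t1):
        ref, partition, _ = toy_t1
        (state,) = ip_cis(ref, partition)
        assert state.omega == -ref.orbital_energies[0] == 10.0
        np.testing.assert_array_equal(state.singles_vector, [1.0])

    def test_two_states_in_ascending_orbital_order(self):
        ref = ScfReference(
            orbital_energies=np.array([-20.0, -19.9, -0.5, 0.5]),
            n_occupied=3,
        )
        from corehole2 import OrbitalPartition

        part = OrbitalPartition(
            frozen=(), active_core=(0, 1), inactive_occ=(2,), virtual=(3,)
        )
        states = ip_cis(ref, part)
        assert [s.omega for s in states] == [20.0, 19.9]

    def test_ks_reference_follows_the_same_rule(self, toy_t1):
        """For a KS reference the ionization energy is still the negative
        orbital energy: no XC evaluation happens after the SCF."""
        ref, partition, _ = toy_t1
        ks = ScfReference(
            orbital_energies=ref.orbital_energies.copy(),
            n_occupied=ref.n_occupied,
            reference_kind="KS",
            functional_tag="PBE",
        )
        assert ip_cis(ks, partition)[0].omega == ip_cis(ref, partition)[0].omega == 10.0


class TestBuildVPerturbative:
    def test_toy_hand_values(self, toy_t1):
        _, _, df = toy_t1
        V = build_v_perturbative(df, 0)
        assert V.V_cja[0, 0, 0] == pytest.approx(-0.10, abs=1e-15)
        assert V.V_caj[0, 0, 0] == pytest.approx(-0.06, abs=1e-15)

    def test_zero_blocks_give_zero_couplings(self):
        df = DFTensors(
            J_CC=np.zeros((2, 1, 1)),
            J_CO=np.zeros((2, 1, 1)),
            J_CV=np.zeros((2, 1, 1)),
            J_OV=np.zeros((2, 1, 1)),
        )
        V = build_v_perturbative(df, 0)
        assert not V.V_cja.any() and not V.V_caj.any()

    def test_bilinear_in_auxiliary_channels(self, toy_t1):
        """Couplings from two auxiliary channels are the sum of the
        per-channel couplings."""
        _, _, df = toy_t1
        rng = np.random.default_rng(2)
        extra = {
            name: rng.standard_normal(getattr(df, name).shape)
            for name in ("J_CC", "J_CO", "J_CV", "J_OV")
        }
        extra["J_CC"] = 0.5 * (extra["J_CC"] + extra["J_CC"].transpose(0, 2, 1))
        df_extra = DFTensors(**extra)
        df_both = DFTensors(
            **{
                name: np.concatenate([getattr(df, name), extra[name]], axis=0)
                for name in extra
            }
        )
        V_a = build_v_perturbative(df, 0)
        V_b = build_v_perturbative(df_extra, 0)
        V_ab = build_v_perturbative(df_both, 0)
        np.testing.assert_allclose(V_ab.V_cja, V_a.V_cja + V_b.V_cja, atol=1e-14)
        np.testing.assert_allclose(V_ab.V_caj, V_a.V_caj + V_b.V_caj, atol=1e-14)

    def test_target_outside_active_block_rejected(self, toy_t1):
        _, _, df = toy_t1
        with pytest.raises(PartitionError):
            build_v_perturbative(df, 1)


class TestDoublesCoefficients:
    def test_toy_hand_values(self, toy_t1):
        _, _, df = toy_t1
        V = build_v_perturbative(df, 0)
        c2 = doubles_coefficients(V, omega=10.0, **EPS)
        assert c2.c_cja[0, 0, 0] == pytest.approx(0.10, abs=1e-15)
        assert c2.c_caj[0, 0, 0] == pytest.approx(0.06, abs=1e-15)
        assert c2.omega_used == 10.0

    def test_zero_couplings_give_zero_coefficients(self, toy_t1):
        _, _, df = toy_t1
        V = build_v_perturbative(df, 0)
        V.V_cja[:] = 0.0
        V.V_caj[:] = 0.0
        c2 = doubles_coefficients(V, omega=10.0, **EPS)
        assert not c2.c_cja.any() and not c2.c_caj.any()

    def test_singular_denominator_names_the_triple(self, toy_t1):
        _, _, df = toy_t1
        V = build_v_perturbative(df, 0)
        with pytest.raises(SingularDenominatorError) as err:
            doubles_coefficients(V, omega=11.0, **EPS)  # D = -10 - 0.5 - 0.5 + 11 = 0
        assert err.value.triple == (0, 0, 0)


class TestDCorrection:
    def test_toy_unscaled_value(self, toy_t1):
        _, _, df = toy_t1
        V = build_v_perturbative(df, 0)
        c2 = doubles_coefficients(V, omega=10.0, **EPS)
        assert d_correction(V, c2, ScalingSpec(1, 1)) == pytest.approx(-0.0152, abs=1e-12)

    def test_toy_sos_value(self, toy_t1):
        _, _, df = toy_t1
        V = build_v_perturbative(df, 0)
        c2 = doubles_coefficients(V, omega=10.0, **EPS)
        assert d_correction(V, c2, ScalingSpec(1.3, 0)) == pytest.approx(-0.01768, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_os_ss_channels_recombine_bilinearly(self, seed):
        from corehole2 import generate_fixture

        system = generate_fixture((2, 4, 4, 6), seed=seed)
        V = build_v_perturbative(system.df, 1)
        c2 = doubles_coefficients(
            V, system.eps_core, system.eps_inact, system.eps_virt,
            omega=-system.eps_core[1],
        )
        full = d_correction(V, c2, ScalingSpec(1, 1))
        os_only = d_correction(V, c2, ScalingSpec(1, 0))
        ss_only = d_correction(V, c2, ScalingSpec(0, 1))
        assert abs(full - (os_only + ss_only)) < 1e-12

    def test_invariant_under_aux_channel_sign_flip(self):
        """The correction is quadratic in each auxiliary channel's J vectors,
        so flipping any channel's sign leaves it unchanged."""
        from corehole2 import generate_fixture

        system = generate_fixture((1, 3, 3, 4), seed=9)
        V = build_v_perturbative(system.df, 0)
        c2 = doubles_coefficients(
            V, system.eps_core, system.eps_inact, system.eps_virt,
            omega=-system.eps_core[0],
        )
        base = d_correction(V, c2, ScalingSpec(1, 1))
        flipped = {
            name: getattr(system.df, name).copy() for name in ("J_CC", "J_CO", "J_CV", "J_OV")
        }
        for name in flipped:
            flipped[name][2] *= -1.0  # flip one auxiliary channel everywhere
        df_f = DFTensors(**flipped)
        V_f = build_v_perturbative(df_f, 0)
        c2_f = doubles_coefficients(
            V_f, system.eps_core, system.eps_inact, system.eps_virt,
            omega=-system.eps_core[0],
        )
        assert abs(d_correction(V_f, c2_f, ScalingSpec(1, 1)) - base) < 1e-12


class TestCisDIonization:
    def test_toy_total_energy(self, toy_t1):
        ref, partition, df = toy_t1
        (state,) = cis_d_ionization(ref, partition, df, ScalingSpec(1, 1))
        assert state.omega == pytest.approx(9.9848, abs=1e-12)
        assert state.correction == pytest.approx(-0.0152, abs=1e-12)

    def test_koopmans_limit_is_exact(self, toy_t1):
        ref, partition, df = toy_t1
        (state,) = cis_d_ionization(ref, partition, df, ScalingSpec(0, 0))
        assert state.omega == -ref.orbital_energies[0]

    def test_hf_and_ks_references_with_same_arrays_agree(self, toy_t1):
        ref, partition, df = toy_t1
        ks = ScfReference(
            orbital_energies=ref.orbital_energies.copy(),
            n_occupied=ref.n_occupied,
            reference_kind="KS",
            functional_tag="PBE",
        )
        a = cis_d_ionization(ref, partition, df, ScalingSpec(1, 1))[0].omega
        b = cis_d_ionization(ks, partition, df, ScalingSpec(1, 1))[0].omega
        assert a == b
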