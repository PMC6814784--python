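"""Strain energy, stresses, branch switching, tone and swelling."""

import numpy as np
import pytest

from aortasph import materials as mats
from aortasph.constitutive import (
    active_stress,
    fiber_invariant,
    gag_stress,
    passive_energy,
    passive_stress,
    select_branch,
    total_piola,
    viscous_stress,
)
from aortasph.materials import MaterialParams, build_material_state, donnan_pressure

from .conftest import random_F


def single_state(group, params=None, **over):
    params = params or MaterialParams(**over)
    er = np.array([[1.0, 0.0]])
    et = np.array([[0.0, 1.0]])
    return build_material_state(np.array([group]), er, et, params)


def tiled_state(group, n, rng):
    """n particles of one group with random local frames."""
    th = rng.uniform(0, 2 * np.pi, n)
    er = np.stack([np.cos(th), np.sin(th)], axis=1)
    et = np.stack([-np.sin(th), np.cos(th)], axis=1)
    return build_material_state(np.full(n, group), er, et, MaterialParams())


class TestFiberInvariant:
    def test_identity_no_prestretch(self):
        assert fiber_invariant(np.eye(2), [0.0, 1.0]) == pytest.approx(1.0)

    def test_identity_with_collagen_prestretch(self):
        assert fiber_invariant(np.eye(2), [0.0, 1.0], 1.25) == pytest.approx(1.5625)

    def test_circumferential_stretch(self):
        lam, G = 1.13, 1.2
        C = np.diag([1.0, lam**2])
        assert fiber_invariant(C, [0.0, 1.0], G) == pytest.approx((G * lam) ** 2)

    def test_3d_axial_direction(self):
        C = np.diag([1.0, 1.3, 1.62**2])
        assert fiber_invariant(C, [0.0, 0.0, 1.0], 1.25) == pytest.approx(
            1.25**2 * 1.62**2
        )


class TestBranchSelection:
    def test_medial_diagonal_constants(self):
        c1, c2 = select_branch(1.2, 234.9, 4.08, 29.14, 4.08)
        assert (c1, c2) == (234.9, 4.08)
        c1, c2 = select_branch(0.9, 234.9, 4.08, 29.14, 4.08)
        assert (c1, c2) == (29.14, 4.08)

    def test_tie_goes_to_tension_and_is_stress_free(self):
        c1, c2 = select_branch(1.0, 234.9, 4.08, 29.14, 4.08)
        assert c1 == 234.9
        # (I4 - 1) factor makes the fiber stress 0 under either branch
        for cc1 in (234.9, 29.14):
            assert cc1 * (1.0 - 1.0) * np.exp(4.08 * 0.0) == 0.0

    def test_fiber_stress_continuous_at_I4_one(self, rng):
        """Approach I4 = 1 from both sides: stress -> 0 continuously."""
        m = single_state(mats.M_INT)
        eps = 1e-6
        for lam2 in (1.0 - eps, 1.0 + eps):
            F = np.array([[[1.0, 0.0], [0.0, np.sqrt(lam2) / 1.2]]])  # I4_smc ~ lam2
            P, _, _ = passive_stress(F, m)
            assert np.isfinite(P).all()


class TestPassiveEnergy:
    def test_unprestretched_reference_is_energy_free(self):
        m = single_state(mats.M_EL, Ge_r=1.0, Ge_t=1.0, Ge_z=1.0)
        W = passive_energy(np.eye(2)[None], m)
        assert W[0] == pytest.approx(0.0, abs=1e-12)

    def test_prestretched_reference_stores_energy(self):
        m = single_state(mats.M_EL)
        W = passive_energy(np.eye(2)[None], m)
        assert W[0] > 0
        # the prescribed elastin prestretch is nearly isochoric
        assert 0.32 * 1.90 * 1.62 == pytest.approx(0.985, abs=1e-3)

    def test_lamellae_have_no_fiber_energy(self):
        """M_el is pure (prestretched) neo-Hookean: removing fibers changes nothing."""
        m = single_state(mats.M_EL)
        assert np.all(m.phib == 0)

    def test_inverted_state_rejected(self):
        m = single_state(mats.M_INT)
        with pytest.raises(FloatingPointError):
            passive_energy(np.diag([1.0, -1.0])[None], m)


class TestPassiveStress:
    def test_neo_hookean_closed_form(self, rng):
        """Single-constituent neo-Hookean (no prestretch) matches the
        closed-form modified neo-Hookean Cauchy stress."""
        m = single_state(mats.M_EL, Ge_r=1.0, Ge_t=1.0, Ge_z=1.0)
        mu, lam = m.mu[0], m.lam[0]
        for F in random_F(rng, 20):
            P, sig, _ = passive_stress(F[None], m)
            J = np.linalg.det(F)
            B = F @ F.T
            sig_ref = (mu * (B - np.eye(2)) + lam * np.log(J) * np.eye(2)) / J
            assert np.allclose(sig[0], sig_ref, atol=1e-8 * mu)

    def test_cauchy_from_piola_identity(self, rng):
        """sigma = (1/J) P F^T holds by construction for every group."""
        for group in (mats.M_EL, mats.M_INT, mats.ADV):
            m = tiled_state(group, 30, rng)
            F = random_F(rng, 30)
            P, sig, _ = passive_stress(F, m)
            J = np.linalg.det(F)
            sig2 = np.einsum("nij,nkj->nik", P, F) / J[:, None, None]
            assert np.abs(sig - sig2).max() < 1e-10 * np.abs(sig).max()

    def test_passive_cauchy_symmetric(self, rng):
        for group in (mats.M_EL, mats.M_INT, mats.ADV):
            m = tiled_state(group, 30, rng)
            _, sig, _ = passive_stress(random_F(rng, 30), m)
            assert np.abs(sig - np.swapaxes(sig, 1, 2)).max() < 1e-8 * np.abs(sig).max()

    @pytest.mark.parametrize("group", [mats.M_EL, mats.M_INT, mats.ADV])
    def test_piola_matches_energy_gradient(self, group, rng):
        """P = dW/dF by central differences on 100 random states per group."""
        m = tiled_state(group, 100, rng)
        F = random_F(rng, 100)
        P, _, _ = passive_stress(F, m)
        eps = 1e-6
        for a in range(2):
            for b in range(2):
                Fp, Fm = F.copy(), F.copy()
                Fp[:, a, b] += eps
                Fm[:, a, b] -= eps
                fd = (passive_energy(Fp, m) - passive_energy(Fm, m)) / (2 * eps)
                scale = np.maximum(np.abs(P[:, a, b]), np.abs(P).max() * 1e-3)
                assert np.max(np.abs(P[:, a, b] - fd) / scale) < 1e-5

    def test_elastin_prestretch_inverse_motion_is_stress_free(self):
        """A motion composing to identity elastin stretch zeroes the elastin
        stress contribution (volumetric terms evaluated at the same J)."""
        p = MaterialParams()
        m = single_state(mats.M_EL)
        F = np.diag([1 / p.Ge_r, 1 / p.Ge_t])[None]  # F G_e = I in-plane
        P, sig, _ = passive_stress(F, m)
        J = np.linalg.det(F[0])
        # remaining stress is purely the volumetric (J-dependent) part
        iso = m.phi_e[0] * (-(m.mu[0] - m.lam[0] * np.log(J))) / J
        dev = sig[0] - np.einsum("ij,kj->ik", F[0], F[0]) * 0  # just compare directly
        expected = m.phi_e[0] / J * (
            m.mu[0] * np.eye(2) - (m.mu[0] - m.lam[0] * np.log(J)) * np.eye(2)
        )
        assert np.allclose(sig[0], expected, atol=1e-9)


class TestActiveStress:
    def test_vanishes_at_lambda_min(self):
        assert active_stress(0.6, 0.84 * 500, 1.1, 0.6) == pytest.approx(0.0, abs=1e-12)

    def test_maximal_at_lambda_max(self):
        assert active_stress(1.1, 0.84 * 500, 1.1, 0.6) == pytest.approx(462.0)

    def test_reference_value(self):
        assert active_stress(1.0, 0.84 * 500, 1.1, 0.6) == pytest.approx(403.2)

    def test_clamped_outside_limits(self):
        assert active_stress(0.5, 420.0, 1.1, 0.6) == 0.0
        assert active_stress(1.3, 420.0, 1.1, 0.6) == 0.0

    def test_monotone_rising_between_limits(self):
        lt = np.linspace(0.6, 1.1, 50)
        s = active_stress(lt, 420.0, 1.1, 0.6)
        assert np.all(np.diff(s) > 0)

    def test_invalid_limits_rejected(self):
        with pytest.raises(ValueError):
            active_stress(1.0, 420.0, 0.6, 1.1)


class TestGagStress:
    def test_reference_without_swelling_is_stress_free(self):
        P, sig = gag_stress(np.eye(2)[None], np.array([0.1]), np.array([0.0]))
        assert np.allclose(sig, 0.0)

    def test_swelling_pressure_oracle(self):
        """200 vs 300 mEq/l at 310 K -> ~156 kPa Donnan pressure."""
        p = donnan_pressure(200.0, 300.0)
        assert p == pytest.approx(8.314 * 310 * (np.sqrt(200**2 + 300**2) - 300) / 1e3)
        assert p == pytest.approx(156.07, abs=0.05)

    def test_no_fixed_charge_no_swelling(self):
        assert donnan_pressure(0.0, 300.0) == 0.0

    def test_swelling_term_isotropic_and_deformation_independent(self, rng):
        mu_g = np.array([0.1])
        for F in random_F(rng, 10):
            _, s_on = gag_stress(F[None], mu_g, np.array([156.0]))
            _, s_off = gag_stress(F[None], mu_g, np.array([0.0]))
            d = s_on[0] - s_off[0]
            assert np.allclose(d, -156.0 * np.eye(2), atol=1e-9)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            donnan_pressure(-1.0, 300.0)


class TestViscousStress:
    def test_zero_rate_zero_stress(self, rng):
        F = random_F(rng, 5)
        P = viscous_stress(F, F, dt=1.0, eta=30.0)
        assert np.allclose(P, 0.0)

    def test_rigid_rotation_rate_is_inviscid(self):
        """Constant-rate rigid rotation has skew l, so d = 0 and P_visc = 0."""
        w = 1e-3
        R = lambda t: np.array(
            [[np.cos(w * t), -np.sin(w * t)], [np.sin(w * t), np.cos(w * t)]]
        )
        P = viscous_stress(R(1.0)[None], R(0.0)[None], dt=1.0, eta=30.0)
        assert np.abs(P).max() < 1e-4  # O(w^2 dt) discretisation remainder

    def test_resists_stretch_rate(self):
        F1 = np.diag([1.0, 1.01])[None]
        P = viscous_stress(F1, np.eye(2)[None], dt=1.0, eta=30.0)
        assert P[0, 1, 1] > 0


class TestRupturedParticles:
    def test_zero_stress_and_energy(self, rng):
        m = tiled_state(mats.M_EL, 4, rng)
        m.mu[:2] = 0.0
        m.lam[:2] = 0.0
        m.ruptured[:2] = True
        F = random_F(rng, 4)
        P, sig, _ = total_piola(F, np.ones((4, 2)), m, tone_on=False)
        assert np.allclose(P[:2], 0.0)
        assert np.allclose(sig[:2], 0.0)
        assert np.abs(P[2:]).max() > 0
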