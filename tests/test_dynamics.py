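"""Force assembly, stabilization, integration, and equilibria."""

import numpy as np
import pytest

from aortasph import _accel
from aortasph import materials as mats
from aortasph.constitutive import total_piola
from aortasph.dynamics import StabilizationParams, WallModel, leapfrog_step
from aortasph.materials import MaterialParams, build_material_state
from aortasph.neighbors import NeighborTable

from .test_neighbors import square_lattice


def free_patch(n=10, jitter=0.25, seed=1):
    X, V = square_lattice(n, n, a=1.0, jitter=jitter, seed=seed)
    t = NeighborTable(X, V, support=3.0)
    th = np.arctan2(X[:, 1] - X[:, 1].mean(), X[:, 0] - X[:, 0].mean())
    er = np.stack([np.cos(th), np.sin(th)], axis=1)
    et = np.stack([-np.sin(th), np.cos(th)], axis=1)
    m = build_material_state(np.full(X.shape[0], mats.M_INT), er, et, MaterialParams())
    return X, V, t, m


def edge_forces(t, x, P, F, alpha_E=0.0):
    f = np.zeros_like(x)
    aE = np.full(t.src.size, float(alpha_E))
    _accel.edge_forces(
        np.ascontiguousarray(x), P, F, t.src, t.dst, t.rot_cos, t.rot_sin,
        t.rvec, t.rlen, t.weight, t.grad_corr, t.active.astype(np.uint8), t.V,
        aE, f,
    )
    return f


class TestInternalForces:
    def test_zero_stress_zero_force(self):
        X, V, t, m = free_patch()
        F = np.tile(np.eye(2), (t.n, 1, 1))
        f = edge_forces(t, X, np.zeros((t.n, 2, 2)), F)
        assert np.allclose(f, 0.0)

    def test_global_balance_free_boundaries(self):
        """Pairwise antisymmetry: sum of all internal forces vanishes."""
        X, V, t, m = free_patch()
        x = X @ (np.eye(2) + np.array([[0.05, 0.02], [0.0, -0.03]])).T
        F = t.deformation_gradient(x)
        P, _, _ = total_piola(F, x, m, tone_on=False)
        f = edge_forces(t, x, P, F)
        scale = np.abs(f).max()
        assert np.abs(f.sum(axis=0)).max() < 1e-9 * max(scale, 1.0)

    def test_uniform_stress_interior_equilibrium(self):
        """A constant stress field has zero divergence: on a translationally
        symmetric lattice the pair contributions cancel exactly at interior
        particles (boundary particles feel the traction deficit)."""
        X, V, t, m = free_patch(jitter=0.0)
        P0 = np.array([[120.0, 30.0], [30.0, -45.0]])
        P = np.tile(P0, (t.n, 1, 1))
        F = np.tile(np.eye(2), (t.n, 1, 1))
        f = edge_forces(t, X, P, F)
        interior = np.all((X > X.min(0) + 3.0) & (X < X.max(0) - 3.0), axis=1)
        fscale = np.abs(f[~interior]).max()  # boundary forces set the scale
        assert np.abs(f[interior]).max() < 1e-9 * fscale


class TestHourglassForces:
    def test_affine_motion_no_penalty(self):
        """delta vanishes for affine maps, so the hourglass force does."""
        X, V, t, m = free_patch(jitter=0.2, seed=2)
        F0 = np.eye(2) + np.array([[0.08, -0.03], [0.05, 0.06]])
        x = X @ F0.T
        F = t.deformation_gradient(x)
        f = edge_forces(t, x, np.zeros((t.n, 2, 2)), F, alpha_E=25.0 * 89.71)
        assert np.abs(f).max() < 1e-9

    def test_alpha_zero_disables(self):
        X, V, t, m = free_patch()
        rng = np.random.default_rng(5)
        x = X + 0.05 * rng.standard_normal(X.shape)
        F = t.deformation_gradient(x)
        f = edge_forces(t, x, np.zeros((t.n, 2, 2)), F, alpha_E=0.0)
        assert np.allclose(f, 0.0)

    def test_resists_zigzag_mode(self):
        """A checkerboard (hourglass) perturbation is pushed back harder at
        larger alpha."""
        X, V, t, m = free_patch(jitter=0.0)
        zig = 0.05 * ((X[:, 0].astype(int) + X[:, 1].astype(int)) % 2 * 2 - 1)
        x = X.copy()
        x[:, 0] += zig
        F = t.deformation_gradient(x)
        f5 = edge_forces(t, x, np.zeros((t.n, 2, 2)), F, alpha_E=5 * 89.71)
        f50 = edge_forces(t, x, np.zeros((t.n, 2, 2)), F, alpha_E=50 * 89.71)
        assert np.abs(f5).max() > 0
        assert np.allclose(f50, 10 * f5)
        # force opposes the perturbation on interior particles
        interior = np.all((X > X.min(0) + 3.0) & (X < X.max(0) - 3.0), axis=1)
        assert np.mean(np.sign(f50[interior, 0]) == -np.sign(zig[interior])) > 0.9

    def test_alpha_range_warning(self):
        with pytest.warns(UserWarning):
            StabilizationParams(alpha=100.0)


class TestLeapfrog:
    def test_constant_force_quadratic(self):
        x = np.zeros((1, 2))
        v = np.zeros((1, 2))
        fconst = np.array([[1.0, 0.0]])
        dt, m = 0.01, np.array([2.0])
        for _ in range(100):
            x, v = leapfrog_step(x, v, fconst, m, dt)
        t = 100 * dt
        exact = 0.5 * (fconst[0, 0] / m[0]) * t**2
        assert x[0, 0] == pytest.approx(exact, rel=0.02)

    def test_zero_force_zero_velocity_fixed_point(self):
        x = np.array([[1.0, 2.0]])
        x2, v2 = leapfrog_step(x, np.zeros((1, 2)), np.zeros((1, 2)), np.ones(1), 0.1)
        assert np.allclose(x2, x) and np.allclose(v2, 0.0)

    def test_time_reversal(self):
        """Frictionless harmonic trajectory retraced by negating velocity."""
        k, m, dt = 1.0, 1.0, 0.01
        x = np.array([[1.0, 0.0]])
        v = np.zeros((1, 2))
        for _ in range(200):
            x, v = leapfrog_step(x, v, -k * x, np.array([m]), dt)
        x, v = x, -v
        # re-centre the staggered velocity by a half-step force application
        for _ in range(200):
            x, v = leapfrog_step(x, v, -k * x, np.array([m]), dt)
        assert np.abs(x[0, 0] - 1.0) < 5e-3

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            leapfrog_step(np.zeros((1, 2)), np.zeros((1, 2)), np.zeros((1, 2)),
                          np.array([0.0]), 0.1)


class TestNumbaParity:
    """The fused numba kernels must match the numpy reference bit-tightly."""

    def test_deformation_gradient_parity(self, small_wall):
        t = small_wall.build_neighbors()
        F0 = np.array([[1.04, 0.0], [0.0, 1.04]])
        x = small_wall.X @ F0.T
        F_np = t.deformation_gradient(x)
        F_nb = np.zeros_like(F_np)
        _accel.edge_deformation_gradients(
            np.ascontiguousarray(x), t.src, t.dst, t.rot_cos, t.rot_sin,
            t.grad_corr, t.active.astype(np.uint8), t.V,
            t.live.astype(np.uint8), F_nb,
        )
        assert np.abs(F_np - F_nb).max() < 1e-13

    def test_stress_parity(self, small_wall, rng):
        t = small_wall.build_neighbors()
        m = small_wall.materials
        x = small_wall.X * 1.02
        F = t.deformation_gradient(x)
        P_np, _, _ = total_piola(F, x, m, tone_on=True)
        P_nb = np.zeros_like(P_np)
        st = _accel.particle_stress(
            F, F.copy(), np.ascontiguousarray(x),
            m.phi_e, m.mu, m.lam, m.Ge2, m.gz2,
            m.fc1p, m.fc2p, m.fc1m, m.fc2m, m.fG2, m.fs2a, m.phib,
            m.et, m.act_coef, m.contractile.astype(np.uint8),
            m.is_gag.astype(np.uint8), m.mu_gag, m.p_swell,
            m.ruptured.astype(np.uint8), m.lam_max, m.lam_min,
            1.0, True, 0.0, 1.0, P_nb,
        )
        assert st == 0
        assert np.abs(P_np - P_nb).max() < 1e-9 * np.abs(P_np).max()


class TestWallEquilibria:
    def test_homeostatic_pressure(self, small_model):
        """Relaxed prestretched lattice reports the homeostatic pressure."""
        rec = small_model.measure()
        assert rec.pressure_mmhg == pytest.approx(102.0, rel=0.10)
        assert rec.lam_theta == pytest.approx(1.0, abs=5e-3)
        assert rec.converged or rec.steps == 0

    def test_reaction_pressure_consistency(self, small_model):
        """Laplace-law pressure vs rim constraint reaction within 5%."""
        rec = small_model.measure()
        p_react = small_model.reaction_pressure()
        assert abs(p_react - rec.pressure_mmhg) / rec.pressure_mmhg < 0.05

    def test_transmural_stress_pattern(self, small_model):
        """Lamellae carry more circumferential stress than intra-lamellar
        tissue at matched radius; radial stress ~0 in bands, compressive
        in lamellae (passive homeostatic state)."""
        rec = small_model.measure()
        sys_ = small_model.system
        mel = sys_.group == mats.M_EL
        mint = sys_.group == mats.M_INT
        assert rec.sigma_tt[mel].mean() > rec.sigma_tt[mint].mean() + 50.0
        assert rec.sigma_rr[mel].mean() < -5.0
        assert abs(rec.sigma_rr[mint].mean()) < 10.0

    def test_no_prestretch_means_no_stress(self):
        """G = identity: the reference lattice is stress-free, P = 0."""
        from aortasph.geometry import WallGeometry, build_wall

        p = MaterialParams(Ge_r=1.0, Ge_t=1.0, Ge_z=1.0, Gk_smc=1.0, Gk_col=1.0)
        w = build_wall(WallGeometry(sector_deg=15.0, density=0.24), p)
        model = WallModel(w)
        rec = model.homeostatic_reference()
        assert abs(rec.pressure_mmhg) < 1.0
        assert np.abs(rec.sigma_tt).max() < 1.0
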