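"""Quasi-static equilibrium by damped explicit dynamics.

Forces from Piola stresses (pairwise antisymmetric), hourglass penalty
forces against non-affine modes, and an artificial viscosity are
integrated with a leapfrog scheme under fictitious particle masses until
kinetic energy and residual force drop below tolerance.  Masses are
scaled per particle from a local stiffness bound, so the stable time
step is uniform and can be fixed at dt = 1 (time is not physical here).

Loading is displacement controlled (semi-inverse): inner-rim particles
are ramped radially, the outer rim is traction free, sector edges are
rotationally periodic, and the luminal pressure is an *output* computed
from the Laplace relation P = sigma_theta h / r_in using the
volume-weighted mean circumferential Cauchy stress.  Pressure targets
are met by secant iteration on the rim radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _accel
from .constitutive import total_piola
from .geometry import ParticleSystem
from .materials import MMHG_TO_KPA, MaterialState
from .neighbors import NeighborTable


class ConvergenceError(RuntimeError):
    pass


@dataclass
class StabilizationParams:
    """Numerical-stabilization and relaxation controls.

    ``alpha`` is the hourglass control (sensible range [5, 50]); ``E`` a
    stiffness-like penalty (defaults to the elastin shear modulus scale);
    ``eta`` the artificial viscosity.  None of these affect converged
    stresses (regression-tested), only the path to equilibrium.
    """

    alpha: float = 25.0
    E: float = 89.71                 # kPa
    eta: float = 30.0                # kPa * step
    dt: float = 1.0
    mass_safety: float = 4.0
    damp: float = -1.0               # per-step velocity scaling; negative selects
                                     # adaptive near-critical damping (Rayleigh
                                     # frequency estimate, the usual DR choice)
    kinetic_damping: bool = False    # zero velocities at kinetic-energy peaks
                                     # (can stall multi-mode transients; off by default)
    tol_ke: float = 1e-6             # KE / peak KE
    tol_f: float = 1e-4              # residual force / mean internal force scale
    check_every: int = 50
    max_steps: int = 20000           # per attempt; a stalled attempt restarts
                                     # with masses refreshed from the new state
    max_attempts: int = 5            # relaxation budget = max_attempts * max_steps
    ramp_steps: int = 400
    warn_only: bool = False          # tolerate hitting max_steps

    def __post_init__(self):
        if not 5.0 <= self.alpha <= 50.0:
            warnings.warn(f"hourglass alpha={self.alpha} outside the validated range [5, 50]")
        if self.dt <= 0 or self.mass_safety <= 0:
            raise ValueError("dt and mass_safety must be positive")


@dataclass
class EquilibriumRecord:
    """Converged state and bulk observables."""

    x: np.ndarray
    sigma: np.ndarray          # (n, 2, 2) Cauchy stress, kPa
    sigma_tt: np.ndarray       # circumferential component (current frame)
    sigma_rr: np.ndarray       # radial component
    sigma_zz: np.ndarray
    pressure_mmhg: float
    pressure_kpa: float
    sigma_theta_mean: float
    r_in: float                # current inner surface radius, um
    r_out: float
    thickness: float
    lam_theta: float           # mean circumferential stretch (Laplace form)
    tone_on: bool
    steps: int
    converged: bool
    fmax: float
    fscale: float
    ke_ratio: float

    @property
    def outer_diameter(self) -> float:
        return 2.0 * self.r_out


def leapfrog_step(x, v, force, mass, dt):
    """One kick-drift leapfrog update (staggered velocities).

    Plain Newtonian update used by the relaxation loop; exposed for
    trajectory-level verification (quadratic free fall, reversibility).
    """
    m = np.asarray(mass, dtype=float)
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    v = v + dt * np.asarray(force) / m[..., None]
    x = x + dt * v
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
        raise FloatingPointError("non-finite state in leapfrog step")
    return x, v


def stiffness_scale(mat: MaterialState, F=None, lambda_z: float = 1.0, headroom: float = 1.5):
    """Per-particle tangent-stiffness bound (kPa) for mass scaling."""
    K = mat.phi_e * (mat.mu + mat.lam)
    if F is None:
        Ctt = np.ones(mat.n)
    else:
        C = np.einsum("nki,nkj->nij", F, F)
        Ctt = np.einsum("ni,nij,nj->n", mat.et, C, mat.et)
    I4 = mat.fG2 * (mat.fs2a * Ctt[:, None] + (1.0 - mat.fs2a) * lambda_z**2)
    xm = np.maximum(np.abs(I4 - 1.0) * headroom, 0.3)
    c1 = np.maximum(mat.fc1p, mat.fc1m)
    c2 = np.maximum(mat.fc2p, mat.fc2m)
    K = K + np.sum(
        mat.phib * c1 * mat.fG2**2 * (1.0 + 2.0 * c2 * xm**2) * np.exp(c2 * xm**2), axis=1
    )
    K = K + mat.act_coef * 6.0
    K = np.where(mat.is_gag, 4.0 * mat.mu_gag + 2.0 * mat.p_swell + 1.0, K)
    return np.maximum(K, 1.0)


class WallModel:
    """Particle system + neighbour table + relaxation state."""

    def __init__(self, system: ParticleSystem, table: NeighborTable | None = None,
                 stab: StabilizationParams | None = None, support: float | None = None):
        self.system = system
        self.table = table if table is not None else system.build_neighbors(support)
        self.mat = system.materials
        self.stab = stab if stab is not None else StabilizationParams()
        self.x = system.X.copy()
        self.v = np.zeros_like(self.x)
        self.tone_on = False
        self.lambda_z = 1.0
        self.rim_scale = 1.0
        self._mass_boost = 1.0

    # -- solver plumbing -------------------------------------------------

    def hourglass_coeff(self):
        """Per-edge penalty stiffness alpha * E_pair.

        E follows the local material modulus scale (as in FEM hourglass
        control, where the penalty is proportional to the element
        modulus): the configured E for elastin-stiff tissue, down to the
        swelling-pressure scale inside soft GAG pools — a uniform stiff
        penalty would overwhelm and overdamp the pool's own mechanics.
        """
        m, s = self.mat, self.stab
        Ehg = m.phi_e * m.mu + np.sum(m.phib * m.fc1p, axis=1)
        gag = m.is_gag
        Ehg[gag] = m.mu_gag[gag] + m.p_swell[gag]
        Ehg = np.clip(Ehg, 1.0, s.E)
        t = self.table
        return s.alpha * 0.5 * (Ehg[t.src] + Ehg[t.dst])

    def masses(self):
        t, s = self.table, self.stab
        F = self.table.deformation_gradient(self.x, check=False)
        K = stiffness_scale(self.mat, F, self.lambda_z)
        # geometric stiffness: concentrated stress (defect tips) stiffens
        # pairs beyond the tangent-modulus bound
        P, _, _ = total_piola(F, self.x, self.mat, self.tone_on, self.lambda_z)
        K = K + np.linalg.norm(P, axis=(1, 2))
        K = K + 2.0 * s.eta / s.dt
        Kpair = K[t.src] + K[t.dst]
        g2 = np.sum(t.grad_corr**2, axis=1)
        aE = self.hourglass_coeff()
        w = np.where(
            t.active,
            t.V[t.src] * t.V[t.dst]
            * (g2 * Kpair + aE * t.weight / t.rlen**2),
            0.0,
        )
        m = s.mass_safety * self._mass_boost * s.dt**2 * np.bincount(
            t.src, weights=w, minlength=t.n
        )
        m[m <= 0] = 1.0
        return m

    def _mat_args(self):
        m = self.mat
        return (
            m.phi_e, m.mu, m.lam, m.Ge2, m.gz2,
            m.fc1p, m.fc2p, m.fc1m, m.fc2m, m.fG2, m.fs2a, m.phib,
            m.et, m.act_coef, m.contractile.astype(np.uint8),
            m.is_gag.astype(np.uint8), m.mu_gag, m.p_swell,
            m.ruptured.astype(np.uint8), m.lam_max, m.lam_min,
        )

    def relax(self, constrained=None, x_target=None, ramp_steps=None):
        """Damped dynamics until force balance.

        Fictitious masses are refreshed from the current state before each
        attempt; a run that stalls (large deformation has outgrown the
        stiffness bound the masses were scaled to) is restarted from where
        it stopped with updated masses and zeroed velocities, and element
        inversion or blow-up triggers a retry with heavier masses.
        """
        t, s = self.table, self.stab
        if constrained is None:
            constrained = self.system.inner_rim
        if x_target is None:
            x_target = self.x.copy()
        ramp = s.ramp_steps if ramp_steps is None else ramp_steps
        total_steps = 0
        local_boost = 1.0
        for attempt in range(s.max_attempts):
            mass = self.masses() * local_boost
            x = self.x.copy()
            v = self.v.copy()
            status, steps, ke, ke_peak, fmax, fscale = _accel.run_relax(
                x, v, mass, t.V,
                t.src, t.dst, t.rot_cos, t.rot_sin, t.rvec, t.rlen, t.weight,
                t.grad_corr, t.active.astype(np.uint8), t.live.astype(np.uint8),
                *self._mat_args(),
                self.lambda_z, self.tone_on,
                constrained.astype(np.uint8), self.x.copy(), x_target,
                ramp,
                s.dt, s.eta, self.hourglass_coeff(), s.damp, s.kinetic_damping,
                s.tol_ke, s.tol_f, s.check_every, s.max_steps,
            )
            if status in (_accel.STATUS_CONVERGED, _accel.STATUS_MAXSTEPS):
                self.x, self.v = x, v
                total_steps += steps
                if status == _accel.STATUS_CONVERGED:
                    return {
                        "steps": total_steps,
                        "converged": True,
                        "fmax": fmax,
                        "fscale": fscale,
                        "ke_ratio": ke / max(ke_peak, 1e-300),
                    }
                # stalled: restart from here with fresh masses, no ramp;
                # repeated stalls escalate the mass safety (marginal modes)
                self.v[:] = 0.0
                ramp = 0
                if attempt >= 1:
                    local_boost *= 2.0
                continue
            # inversion / non-finite: stiffer masses, slower ramp, retry
            self._mass_boost *= 4.0
            ramp = max(ramp, 200) * 2
            self.v[:] = 0.0
        if status == _accel.STATUS_MAXSTEPS and s.warn_only:
            return {
                "steps": total_steps,
                "converged": False,
                "fmax": fmax,
                "fscale": fscale,
                "ke_ratio": ke / max(ke_peak, 1e-300),
            }
        raise ConvergenceError(
            f"relaxation did not converge in {total_steps} steps "
            f"(ke/peak={ke / max(ke_peak, 1e-300):.2e}, "
            f"fmax/fscale={fmax / max(fscale, 1e-300):.2e})"
        )

    # -- observables ------------------------------------------------------

    def measure(self, diag=None) -> EquilibriumRecord:
        sys_, t = self.system, self.table
        F = t.deformation_gradient(self.x)
        P, sigma, sigma_zz = total_piola(F, self.x, self.mat, self.tone_on, self.lambda_z)
        r = np.linalg.norm(self.x, axis=1)
        erc = self.x / r[:, None]
        etc = np.stack([-erc[:, 1], erc[:, 0]], axis=1)
        s_tt = np.einsum("ni,nij,nj->n", etc, sigma, etc)
        s_rr = np.einsum("ni,nij,nj->n", erc, sigma, erc)
        s_mean = float(np.sum(sys_.V * s_tt) / np.sum(sys_.V))
        # rim particles sit half a radial cell inside the wall surfaces
        half_in = float(sys_.R.min() - sys_.geometry.r_in)
        half_out = float(sys_.geometry.r_out - sys_.R.max())
        lam_r = np.einsum("ni,nij,nj->n", erc, F, sys_.er)
        rim_i, rim_o = sys_.inner_rim, sys_.outer_rim
        r_in = float(np.mean(r[rim_i]) - half_in * np.mean(lam_r[rim_i]))
        r_out = float(np.mean(r[rim_o]) + half_out * np.mean(lam_r[rim_o]))
        h = r_out - r_in
        P_kpa = s_mean * h / r_in
        geom = sys_.geometry
        lam_theta = (r_in + h / 2.0) / (geom.r_in + geom.thickness / 2.0)
        diag = diag or {}
        return EquilibriumRecord(
            x=self.x.copy(), sigma=sigma, sigma_tt=s_tt, sigma_rr=s_rr, sigma_zz=sigma_zz,
            pressure_mmhg=P_kpa / MMHG_TO_KPA, pressure_kpa=P_kpa, sigma_theta_mean=s_mean,
            r_in=r_in, r_out=r_out, thickness=h, lam_theta=lam_theta, tone_on=self.tone_on,
            steps=diag.get("steps", 0), converged=diag.get("converged", True),
            fmax=diag.get("fmax", np.nan), fscale=diag.get("fscale", np.nan),
            ke_ratio=diag.get("ke_ratio", np.nan),
        )

    def reaction_pressure(self) -> float:
        """Pressure (mmHg) implied by the net radial rim reaction.

        The constraint reaction on the held inner rim must balance the
        pressure resultant over the inner arc: sum(reaction . e_r)
        = P * r_in * sector.  Independent cross-check of the Laplace
        pressure report.
        """
        t = self.table
        F = t.deformation_gradient(self.x)
        P, _, _ = total_piola(F, self.x, self.mat, self.tone_on, self.lambda_z)
        f = np.zeros_like(self.x)
        _accel.edge_forces(
            self.x, P, F, t.src, t.dst, t.rot_cos, t.rot_sin, t.rvec, t.rlen,
            t.weight, t.grad_corr, t.active.astype(np.uint8), t.V,
            self.hourglass_coeff(), f,
        )
        rim = self.system.inner_rim
        r = np.linalg.norm(self.x[rim], axis=1)
        erc = self.x[rim] / r[:, None]
        reaction = -np.sum(np.einsum("ni,ni->n", f[rim], erc))
        rec = self.measure()
        P_kpa = reaction / (rec.r_in * self.system.geometry.sector_rad)
        return P_kpa / MMHG_TO_KPA

    # -- equilibration protocols ------------------------------------------

    def homeostatic_reference(self) -> EquilibriumRecord:
        """Relax the prestretched lattice with the inner rim held at R_in.

        At the homeostatic reference F = I and every constituent is
        loaded through its deposition prestretch; a short relaxation
        removes the small lattice-scale residual.  The reported Laplace
        pressure of the converged state is the homeostatic pressure
        (~102 mmHg for the default wall).
        """
        diag = self.relax(x_target=self.x.copy(), ramp_steps=0)
        return self.measure(diag)

    def equilibrate_rim_scale(self, scale: float, tone_on: bool | None = None,
                              ramp_steps=None) -> EquilibriumRecord:
        """Ramp the inner rim radially to ``scale x R_in`` and relax."""
        if tone_on is not None:
            self.tone_on = tone_on
        rim = self.system.inner_rim
        x_target = self.x.copy()
        x_target[rim] = scale * self.system.X[rim]
        diag = self.relax(constrained=rim, x_target=x_target, ramp_steps=ramp_steps)
        self.rim_scale = scale
        return self.measure(diag)

    def equilibrate_pressure(self, pressure_mmhg: float, tone_on: bool | None = None,
                             tol_mmhg: float = 0.5, max_iter: int = 40,
                             max_step: float = 0.08) -> EquilibriumRecord:
        """Find the rim radius whose equilibrium reports the target pressure.

        Secant iteration on the rim scale; each evaluation is a fully
        relaxed equilibrium warm-started from the previous one.
        """
        if tone_on is not None:
            self.tone_on = tone_on
        rec = self.equilibrate_rim_scale(self.rim_scale)
        s0, p0 = self.rim_scale, rec.pressure_mmhg
        # initial slope guess from the passive homeostatic state:
        # dP/dscale is of order 20 mmHg per % for a stiff artery
        slope = 4000.0
        s1 = s0
        for _ in range(max_iter):
            if abs(p0 - pressure_mmhg) < tol_mmhg:
                return rec
            step = (pressure_mmhg - p0) / slope
            step = np.clip(step, -max_step, max_step)
            s1 = s0 + step
            rec = self.equilibrate_rim_scale(s1)
            p1 = rec.pressure_mmhg
            if abs(p1 - p0) > 1e-9 and abs(s1 - s0) > 1e-12:
                slope = np.clip((p1 - p0) / (s1 - s0), 200.0, 1e5)
            s0, p0 = s1, p1
        raise ConvergenceError(
            f"pressure iteration did not reach {pressure_mmhg} mmHg "
            f"(last {p0:.2f} at rim scale {s0:.4f})"
        )
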