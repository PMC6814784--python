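"""Constitutive layer: strain energy and stresses per particle.

The mixture strain energy is

    W = phi_e [ mu/2 (I1_e - 3) - mu ln J + lam_hat/2 (ln J)^2 ]
        + sum_k phi_ck beta_k c1/(4 c2) ( exp(c2 (I4_k - 1)^2) - 1 ),

with I1_e the first invariant of the elastin constituent (prestretch-
composed, F_e = F G_e) and I4_k the squared fiber stretch of family k,
I4_k = G_k^2 (C : M_k x M_k).  Tension and compression use separate
(c1, c2) constants; the branch switch at I4 = 1 is stress-continuous
because the fiber stress carries an (I4 - 1) factor.

The motion is in-plane (2x2 deformation gradients) at fixed axial stretch
lambda_z = 1 relative to the prestretched reference; axial (out-of-plane)
stress is evaluated for reporting but never enters in-plane force balance.

All derivatives are analytic; finite differencing appears only in tests.
"""

from __future__ import annotations

import numpy as np

from .materials import MaterialState


def fiber_invariant(C, direction, prestretch=1.0):
    """Squared fiber stretch I4 = G^2 (C : M x M) for a unit direction M.

    ``C`` may be a single matrix or a batch (..., d, d); ``direction`` a
    matching unit vector (2D in-plane or 3D with the axial component).
    """
    C = np.asarray(C, dtype=float)
    M = np.asarray(direction, dtype=float)
    CM = np.einsum("...ij,...j->...i", C, M)
    return prestretch**2 * np.einsum("...i,...i->...", M, CM)


def select_branch(I4, c1_plus, c2_plus, c1_minus, c2_minus):
    """Tension constants for I4 >= 1, compression constants for I4 < 1."""
    I4 = np.asarray(I4, dtype=float)
    tens = I4 >= 1.0
    c1 = np.where(tens, c1_plus, c1_minus)
    c2 = np.where(tens, c2_plus, c2_minus)
    return c1, c2


def _det2(F):
    return F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]


def _inv2(F):
    J = _det2(F)
    inv = np.empty_like(F)
    inv[..., 0, 0] = F[..., 1, 1]
    inv[..., 0, 1] = -F[..., 0, 1]
    inv[..., 1, 0] = -F[..., 1, 0]
    inv[..., 1, 1] = F[..., 0, 0]
    return inv / J[..., None, None]


def _I4_families(C, m: MaterialState, lambda_z: float):
    """I4 per fiber family, (n, 4); families mix theta and z by sin^2(alpha)."""
    Ctt = np.einsum("ni,nij,nj->n", m.et, C, m.et)
    return m.fG2 * (m.fs2a * Ctt[:, None] + (1.0 - m.fs2a) * lambda_z**2)


def _fiber_coeff(I4, m: MaterialState):
    """d(fiber energy)/dI4 * 2 summed weights: phib * c1 (I4-1) exp(c2 (I4-1)^2)."""
    x = I4 - 1.0
    c1, c2 = select_branch(I4, m.fc1p, m.fc2p, m.fc1m, m.fc2m)
    return m.phib * c1 * x * np.exp(c2 * x * x)


def passive_energy(F, m: MaterialState, lambda_z: float = 1.0):
    """Strain energy density W (kPa) per particle; GAG particles return 0.

    ``F`` has shape (n, 2, 2).  Raises on J <= 0.
    """
    F = np.asarray(F, dtype=float)
    J = _det2(F) * lambda_z
    if np.any(J <= 0):
        raise FloatingPointError("J <= 0 in passive_energy")
    C = np.einsum("nki,nkj->nij", F, F)
    lnJ = np.log(J)
    I1e = np.einsum("nij,nij->n", C, m.Ge2) + m.gz2
    We = m.phi_e * (0.5 * m.mu * (I1e - 3.0) - m.mu * lnJ + 0.5 * m.lam * lnJ**2)
    I4 = _I4_families(C, m, lambda_z)
    x = I4 - 1.0
    c1, c2 = select_branch(I4, m.fc1p, m.fc2p, m.fc1m, m.fc2m)
    Wf = np.sum(m.phib * c1 / (4.0 * c2) * (np.exp(c2 * x * x) - 1.0), axis=1)
    W = We + Wf
    W[m.is_gag] = 0.0
    return W


def passive_stress(F, m: MaterialState, lambda_z: float = 1.0):
    """First Piola-Kirchhoff and Cauchy stress of the passive mixture.

    Returns ``(P, sigma, sigma_zz)`` with P, sigma of shape (n, 2, 2).
    GAG particles get their neo-Hookean + swelling stress (see gag_stress);
    ruptured particles (mu = lam = 0, no fibers) return zero.
    """
    F = np.asarray(F, dtype=float)
    n = F.shape[0]
    J = _det2(F) * lambda_z
    if np.any(J <= 0):
        raise FloatingPointError("J <= 0 in passive_stress")
    C = np.einsum("nki,nkj->nij", F, F)
    lnJ = np.log(J)
    Cinv = _inv2(C)
    eye = np.eye(2)
    # elastin: S = 2 dW/dC = phi_e [mu Ge2 - (mu - lam lnJ) C^-1]
    S = m.phi_e[:, None, None] * (
        m.mu[:, None, None] * m.Ge2
        - (m.mu - m.lam * lnJ)[:, None, None] * Cinv
    )
    I4 = _I4_families(C, m, lambda_z)
    coeff = _fiber_coeff(I4, m)  # (n, 4)
    w_theta = np.sum(coeff * m.fG2 * m.fs2a, axis=1)
    S = S + w_theta[:, None, None] * np.einsum("ni,nj->nij", m.et, m.et)
    P = np.einsum("nij,njk->nik", F, S)
    sigma = np.einsum("nij,nkj->nik", P, F) / J[:, None, None]
    sigma_zz = (
        m.phi_e * (m.mu * m.gz2 - m.mu + m.lam * lnJ)
        + np.sum(coeff * m.fG2 * (1.0 - m.fs2a), axis=1) * lambda_z**2
    ) / J
    # GAG particles: isotropic neo-Hookean + optional Donnan swelling
    if np.any(m.is_gag):
        gmask = m.is_gag
        Pg, sg = gag_stress(F[gmask], m.mu_gag[gmask], m.p_swell[gmask], lambda_z)
        P[gmask], sigma[gmask] = Pg, sg
        sigma_zz[gmask] = -m.p_swell[gmask]
    return P, sigma, sigma_zz


def gag_stress(F, mu_gag, p_swell, lambda_z: float = 1.0):
    """GAG-pool stress: sigma = mu_gag/J (B - I) - p_swell I.

    The swelling term is deformation-independent and purely isotropic;
    ``p_swell`` is zero until osmotic swelling is switched on.
    Returns ``(P, sigma)``.
    """
    F = np.asarray(F, dtype=float)
    J = _det2(F) * lambda_z
    B = np.einsum("nik,njk->nij", F, F)
    eye = np.eye(2)
    sigma = (np.asarray(mu_gag) / J)[:, None, None] * (B - eye) - np.asarray(p_swell)[
        :, None, None
    ] * eye
    FinvT = np.swapaxes(_inv2(F), -1, -2)
    P = J[:, None, None] * np.einsum("nij,njk->nik", sigma, FinvT)
    return P, sigma


def active_stress(lam_theta, act_coef, lam_max: float, lam_min: float):
    """Parabolic active-tone Cauchy stress (kPa), clamped outside limits.

    sigma_act = phi_c2 T_max lam_theta [1 - ((lam_max - lam)/(lam_max - lam_min))^2]

    vanishing at lam_min and maximal at lam_max; ``act_coef`` is
    phi_c2 * T_max per particle (zero where there is no tone).
    """
    if lam_max <= lam_min:
        raise ValueError("lam_max must exceed lam_min")
    lt = np.asarray(lam_theta, dtype=float)
    s = np.asarray(act_coef) * lt * (1.0 - ((lam_max - lt) / (lam_max - lam_min)) ** 2)
    return np.where((lt >= lam_min) & (lt <= lam_max), s, 0.0)


def active_piola(F, x, sigma_act, lambda_z: float = 1.0):
    """Map active circumferential Cauchy stress into Piola stress.

    The tone acts along the *current* circumferential direction (the unit
    vector perpendicular to the current radius), so the traction stays
    physically circumferential during constriction:
    P_act = J sigma_act (e_t x e_t) F^{-T}.
    """
    F = np.asarray(F, dtype=float)
    x = np.asarray(x, dtype=float)
    J = _det2(F) * lambda_z
    r = np.linalg.norm(x, axis=1)
    etc = np.stack([-x[:, 1], x[:, 0]], axis=1) / r[:, None]
    sig = np.asarray(sigma_act)[:, None, None] * np.einsum("ni,nj->nij", etc, etc)
    FinvT = np.swapaxes(_inv2(F), -1, -2)
    return J[:, None, None] * np.einsum("nij,njk->nik", sig, FinvT)


def viscous_stress(F, F_prev, dt: float, eta: float, lambda_z: float = 1.0):
    """Numerical-stabilization viscous Piola stress P = 2 eta J d F^{-T}.

    ``d`` is the symmetric part of the spatial velocity gradient
    l = Fdot F^{-1} with Fdot backward-differenced between steps; the
    term vanishes at equilibrium and does not alter converged stresses.
    """
    F = np.asarray(F, dtype=float)
    J = _det2(F) * lambda_z
    Fdot = (F - np.asarray(F_prev, dtype=float)) / dt
    Finv = _inv2(F)
    l = np.einsum("nij,njk->nik", Fdot, Finv)
    d = 0.5 * (l + np.swapaxes(l, -1, -2))
    FinvT = np.swapaxes(Finv, -1, -2)
    return 2.0 * eta * J[:, None, None] * np.einsum("nij,njk->nik", d, FinvT)


def circumferential_stretch(F, m: MaterialState):
    """lambda_theta = sqrt(C : e_t x e_t) w.r.t. the passive reference frame."""
    C = np.einsum("nki,nkj->nij", F, F)
    return np.sqrt(np.einsum("ni,nij,nj->n", m.et, C, m.et))


def total_piola(F, x, m: MaterialState, tone_on: bool, lambda_z: float = 1.0,
                F_prev=None, dt: float = 1.0, eta: float = 0.0):
    """Total Piola stress (passive + active + viscous) and reported Cauchy stress.

    The reported sigma excludes the viscous stabilizer (which is zero at
    equilibrium anyway).  Returns ``(P_total, sigma, sigma_zz)``.
    """
    P, sigma, sigma_zz = passive_stress(F, m, lambda_z)
    if tone_on:
        on = m.contractile & (m.act_coef > 0) & ~m.is_gag & ~m.ruptured
        if np.any(on):
            lt = circumferential_stretch(F[on], _subset(m, on))
            s_act = active_stress(lt, m.act_coef[on], m.lam_max, m.lam_min)
            Pa = active_piola(F[on], x[on], s_act, lambda_z)
            P[on] = P[on] + Pa
            J = _det2(F[on]) * lambda_z
            sigma[on] = sigma[on] + np.einsum(
                "nij,nkj->nik", Pa, F[on]
            ) / J[:, None, None]
    if eta > 0.0 and F_prev is not None:
        P = P + viscous_stress(F, F_prev, dt, eta, lambda_z)
    P[m.ruptured] = 0.0
    sigma[m.ruptured] = 0.0
    sigma_zz[m.ruptured] = 0.0
    return P, sigma, sigma_zz


def _subset(m: MaterialState, mask):
    import dataclasses

    kw = {}
    for f in dataclasses.fields(m):
        v = getattr(m, f.name)
        kw[f.name] = v[mask] if isinstance(v, np.ndarray) else v
    return MaterialState(**kw)
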