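"""Fused numba kernels for the dynamic-relaxation loop.

The formulas here mirror the reference implementations in
``neighbors.deformation_gradient`` and ``constitutive`` exactly; a parity
test keeps the two paths in lock-step.  Everything is float64 and single
threaded — problem sizes are a few thousand particles.

Status codes returned by ``run_relax``:
0 converged, 1 max-steps reached, 2 element inversion (J <= 0),
3 non-finite state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_CONVERGED = 0
STATUS_MAXSTEPS = 1
STATUS_INVERTED = 2
STATUS_NONFINITE = 3


@njit(cache=True)
def edge_deformation_gradients(x, src, dst, rot_c, rot_s, grad_corr, active, V, live, F):
    n = F.shape[0]
    F[:] = 0.0
    for e in range(src.shape[0]):
        if not active[e]:
            continue
        i = src[e]
        j = dst[e]
        c = rot_c[e]
        s = rot_s[e]
        xjx = c * x[j, 0] - s * x[j, 1]
        xjy = s * x[j, 0] + c * x[j, 1]
        rx = xjx - x[i, 0]
        ry = xjy - x[i, 1]
        w = V[j]
        gx = grad_corr[e, 0]
        gy = grad_corr[e, 1]
        F[i, 0, 0] += rx * w * gx
        F[i, 0, 1] += rx * w * gy
        F[i, 1, 0] += ry * w * gx
        F[i, 1, 1] += ry * w * gy
    for i in range(n):
        if not live[i]:
            F[i, 0, 0] = 1.0
            F[i, 0, 1] = 0.0
            F[i, 1, 0] = 0.0
            F[i, 1, 1] = 1.0
    return F


@njit(cache=True)
def particle_stress(
    F,
    F_prev,
    x,
    # material arrays
    phi_e,
    mu,
    lam,
    Ge2,
    gz2,
    fc1p,
    fc2p,
    fc1m,
    fc2m,
    fG2,
    fs2a,
    phib,
    et,
    act_coef,
    contractile,
    is_gag,
    mu_gag,
    p_swell,
    ruptured,
    lam_max,
    lam_min,
    lambda_z,
    tone_on,
    eta,
    dt,
    P,
):
    """Total first Piola-Kirchhoff stress per particle.  Returns status."""
    n = F.shape[0]
    for i in range(n):
        F00 = F[i, 0, 0]
        F01 = F[i, 0, 1]
        F10 = F[i, 1, 0]
        F11 = F[i, 1, 1]
        detF = F00 * F11 - F01 * F10
        J = detF * lambda_z
        if ruptured[i]:
            P[i, 0, 0] = P[i, 0, 1] = P[i, 1, 0] = P[i, 1, 1] = 0.0
            continue
        if J <= 0.0:
            return STATUS_INVERTED
        # F^{-1}
        iF00 = F11 / detF
        iF01 = -F01 / detF
        iF10 = -F10 / detF
        iF11 = F00 / detF
        if is_gag[i]:
            # sigma = mu_gag/J (B - I) - p_swell I ; P = J sigma F^{-T}
            B00 = F00 * F00 + F01 * F01
            B01 = F00 * F10 + F01 * F11
            B11 = F10 * F10 + F11 * F11
            s00 = mu_gag[i] / J * (B00 - 1.0) - p_swell[i]
            s01 = mu_gag[i] / J * B01
            s11 = mu_gag[i] / J * (B11 - 1.0) - p_swell[i]
            P[i, 0, 0] = J * (s00 * iF00 + s01 * iF01)
            P[i, 0, 1] = J * (s00 * iF10 + s01 * iF11)
            P[i, 1, 0] = J * (s01 * iF00 + s11 * iF01)
            P[i, 1, 1] = J * (s01 * iF10 + s11 * iF11)
        else:
            C00 = F00 * F00 + F10 * F10
            C01 = F00 * F01 + F10 * F11
            C11 = F01 * F01 + F11 * F11
            detC = detF * detF
            lnJ = np.log(J)
            # C^{-1}
            iC00 = C11 / detC
            iC01 = -C01 / detC
            iC11 = C00 / detC
            coef = mu[i] - lam[i] * lnJ
            pe = phi_e[i]
            S00 = pe * (mu[i] * Ge2[i, 0, 0] - coef * iC00)
            S01 = pe * (mu[i] * Ge2[i, 0, 1] - coef * iC01)
            S11 = pe * (mu[i] * Ge2[i, 1, 1] - coef * iC11)
            # fibers: in-plane action along reference e_theta
            ex = et[i, 0]
            ey = et[i, 1]
            Ctt = ex * (C00 * ex + C01 * ey) + ey * (C01 * ex + C11 * ey)
            wth = 0.0
            for k in range(4):
                if phib[i, k] <= 0.0:
                    continue
                I4 = fG2[i, k] * (fs2a[i, k] * Ctt + (1.0 - fs2a[i, k]) * lambda_z * lambda_z)
                xk = I4 - 1.0
                if I4 >= 1.0:
                    c1 = fc1p[i, k]
                    c2 = fc2p[i, k]
                else:
                    c1 = fc1m[i, k]
                    c2 = fc2m[i, k]
                wth += phib[i, k] * c1 * xk * np.exp(c2 * xk * xk) * fG2[i, k] * fs2a[i, k]
            S00 += wth * ex * ex
            S01 += wth * ex * ey
            S11 += wth * ey * ey
            P[i, 0, 0] = F00 * S00 + F01 * S01
            P[i, 0, 1] = F00 * S01 + F01 * S11
            P[i, 1, 0] = F10 * S00 + F11 * S01
            P[i, 1, 1] = F10 * S01 + F11 * S11
            if tone_on and contractile[i] and act_coef[i] > 0.0:
                lt = np.sqrt(Ctt)
                if lam_min <= lt <= lam_max:
                    sa = act_coef[i] * lt * (1.0 - ((lam_max - lt) / (lam_max - lam_min)) ** 2)
                    r = np.sqrt(x[i, 0] ** 2 + x[i, 1] ** 2)
                    tx = -x[i, 1] / r
                    ty = x[i, 0] / r
                    # P_act = J sa (t x t) F^{-T}
                    P[i, 0, 0] += J * sa * tx * (tx * iF00 + ty * iF01)
                    P[i, 0, 1] += J * sa * tx * (tx * iF10 + ty * iF11)
                    P[i, 1, 0] += J * sa * ty * (tx * iF00 + ty * iF01)
                    P[i, 1, 1] += J * sa * ty * (tx * iF10 + ty * iF11)
        if eta > 0.0:
            # P_visc = 2 eta J d F^{-T}, d = sym(Fdot F^{-1})
            d00 = (F00 - F_prev[i, 0, 0]) / dt
            d01 = (F01 - F_prev[i, 0, 1]) / dt
            d10 = (F10 - F_prev[i, 1, 0]) / dt
            d11 = (F11 - F_prev[i, 1, 1]) / dt
            l00 = d00 * iF00 + d01 * iF01
            l01 = d00 * iF10 + d01 * iF11
            l10 = d10 * iF00 + d11 * iF01
            l11 = d10 * iF10 + d11 * iF11
            sym01 = 0.5 * (l01 + l10)
            P[i, 0, 0] += 2.0 * eta * J * (l00 * iF00 + sym01 * iF01)
            P[i, 0, 1] += 2.0 * eta * J * (l00 * iF10 + sym01 * iF11)
            P[i, 1, 0] += 2.0 * eta * J * (sym01 * iF00 + l11 * iF01)
            P[i, 1, 1] += 2.0 * eta * J * (sym01 * iF10 + l11 * iF11)
    return 0


@njit(cache=True)
def edge_forces(
    x,
    P,
    F,
    src,
    dst,
    rot_c,
    rot_s,
    rvec,
    rlen,
    weight,
    grad_corr,
    active,
    V,
    alpha_E,
    f,
):
    """Internal (pairwise antisymmetric) plus hourglass forces.

    Internal: each directed edge contributes t = Vi Vj P_i grad~ to its
    source and the back-rotated -t to its target, so pair contributions
    are equal and opposite by construction.

    Hourglass: the full symmetric pair term is accumulated on the source
    only; the transposed edge supplies the reaction.  delta is the
    projection of the affine-prediction error F R - r onto the current
    pair direction.  ``alpha_E`` is the per-edge penalty stiffness
    alpha * E_pair (E_pair follows the local material modulus, as in FEM
    hourglass control).  Returns the summed |t| for the force scale.
    """
    f[:] = 0.0
    gross = 0.0
    for e in range(src.shape[0]):
        if not active[e]:
            continue
        i = src[e]
        j = dst[e]
        c = rot_c[e]
        s = rot_s[e]
        vv = V[i] * V[j]
        gx = grad_corr[e, 0]
        gy = grad_corr[e, 1]
        tx = vv * (P[i, 0, 0] * gx + P[i, 0, 1] * gy)
        ty = vv * (P[i, 1, 0] * gx + P[i, 1, 1] * gy)
        f[i, 0] += tx
        f[i, 1] += ty
        # reaction on the real neighbour, rotated back from image space
        f[j, 0] -= c * tx + s * ty
        f[j, 1] -= -s * tx + c * ty
        gross += np.sqrt(tx * tx + ty * ty)
        if alpha_E[e] > 0.0:
            # current offset to the (image of the) neighbour
            xjx = c * x[j, 0] - s * x[j, 1]
            xjy = s * x[j, 0] + c * x[j, 1]
            rx = xjx - x[i, 0]
            ry = xjy - x[i, 1]
            rl = np.sqrt(rx * rx + ry * ry)
            ux = rx / rl
            uy = ry / rl
            Rx = rvec[e, 0]
            Ry = rvec[e, 1]
            di = (F[i, 0, 0] * Rx + F[i, 0, 1] * Ry - rx) * ux + (
                F[i, 1, 0] * Rx + F[i, 1, 1] * Ry - ry
            ) * uy
            # neighbour's F conjugated into image space: Rot F Rot^T
            a00 = c * F[j, 0, 0] - s * F[j, 1, 0]
            a01 = c * F[j, 0, 1] - s * F[j, 1, 1]
            a10 = s * F[j, 0, 0] + c * F[j, 1, 0]
            a11 = s * F[j, 0, 1] + c * F[j, 1, 1]
            b00 = a00 * c - a01 * s
            b01 = a00 * s + a01 * c
            b10 = a10 * c - a11 * s
            b11 = a10 * s + a11 * c
            dj = (b00 * Rx + b01 * Ry - rx) * ux + (b10 * Rx + b11 * Ry - ry) * uy
            coef = -alpha_E[e] * vv * weight[e] / (2.0 * rlen[e] * rlen[e]) * (di + dj)
            f[i, 0] += coef * ux
            f[i, 1] += coef * uy
    return gross


@njit(cache=True)
def run_relax(
    x,
    v,
    m,
    V,
    # edges
    src,
    dst,
    rot_c,
    rot_s,
    rvec,
    rlen,
    weight,
    grad_corr,
    active,
    live,
    # materials
    phi_e,
    mu,
    lam,
    Ge2,
    gz2,
    fc1p,
    fc2p,
    fc1m,
    fc2m,
    fG2,
    fs2a,
    phib,
    et,
    act_coef,
    contractile,
    is_gag,
    mu_gag,
    p_swell,
    ruptured,
    lam_max,
    lam_min,
    lambda_z,
    tone_on,
    # boundary conditions
    constrained,
    x_start,
    x_target,
    ramp_steps,
    # solver parameters
    dt,
    eta,
    alpha_E,
    damp,
    kinetic_damping,
    tol_ke,
    tol_f,
    check_every,
    max_steps,
):
    """Leapfrog dynamic relaxation to quasi-static equilibrium (in place).

    Returns (status, steps, ke, ke_peak, fmax, fscale).
    """
    n = x.shape[0]
    F = np.zeros((n, 2, 2))
    F_prev = np.zeros((n, 2, 2))
    P = np.zeros((n, 2, 2))
    f = np.zeros((n, 2))
    f_old = np.zeros((n, 2))
    edge_deformation_gradients(x, src, dst, rot_c, rot_s, grad_corr, active, V, live, F)
    F_prev[:] = F
    ke_peak = 1e-300
    ke_prev = 0.0
    ke_prev2 = 0.0
    ke = 0.0
    fmax = 0.0
    vmax = 0.0
    fscale = 1.0
    status = STATUS_MAXSTEPS
    steps = 0
    for step in range(max_steps):
        steps = step + 1
        # boundary ramp: prescribed particles follow a smooth schedule
        if ramp_steps > 0 and step <= ramp_steps:
            frac = step / ramp_steps
            frac = frac * frac * (3.0 - 2.0 * frac)  # smoothstep
        else:
            frac = 1.0
        for i in range(n):
            if constrained[i]:
                x[i, 0] = x_start[i, 0] + frac * (x_target[i, 0] - x_start[i, 0])
                x[i, 1] = x_start[i, 1] + frac * (x_target[i, 1] - x_start[i, 1])
                v[i, 0] = 0.0
                v[i, 1] = 0.0
        edge_deformation_gradients(x, src, dst, rot_c, rot_s, grad_corr, active, V, live, F)
        st = particle_stress(
            F, F_prev, x,
            phi_e, mu, lam, Ge2, gz2,
            fc1p, fc2p, fc1m, fc2m, fG2, fs2a, phib,
            et, act_coef, contractile, is_gag, mu_gag, p_swell, ruptured,
            lam_max, lam_min, lambda_z, tone_on, eta, dt, P,
        )
        if st != 0:
            status = st
            break
        F_prev[:] = F
        gross = edge_forces(
            x, P, F, src, dst, rot_c, rot_s, rvec, rlen, weight, grad_corr,
            active, V, alpha_E, f,
        )
        n_free = 0
        ke = 0.0
        fmax = 0.0
        vmax = 0.0
        past_ramp = step > ramp_steps
        # adaptive near-critical damping (dynamic relaxation): estimate the
        # dominant frequency from the Rayleigh quotient of the local
        # stiffness sampled along the current velocity,
        # k ~ -(df/dx) = (f_prev - f) / (v dt)
        local_damp = damp
        if damp < 0.0:
            num = 0.0
            den = 0.0
            for i in range(n):
                if constrained[i] or not live[i]:
                    continue
                num += v[i, 0] * (f_old[i, 0] - f[i, 0]) + v[i, 1] * (f_old[i, 1] - f[i, 1])
                den += m[i] * (v[i, 0] ** 2 + v[i, 1] ** 2)
            if den > 0.0 and num > 0.0:
                w = np.sqrt(num / (den * dt))
                local_damp = (1.0 - w * dt) / (1.0 + w * dt)
                if local_damp < 0.7:
                    local_damp = 0.7
                elif local_damp > 0.999:
                    # near-zero sampled stiffness: critical damping would be
                    # none at all, but force-free drift must still decay
                    local_damp = 0.999
            else:
                local_damp = 0.999
        for i in range(n):
            f_old[i, 0] = f[i, 0]
            f_old[i, 1] = f[i, 1]
            if constrained[i] or not live[i]:
                continue
            n_free += 1
            ax = f[i, 0] / m[i]
            ay = f[i, 1] / m[i]
            v[i, 0] = local_damp * v[i, 0] + dt * ax
            v[i, 1] = local_damp * v[i, 1] + dt * ay
            x[i, 0] += dt * v[i, 0]
            x[i, 1] += dt * v[i, 1]
            ke += 0.5 * m[i] * (v[i, 0] ** 2 + v[i, 1] ** 2)
            fm = np.sqrt(f[i, 0] ** 2 + f[i, 1] ** 2)
            if fm > fmax:
                fmax = fm
            vm = np.sqrt(v[i, 0] ** 2 + v[i, 1] ** 2)
            if vm > vmax:
                vmax = vm
        if not np.isfinite(ke):
            status = STATUS_NONFINITE
            break
        if ke > ke_peak:
            ke_peak = ke
        # kinetic damping: zero velocities when kinetic energy peaks,
        # then restart the peak accounting from zero
        if kinetic_damping and past_ramp and ke < ke_prev and ke_prev > ke_prev2:
            for i in range(n):
                if not constrained[i]:
                    v[i, 0] = 0.0
                    v[i, 1] = 0.0
            ke_prev = 0.0
            ke_prev2 = 0.0
        else:
            ke_prev2 = ke_prev
            ke_prev = ke
        if past_ramp and step % check_every == 0:
            fscale = gross / max(n_free, 1)
            # absolute floors: a stress-free state has no meaningful force
            # scale, so noise-level forces/energies count as converged
            ke_ok = ke / ke_peak < tol_ke or ke < 1e-18
            f_ok = fmax < tol_f * fscale or fmax < 1e-10
            still = vmax * dt < 1e-6
            if f_ok and (ke_ok or still):
                status = STATUS_CONVERGED
                break
    return status, steps, ke, ke_peak, fmax, fscale
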