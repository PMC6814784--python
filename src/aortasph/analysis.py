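"""Bulk and transmural observables, plus the thin-wall analytic oracle.

The thin-wall oracle homogenises the layered wall into a single mixture
(thickness-weighted group fractions), evaluates the mean circumferential
Cauchy stress under incompressible membrane kinematics
(lambda_r = 1/lambda_theta at fixed axial stretch) and reports the
Laplace pressure P = sigma_theta h / r_in.  It is a validation target for
the particle model's bulk pressure-diameter response, never a substitute
for it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constitutive import active_stress, passive_stress
from .dynamics import EquilibriumRecord, WallModel
from .geometry import ParticleSystem
from .materials import MMHG_TO_KPA, MaterialParams, build_material_state
from . import materials as mats


def group_volume_fractions(system: ParticleSystem) -> dict:
    """Reference volume fraction of each particle group."""
    out = {}
    tot = float(system.V.sum())
    for code, name in mats.GROUP_NAMES.items():
        out[name] = float(system.V[system.group == code].sum()) / tot
    return out


def _single_particle_state(group_code: int, params: MaterialParams):
    er = np.array([[1.0, 0.0]])
    et = np.array([[0.0, 1.0]])
    return build_material_state(np.array([group_code]), er, et, params)


def thin_wall_pressure(system: ParticleSystem, lam_theta, active: bool = False,
                       params: MaterialParams | None = None):
    """Laplace-law pressure (mmHg) of the homogenised wall at stretch(es).

    lambda_theta is the mid-wall circumferential stretch; incompressible
    membrane kinematics give lambda_r = 1/lambda_theta, thickness
    h = H / lambda_theta and r_in = lambda_theta R_mid - h/2.
    """
    params = params or system.params or MaterialParams()
    fr = group_volume_fractions(system)
    lam = np.atleast_1d(np.asarray(lam_theta, dtype=float))
    geom = system.geometry
    states = {name: _single_particle_state(code, params)
              for code, name in mats.GROUP_NAMES.items() if name != "GAG"}
    P_out = np.empty(lam.size)
    for i, lt in enumerate(lam):
        F = np.array([[[1.0 / lt, 0.0], [0.0, lt]]])
        s_mean = 0.0
        for name, st in states.items():
            _, sig, _ = passive_stress(F, st)
            # membrane plane stress: the through-thickness reaction
            # enforces sigma_rr ~ 0, so the physically carried hoop
            # stress is the difference sigma_tt - sigma_rr
            s_mean += fr[name] * (sig[0, 1, 1] - sig[0, 0, 0])
        if active:
            st = states["M_int"]
            s_act = active_stress(lt, st.act_coef, st.lam_max, st.lam_min)
            s_mean += fr["M_int"] * float(np.atleast_1d(s_act)[0])
        h = geom.thickness / lt
        r_mid = lt * (geom.r_in + geom.thickness / 2.0)
        r_in = r_mid - h / 2.0
        P_out[i] = s_mean * h / r_in / MMHG_TO_KPA
    return P_out if np.ndim(lam_theta) else float(P_out[0])


def thin_wall_curve(system: ParticleSystem, lam_grid, active: bool = False) -> pd.DataFrame:
    """Pressure-diameter table of the homogenised membrane model."""
    lam_grid = np.asarray(lam_grid, dtype=float)
    geom = system.geometry
    P = thin_wall_pressure(system, lam_grid, active=active)
    h = geom.thickness / lam_grid
    r_mid = lam_grid * (geom.r_in + geom.thickness / 2.0)
    return pd.DataFrame(
        {
            "lam_theta": lam_grid,
            "pressure_mmhg": P,
            "outer_diameter_um": 2.0 * (r_mid + h / 2.0),
        }
    )


def pressure_diameter_curve(model: WallModel, rim_scales, active: bool | None = None) -> pd.DataFrame:
    """Equilibrate the particle model over a sweep of rim radii.

    Returns one row per converged equilibrium: reported pressure, outer
    diameter, mean circumferential stretch and stress.  Sweeps should be
    ordered (monotone rim scales) so each point warm-starts the next.
    """
    rows = []
    for s in rim_scales:
        rec = model.equilibrate_rim_scale(float(s), tone_on=active)
        rows.append(
            {
                "rim_scale": float(s),
                "pressure_mmhg": rec.pressure_mmhg,
                "outer_diameter_um": rec.outer_diameter,
                "lam_theta": rec.lam_theta,
                "sigma_theta_mean_kpa": rec.sigma_theta_mean,
            }
        )
    return pd.DataFrame(rows)


def transmural_profile(record: EquilibriumRecord, system: ParticleSystem,
                       theta_deg: float, window_deg: float = 2.0) -> pd.DataFrame:
    """Stress profile along a radial line (angular window around theta).

    Rows sorted by current radius; used to inspect load transfer across a
    defect midline.
    """
    th = np.rad2deg(system.theta)
    half = max(window_deg, np.rad2deg(system.geometry.spacing / system.geometry.r_in)) / 2.0
    mask = np.abs(th - theta_deg) <= half
    if not mask.any():
        raise ValueError("empty angular window")
    r = np.linalg.norm(record.x[mask], axis=1)
    df = pd.DataFrame(
        {
            "radius_um": r,
            "ref_radius_um": system.R[mask],
            "group": [mats.GROUP_NAMES[g] for g in system.group[mask]],
            "sigma_tt_kpa": record.sigma_tt[mask],
            "sigma_rr_kpa": record.sigma_rr[mask],
        }
    )
    return df.sort_values("radius_um", ignore_index=True)
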