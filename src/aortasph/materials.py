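"""Constituent specifications for the layered aortic wall.

Each particle carries a mixture of constituents through mass fractions:
an (anisotropically prestretched) neo-Hookean elastin matrix plus up to
four exponential fiber families (axial, circumferential, two symmetric
diagonals).  Deposition prestretches make the in vivo loaded state the
kinematic reference: ``F = I`` there, yet every constituent is stressed
through its own prestretch (``F_e = F G_e`` for elastin,
``C_k = G_k^2 C`` for fibers) — the constrained-mixture convention.

Parameter defaults are the murine descending-thoracic-aorta set used
throughout the package; stresses in kPa, lengths in um.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

# group codes
M_EL, M_INT, ADV, GAG = 0, 1, 2, 3
GROUP_NAMES = {M_EL: "M_el", M_INT: "M_int", ADV: "A", GAG: "GAG"}

# fiber family slots: axial, circumferential, diagonal(+), diagonal(-)
N_FAM = 4

MMHG_TO_KPA = 0.133322

#: universal gas constant (J / mol K)
R_GAS = 8.314
#: absolute body temperature (K)
T_BODY = 310.0


@dataclass
class MaterialParams:
    """Wall material constants (murine thoracic aorta defaults)."""

    # elastin (neo-Hookean matrix)
    mu: float = 89.71            # kPa
    lam_hat_ratio: float = 1000.0  # lambda_hat / mu, near-incompressibility penalty

    # medial axial + diagonal collagen (tension / compression)
    med_c1p: float = 234.9       # kPa
    med_c2p: float = 4.08
    med_c1m: float = 29.14       # kPa
    med_c2m: float = 4.08
    alpha0_deg: float = 29.91    # diagonal family angle from the axial direction

    # medial SMC + circumferential collagen
    smc_c1p: float = 261.4       # kPa
    smc_c2p: float = 0.24
    smc_c1m: float = 249.5       # kPa
    smc_c2m: float = 0.15

    # adventitial collagen (all families)
    adv_c1p: float = 234.9
    adv_c2p: float = 4.08
    adv_c1m: float = 29.14
    adv_c2m: float = 4.08

    # mass fractions
    phi_mel_e: float = 1.0
    phi_mint_e: float = 0.1
    phi_mint_c2: float = 0.84
    phi_mint_c134: float = 0.06
    beta_mint_z: float = 0.056
    beta_mint_d: float = 0.944
    phi_adv_e: float = 0.04
    phi_adv_c: float = 0.96
    beta_adv_z: float = 0.067
    beta_adv_d: float = 0.877
    beta_adv_t: float = 0.056

    # deposition prestretches (radial, circumferential, axial; all groups)
    Ge_r: float = 0.32
    Ge_t: float = 1.90
    Ge_z: float = 1.62
    Gk_smc: float = 1.20         # SMC + circumferential collagen
    Gk_col: float = 1.25         # remaining collagen families

    # active tone
    T_max: float = 500.0         # kPa
    lam_max: float = 1.1
    lam_min: float = 0.6

    # GAG pool
    mu_gag: float = 0.1          # kPa
    c_fc: float = 200.0          # fixed-charge concentration, mEq/l == mol/m^3
    c_star: float = 300.0        # bath ionic concentration, mEq/l

    @property
    def lam_hat(self) -> float:
        return self.lam_hat_ratio * self.mu

    def validate(self) -> None:
        if self.lam_max <= self.lam_min:
            raise ValueError("lam_max must exceed lam_min")
        if self.c_fc < 0 or self.c_star < 0:
            raise ValueError("ionic concentrations must be non-negative")
        s_int = self.phi_mint_e + self.phi_mint_c2 + self.phi_mint_c134
        s_adv = self.phi_adv_e + self.phi_adv_c
        if abs(s_int - 1.0) > 1e-9 or abs(s_adv - 1.0) > 1e-9:
            raise ValueError("constituent mass fractions must sum to 1")

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialParams":
        known = {f.name for f in fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown material parameters: {sorted(bad)}")
        return cls(**d)


def donnan_pressure(c_fc: float, c_star: float, temperature: float = T_BODY) -> float:
    """Gibbs-Donnan osmotic swelling pressure in kPa.

    ``RT (sqrt(c_fc^2 + c*^2) - c*)`` with concentrations in mEq/l
    (numerically equal to mol/m^3 for monovalent ions), giving Pa, here
    returned in kPa.  For the default pool (200 vs 300 mEq/l) this is
    ~156 kPa.
    """
    if c_fc < 0 or c_star < 0:
        raise ValueError("concentrations must be non-negative")
    return R_GAS * temperature * (np.sqrt(c_fc**2 + c_star**2) - c_star) / 1e3


@dataclass
class MaterialState:
    """Per-particle constitutive arrays consumed by the solver.

    Fiber families are stored dense (n, 4); a family with phib == 0 is
    inert.  ``phib`` is the product of the constituent mass fraction and
    its direction fraction beta.
    """

    phi_e: np.ndarray      # (n,) elastin mass fraction
    mu: np.ndarray         # (n,) kPa; zeroed on lamellar rupture
    lam: np.ndarray        # (n,) kPa
    Ge2: np.ndarray        # (n, 2, 2) in-plane elastin prestretch squared (frame-composed)
    gz2: np.ndarray        # (n,) out-of-plane (G_z lambda_z)^2
    fc1p: np.ndarray       # (n, 4)
    fc2p: np.ndarray
    fc1m: np.ndarray
    fc2m: np.ndarray
    fG2: np.ndarray        # (n, 4) fiber prestretch squared
    fs2a: np.ndarray       # (n, 4) sin^2 of family angle from axial
    phib: np.ndarray       # (n, 4)
    er: np.ndarray         # (n, 2) reference radial unit vector
    et: np.ndarray         # (n, 2) reference circumferential unit vector
    act_coef: np.ndarray   # (n,) phi_c2 * T_max (kPa); 0 where no tone
    contractile: np.ndarray  # (n,) bool; step I sets False
    is_gag: np.ndarray     # (n,) bool
    mu_gag: np.ndarray     # (n,) kPa
    p_swell: np.ndarray    # (n,) kPa; step III sets Donnan pressure
    ruptured: np.ndarray   # (n,) bool; detached from all neighbour lists
    lam_max: float = 1.1
    lam_min: float = 0.6

    @property
    def n(self) -> int:
        return self.phi_e.shape[0]

    def copy(self) -> "MaterialState":
        return MaterialState(
            **{
                f.name: (getattr(self, f.name).copy() if isinstance(getattr(self, f.name), np.ndarray) else getattr(self, f.name))
                for f in fields(self)
            }
        )


def build_material_state(group, er, et, params: MaterialParams, lambda_z: float = 1.0) -> MaterialState:
    """Assemble per-particle constitutive arrays from group labels.

    Parameters
    ----------
    group:
        (n,) int array of group codes (M_EL, M_INT, ADV).
    er, et:
        (n, 2) reference radial / circumferential unit vectors.
    lambda_z:
        Axial stretch relative to the prestretched reference (1 for all
        simulations here; the in vivo axial stretch lives inside G_z).
    """
    params.validate()
    p = params
    group = np.asarray(group)
    n = group.shape[0]
    phi_e = np.where(group == M_EL, p.phi_mel_e, np.where(group == M_INT, p.phi_mint_e, p.phi_adv_e))
    mu = np.full(n, p.mu)
    lam = np.full(n, p.lam_hat)
    # in-plane elastin prestretch squared in the particle's local frame
    Ge2 = (
        p.Ge_r**2 * np.einsum("ni,nj->nij", er, er)
        + p.Ge_t**2 * np.einsum("ni,nj->nij", et, et)
    )
    gz2 = np.full(n, (p.Ge_z * lambda_z) ** 2)

    s2a_diag = np.sin(np.deg2rad(p.alpha0_deg)) ** 2
    fs2a = np.tile(np.array([0.0, 1.0, s2a_diag, s2a_diag]), (n, 1))

    fc1p = np.zeros((n, N_FAM))
    fc2p = np.ones((n, N_FAM))
    fc1m = np.zeros((n, N_FAM))
    fc2m = np.ones((n, N_FAM))
    fG2 = np.ones((n, N_FAM))
    phib = np.zeros((n, N_FAM))

    mint = group == M_INT
    adv = group == ADV
    # medial intra-lamellar: SMC+circ collagen family plus axial/diagonal collagen
    phib[mint, 0] = p.phi_mint_c134 * p.beta_mint_z
    phib[mint, 1] = p.phi_mint_c2
    phib[mint, 2] = phib[mint, 3] = p.phi_mint_c134 * p.beta_mint_d / 2.0
    for k, (c1p, c2p, c1m, c2m, G) in enumerate(
        [
            (p.med_c1p, p.med_c2p, p.med_c1m, p.med_c2m, p.Gk_col),
            (p.smc_c1p, p.smc_c2p, p.smc_c1m, p.smc_c2m, p.Gk_smc),
            (p.med_c1p, p.med_c2p, p.med_c1m, p.med_c2m, p.Gk_col),
            (p.med_c1p, p.med_c2p, p.med_c1m, p.med_c2m, p.Gk_col),
        ]
    ):
        fc1p[mint, k], fc2p[mint, k] = c1p, c2p
        fc1m[mint, k], fc2m[mint, k] = c1m, c2m
        fG2[mint, k] = G**2
    # adventitia: one set of constants for all four families
    phib[adv, 0] = p.phi_adv_c * p.beta_adv_z
    phib[adv, 1] = p.phi_adv_c * p.beta_adv_t
    phib[adv, 2] = phib[adv, 3] = p.phi_adv_c * p.beta_adv_d / 2.0
    fc1p[adv], fc2p[adv] = p.adv_c1p, p.adv_c2p
    fc1m[adv], fc2m[adv] = p.adv_c1m, p.adv_c2m
    fG2[adv] = p.Gk_col**2

    act_coef = np.where(mint, p.phi_mint_c2 * p.T_max, 0.0)

    return MaterialState(
        phi_e=phi_e.astype(float),
        mu=mu,
        lam=lam,
        Ge2=Ge2,
        gz2=gz2,
        fc1p=fc1p,
        fc2p=fc2p,
        fc1m=fc1m,
        fc2m=fc2m,
        fG2=fG2,
        fs2a=fs2a,
        phib=phib,
        er=np.ascontiguousarray(er, dtype=float),
        et=np.ascontiguousarray(et, dtype=float),
        act_coef=act_coef,
        contractile=mint.copy(),
        is_gag=np.zeros(n, dtype=bool),
        mu_gag=np.full(n, p.mu_gag),
        p_swell=np.zeros(n),
        ruptured=np.zeros(n, dtype=bool),
        lam_max=p.lam_max,
        lam_min=p.lam_min,
    )
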