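"""Spiky kernel and its gradient.

The smoothing kernel is a third-order polynomial ("Spiky") with compact
support ``h``:

    xi(R) = 10 (h - R)^3 / (pi h^5)   for R < h,   0 otherwise.

It is normalised in 2D (``integral xi dA = 1``) and, unlike the cubic
B-spline, keeps a non-vanishing gradient as R -> 0, which avoids particle
clumping in collocation solid mechanics.  All lengths are in micrometres,
so weights carry units of 1/um^2 and gradients 1/um^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class KernelModel:
    """Compactly supported Spiky kernel.

    Parameters
    ----------
    support_radius:
        Kernel support ``h`` in um.  Distinct from the wall thickness,
        which also uses the letter *h* in Laplace-law formulas.
    """

    support_radius: float

    def __post_init__(self) -> None:
        if not self.support_radius > 0:
            raise ValueError("kernel support_radius must be positive")

    def weight(self, distance):
        return kernel_weight(distance, self.support_radius)

    def gradient(self, offset):
        return kernel_gradient(offset, self.support_radius)


def kernel_weight(distance, support):
    """Evaluate the Spiky kernel ``xi(R)``.

    Parameters
    ----------
    distance:
        Scalar or array of non-negative reference distances R (um).
    support:
        Kernel support h (um), positive.

    Returns
    -------
    Weight(s) with 2D units 1/um^2; exactly 0 at and beyond ``support``.
    """
    R = np.asarray(distance, dtype=float)
    if not support > 0:
        raise ValueError("kernel support must be positive")
    if np.any(R < 0):
        raise ValueError("kernel distance must be non-negative")
    w = np.where(R < support, 10.0 * (support - R) ** 3 / (np.pi * support**5), 0.0)
    if np.isscalar(distance) or np.ndim(distance) == 0:
        return float(w)
    return w


def kernel_gradient(offset, support):
    """Referential gradient of the Spiky kernel.

    ``grad xi = (d xi / d R) * R_vec / R`` with
    ``d xi / d R = -30 (h - R)^2 / (pi h^5)``, so the gradient points from
    the neighbour towards the particle (down-hill in weight).

    A zero offset returns the zero vector by convention; particles are
    never their own neighbours, so this only arises for coincident
    particles, which lattice construction rejects.

    Parameters
    ----------
    offset:
        Reference offset vector(s) ``R_j = X_j - X_i``, shape (..., 2).
    support:
        Kernel support h (um).
    """
    if not support > 0:
        raise ValueError("kernel support must be positive")
    Rv = np.asarray(offset, dtype=float)
    scalar = Rv.ndim == 1
    Rv = np.atleast_2d(Rv)
    R = np.linalg.norm(Rv, axis=-1)
    mag = np.zeros_like(R)
    inside = (R > 0) & (R < support)
    mag[inside] = -30.0 * (support - R[inside]) ** 2 / (np.pi * support**5)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(R[..., None] > 0, Rv / np.where(R[..., None] > 0, R[..., None], 1.0), 0.0)
    g = mag[..., None] * unit
    return g[0] if scalar else g
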