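"""Neighbour tables, corrected kernel gradients, and discrete kinematics.

This is a total-Lagrangian formulation: neighbour sets, kernel weights and
gradients are all evaluated once on the *reference* lattice and then reused
at every step, which is what makes severing reference connectivity a
faithful model of material rupture.

First-order completeness of the discrete gradient is restored with a
per-particle correction matrix

    A_i = sum_j V_j grad(xi)(R_j) (x) R_j,
    corrected grad = A_i^{-1} grad(xi)(R_j),

so that affine deformations are reproduced exactly, including at free
boundaries (no ghost particles are needed).

Rotational sector periodicity: a particle near a sector edge sees *images*
of particles from the opposite edge, rotated by +/- the sector angle.
Edges store a rotation code; forces computed on an image are mapped back to
the real particle by the inverse rotation.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .kernels import kernel_gradient, kernel_weight

_COND_LIMIT = 1e8


class BoundaryDeficiencyError(RuntimeError):
    """Raised when a particle's correction matrix is (near) singular."""


class NeighborTable:
    """Directed-edge neighbour table over a fixed reference lattice.

    Every undirected neighbour pair appears as two directed edges, one per
    endpoint, so per-particle sums are plain segment reductions over ``src``.
    ``rot`` holds the sector-rotation power s in {-1, 0, +1} applied to the
    neighbour's coordinates (0 for ordinary pairs).
    """

    def __init__(self, ref_positions, volumes, support, sector_angle=None):
        X = np.ascontiguousarray(ref_positions, dtype=float)
        V = np.ascontiguousarray(volumes, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("ref_positions must have shape (n, 2)")
        if V.shape != (X.shape[0],):
            raise ValueError("volumes must have shape (n,)")
        if not support > 0:
            raise ValueError("support must be positive")
        self.n = X.shape[0]
        self.support = float(support)
        self.sector_angle = None if sector_angle is None else float(sector_angle)
        self.X = X
        self.V = V
        self._build_edges()
        self.compute_corrections()

    # -- construction ---------------------------------------------------

    def _rotation(self, s):
        if s == 0 or self.sector_angle is None:
            return np.eye(2)
        a = s * self.sector_angle
        c, si = np.cos(a), np.sin(a)
        return np.array([[c, -si], [si, c]])

    def _build_edges(self):
        X, h, n = self.X, self.support, self.n
        shifts = [0] if self.sector_angle is None else [-1, 0, 1]
        pts = np.concatenate([X @ self._rotation(s).T for s in shifts], axis=0)
        tree = cKDTree(pts)
        src_l, dst_l, rot_l = [], [], []
        for i, hits in enumerate(tree.query_ball_point(X, h)):
            for k in hits:
                s = shifts[k // n]
                j = k % n
                if s == 0 and j == i:
                    continue
                d = pts[k] - X[i]
                R = float(np.hypot(d[0], d[1]))
                if R >= h:
                    continue
                if R == 0.0:
                    raise ValueError(f"coincident particles {i} and {j} (rot {s})")
                src_l.append(i)
                dst_l.append(j)
                rot_l.append(s)
        if not src_l:
            raise ValueError("no neighbour pairs found (support too small?)")
        src = np.asarray(src_l, dtype=np.int64)
        order = np.argsort(src, kind="stable")
        self.src = src[order]
        self.dst = np.asarray(dst_l, dtype=np.int64)[order]
        self.rot = np.asarray(rot_l, dtype=np.int8)[order]
        counts = np.bincount(self.src, minlength=n)
        if np.any(counts == 0):
            lonely = int(np.flatnonzero(counts == 0)[0])
            raise ValueError(f"isolated particle {lonely}: no neighbours within support")
        # per-edge image rotation entries (cos, sin of s * sector angle)
        ang = (
            np.zeros(self.src.size)
            if self.sector_angle is None
            else self.rot.astype(float) * self.sector_angle
        )
        self.rot_cos = np.cos(ang)
        self.rot_sin = np.sin(ang)
        img = self.rotate(self.X[self.dst])
        self.rvec = img - self.X[self.src]
        self.rlen = np.linalg.norm(self.rvec, axis=1)
        self.weight = kernel_weight(self.rlen, h)
        self.grad_raw = kernel_gradient(self.rvec, h)
        self.active = np.ones(self.src.size, dtype=bool)

    def rotate(self, vec, inverse=False):
        """Apply each edge's image rotation to per-edge vectors (E, 2)."""
        c = self.rot_cos
        s = -self.rot_sin if inverse else self.rot_sin
        out = np.empty_like(vec)
        out[:, 0] = c * vec[:, 0] - s * vec[:, 1]
        out[:, 1] = s * vec[:, 0] + c * vec[:, 1]
        return out

    # -- corrected gradients --------------------------------------------

    def compute_corrections(self):
        """(Re)build correction matrices and corrected gradients.

        Must be called after any change to the active-edge set; severed
        pairs contribute to no sums.
        """
        n = self.n
        w = np.where(self.active, self.V[self.dst], 0.0)
        A = np.empty((n, 2, 2))
        for a in range(2):
            for b in range(2):
                A[:, a, b] = np.bincount(
                    self.src, weights=w * self.grad_raw[:, a] * self.rvec[:, b], minlength=n
                )
        # only particles that still have active edges need invertible A
        live = np.bincount(self.src, weights=self.active.astype(float), minlength=n) > 0
        sv = np.linalg.svd(A[live], compute_uv=False)
        bad = (sv[:, -1] <= 0) | (sv[:, 0] / np.where(sv[:, -1] > 0, sv[:, -1], 1.0) > _COND_LIMIT)
        if np.any(bad):
            pid = int(np.flatnonzero(live)[np.flatnonzero(bad)[0]])
            raise BoundaryDeficiencyError(
                f"particle {pid}: correction matrix singular or ill-conditioned "
                "(fewer than 3 non-collinear neighbours?)"
            )
        Ainv = np.zeros_like(A)
        Ainv[live] = np.linalg.inv(A[live])
        self.A = A
        self.grad_corr = np.einsum("eab,eb->ea", Ainv[self.src], self.grad_raw)
        self.grad_corr[~self.active] = 0.0
        self.live = live
        return A

    # -- surgery ---------------------------------------------------------

    def sever_pairs(self, pairs, recompute=True):
        """Deactivate the undirected pairs ``(i, j)`` in both directions."""
        pairs = np.atleast_2d(np.asarray(pairs, dtype=np.int64))
        key = set()
        for i, j in pairs:
            key.add((int(i), int(j)))
            key.add((int(j), int(i)))
        hit = np.fromiter(
            ((int(s), int(d)) in key for s, d in zip(self.src, self.dst)),
            dtype=bool,
            count=self.src.size,
        )
        self.active &= ~hit
        if recompute:
            self.compute_corrections()

    def detach_particles(self, ids, recompute=True):
        """Remove particles from *all* neighbour lists (rupture step ii)."""
        mask = np.zeros(self.n, dtype=bool)
        mask[np.asarray(ids, dtype=np.int64)] = True
        self.active &= ~(mask[self.src] | mask[self.dst])
        if recompute:
            self.compute_corrections()

    def n_neighbors(self):
        return np.bincount(self.src, weights=self.active.astype(float), minlength=self.n).astype(int)

    def n_active_pairs(self):
        return int(self.active.sum()) // 2

    # -- discrete operators ----------------------------------------------

    def approximate_field(self, values, include_self=True):
        """Kernel-smoothed field  g_hat(X_i) = sum_j g(X_j) V_j xi(R_j).

        The particle's own term ``g_i V_i xi(0)`` is included by default:
        the Spiky kernel carries ~35% of its discrete partition of unity at
        R = 0, so dropping it would destroy zeroth-order consistency.
        Gradient and force sums are unaffected (the self-gradient is zero).
        """
        g = np.asarray(values, dtype=float)
        w = np.where(self.active, self.V[self.dst] * self.weight, 0.0)
        out = np.bincount(self.src, weights=w * g[self.dst], minlength=self.n)
        if include_self:
            out = out + g * self.V * kernel_weight(0.0, self.support)
        return out

    def partition_of_unity(self, include_self=True):
        return self.approximate_field(np.ones(self.n), include_self=include_self)

    def deformation_gradient(self, current_positions, lambda_z=1.0, check=True):
        """Per-particle deformation gradient F_i = sum_j r_j (x) V_j grad~(R_j).

        Returns the in-plane (n, 2, 2) block; ``J = det(F) * lambda_z``.
        Particles with no active edges (fully detached) get F = I.
        """
        x = np.asarray(current_positions, dtype=float)
        r = self.rotate(x[self.dst]) - x[self.src]
        w = np.where(self.active, self.V[self.dst], 0.0)
        F = np.empty((self.n, 2, 2))
        for a in range(2):
            for b in range(2):
                F[:, a, b] = np.bincount(
                    self.src, weights=w * r[:, a] * self.grad_corr[:, b], minlength=self.n
                )
        F[~self.live] = np.eye(2)
        if check:
            J = (F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]) * lambda_z
            if np.any(J <= 0):
                bad = int(np.argmin(J))
                raise FloatingPointError(f"element inversion: J <= 0 at particle {bad}")
        return F
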