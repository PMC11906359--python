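"""Linear-algebra primitives on the Grassmann manifold Gr(G, P).

A point of Gr(G, P) is a P-dimensional linear subspace of R^G, represented
computationally by one orthonormal G x P basis matrix (a representative of
the equivalence class of bases spanning the same subspace).  Tangent vectors
at a base point ``o`` are represented by G x P matrices ``A`` satisfying the
horizontality condition ``o.T @ A = 0``.

These primitives back the condition-dependent subspaces of the latent
embedding regression model: every condition's subspace is reached from a
shared base point through the exponential map, and tangent vectors are
recovered from fitted per-condition subspaces through the logarithm map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrassmannPoint",
    "TangentVector",
    "grassmann_exp",
    "grassmann_log",
    "principal_angles",
    "orthonormalize",
    "zero_tangent",
]

_ORTHO_TOL = 1e-8


def _fix_column_signs(m: np.ndarray) -> np.ndarray:
    """Flip column signs so the largest-magnitude entry of each column is positive.

    SVD/QR factors are sign-ambiguous; fixing a convention makes fits
    reproducible across runs and BLAS backends.
    """
    if m.size == 0:
        return m
    idx = np.argmax(np.abs(m), axis=0)
    signs = np.sign(m[idx, np.arange(m.shape[1])])
    signs[signs == 0] = 1.0
    return m * signs


@dataclass(frozen=True)
class GrassmannPoint:
    """A P-dimensional subspace of R^G, stored as one orthonormal representative."""

    basis: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        basis = np.ascontiguousarray(np.asarray(self.basis, dtype=float))
        object.__setattr__(self, "basis", basis)
        if basis.ndim != 2:
            raise ValueError("basis must be a 2-D matrix")
        g, p = basis.shape
        if not p < g:
            raise ValueError(f"subspace dimension P={p} must be < ambient dimension G={g}")
        gram = basis.T @ basis
        err = np.linalg.norm(gram - np.eye(p))
        if err > 1e-8:
            raise ValueError(
                f"basis columns are not orthonormal (||B'B - I||_F = {err:.2e}); "
                "use orthonormalize() first"
            )

    @property
    def ambient_dim(self) -> int:
        return self.basis.shape[0]

    @property
    def subspace_dim(self) -> int:
        return self.basis.shape[1]


@dataclass(frozen=True)
class TangentVector:
    """A tangent vector at ``base``, represented by a horizontal G x P matrix."""

    coords: np.ndarray = field(repr=False)
    base: GrassmannPoint

    def __post_init__(self) -> None:
        coords = np.ascontiguousarray(np.asarray(self.coords, dtype=float))
        object.__setattr__(self, "coords", coords)
        if coords.shape != self.base.basis.shape:
            raise ValueError(
                f"tangent coords shape {coords.shape} does not match base "
                f"{self.base.basis.shape}"
            )
        horiz = np.linalg.norm(self.base.basis.T @ coords)
        scale = max(1.0, np.linalg.norm(coords))
        if horiz > _ORTHO_TOL * scale:
            raise ValueError(
                f"tangent is not horizontal at base (||o'A|| = {horiz:.2e})"
            )

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.coords))


def zero_tangent(base: GrassmannPoint) -> TangentVector:
    return TangentVector(np.zeros_like(base.basis), base)


def orthonormalize(m: np.ndarray) -> GrassmannPoint:
    """Orthonormal basis of the column space of ``m`` with a deterministic sign.

    Raises if ``m`` is rank deficient (the columns do not span a
    P-dimensional subspace).
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    u, s, _ = np.linalg.svd(m, full_matrices=False)
    p = m.shape[1]
    if s[-1] <= max(m.shape) * np.finfo(float).eps * s[0] or s[-1] == 0.0:
        raise np.linalg.LinAlgError(
            f"matrix is rank deficient (smallest singular value {s[-1]:.2e}); "
            f"columns do not span a {p}-dimensional subspace"
        )
    return GrassmannPoint(_fix_column_signs(u[:, :p]))


def grassmann_exp(base: GrassmannPoint, tangent: TangentVector) -> GrassmannPoint:
    """Exponential map: follow ``tangent`` from ``base`` to a new subspace.

    With the thin SVD ``A = U diag(d) V'`` of the tangent representative, the
    image is spanned by ``o V diag(cos d) V' + U diag(sin d) V'``.  The result
    is re-orthonormalized to absorb floating-point drift.
    """
    if tangent.base is not base and not np.array_equal(tangent.base.basis, base.basis):
        raise ValueError("tangent is not anchored at the given base point")
    a = tangent.coords
    if not np.any(a):
        return base
    u, d, vt = np.linalg.svd(a, full_matrices=False)
    o = base.basis
    new = o @ (vt.T * np.cos(d)) @ vt + (u * np.sin(d)) @ vt
    # polar (symmetric) re-orthonormalization: absorbs floating-point drift
    # while preserving the representative frame, which keeps latent
    # coordinates consistently identified across conditions
    un, _, vtn = np.linalg.svd(new, full_matrices=False)
    return GrassmannPoint(un @ vtn)


def grassmann_log(base: GrassmannPoint, target: GrassmannPoint) -> TangentVector:
    """Logarithm map: the tangent at ``base`` whose exponential spans ``target``.

    Uses the standard closed form ``M = (I - o o') q (o' q)^{-1}``,
    ``M = U diag(s) V'``, ``A = U diag(arctan s) V'``.  Requires all principal
    angles between the subspaces to be below pi/2; otherwise ``o' q`` is
    singular and no unique geodesic exists.
    """
    o, q = base.basis, target.basis
    if o.shape != q.shape:
        raise ValueError(f"shape mismatch: base {o.shape} vs target {q.shape}")
    otq = o.T @ q
    sv = np.linalg.svd(otq, compute_uv=False)
    if sv[-1] < 1e-10:
        raise np.linalg.LinAlgError(
            "subspaces contain (near-)orthogonal directions (antipodal subspace); "
            "the logarithm map is undefined"
        )
    m = (q - o @ otq) @ np.linalg.inv(otq)
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    a = (u * np.arctan(s)) @ vt
    # project out any numerical vertical component before validating
    a -= o @ (o.T @ a)
    return TangentVector(a, base)


def principal_angles(p: GrassmannPoint, q: GrassmannPoint) -> np.ndarray:
    """Principal angles between two subspaces, ascending, each in [0, pi/2]."""
    if p.basis.shape != q.basis.shape:
        raise ValueError(f"shape mismatch: {p.basis.shape} vs {q.basis.shape}")
    ptq = p.basis.T @ q.basis
    cos_sv = np.linalg.svd(ptq, compute_uv=False)
    angles = np.sort(np.arccos(np.clip(cos_sv, 0.0, 1.0)))
    # the cosine formulation loses precision near zero; refine small angles
    # with the sine-based formulation (Knyazev & Argentati)
    sin_sv = np.linalg.svd(q.basis - p.basis @ ptq, compute_uv=False)
    sin_angles = np.sort(np.arcsin(np.clip(sin_sv, 0.0, 1.0)))
    return np.where(angles < 0.5, sin_angles, angles)
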