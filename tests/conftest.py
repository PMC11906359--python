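import warnings

import numpy as np
import pytest

from lemur.grassmann import GrassmannPoint, TangentVector, orthonormalize

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_point(rng, g, p) -> GrassmannPoint:
    return orthonormalize(rng.standard_normal((g, p)))


def random_tangent(rng, base: GrassmannPoint, norm: float | None = None) -> TangentVector:
    o = base.basis
    a = rng.standard_normal(o.shape)
    a -= o @ (o.T @ a)
    if norm is not None:
        a *= norm / np.linalg.norm(a)
    return TangentVector(a, base)


def symmetric_two_condition_data(rng, g=30, p=3, n=100, tangent_scale=0.6, z_scale=3.0):
    """Noiseless two-condition data generated exactly from the model.

    The base point is the geodesic midpoint (tangents +/-A with all
    principal angles below pi/4), both conditions share the same
    per-condition-centered, row-isotropic latent coordinates, so the fitted
    pooled base subspace equals the generating one and counterfactual
    predictions are exact.
    """
    from lemur.grassmann import grassmann_exp

    o = random_point(rng, g, p)
    a = rng.standard_normal((g, p))
    a -= o.basis @ (o.basis.T @ a)
    a *= tangent_scale / np.linalg.svd(a, compute_uv=False)[0]
    t = TangentVector(a, o)
    r1 = grassmann_exp(o, t).basis
    r2 = grassmann_exp(o, TangentVector(-a, o)).basis
    z = rng.standard_normal((p, n))
    for _ in range(60):
        z -= z.mean(axis=1, keepdims=True)
        u, _, vt = np.linalg.svd(z, full_matrices=False)
        z = (u @ vt) * z_scale
    z -= z.mean(axis=1, keepdims=True)
    gamma = rng.standard_normal((g, 2))
    x = np.zeros((2 * n, 2))
    x[:n, 0] = 1.0
    x[n:, 1] = 1.0
    y = np.concatenate([r1 @ z + gamma[:, :1], r2 @ z + gamma[:, 1:]], axis=1)
    return {"Y": y, "X": x, "o": o, "R1": r1, "R2": r2, "Z": z, "Gamma": gamma}
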