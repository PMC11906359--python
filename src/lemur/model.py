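"""Multi-condition PCA / latent embedding regression.

The model decomposes a genes x cells matrix ``Y`` as

    Y[:, c] = R(x_c) S(x_c) Z'[:, c] + gamma'(x_c) + noise,

where ``x_c`` is the row of the design matrix for cell ``c``, ``R(x)`` is a
condition-dependent orthonormal G x P basis obtained from a shared base
subspace ``o`` through the Grassmann exponential map of a design-linear
tangent field ``sum_k x_k B[:, :, k]``, ``gamma(x) = Gamma @ x`` is a linear
offset, and ``S(x), s0(x)`` is an optional affine alignment of the latent
coordinates (identity unless fitted from matching sets).  With an
intercept-only design the model reduces exactly to PCA.

The estimator follows scikit-learn conventions (``fit`` / ``transform`` /
``predict``, trailing-underscore fitted attributes); the module-level
functions are thin wrappers kept for a functional style.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.extmath import randomized_svd

from .datatypes import DesignMatrix, as_design_array
from .grassmann import (
    GrassmannPoint,
    TangentVector,
    _fix_column_signs,
    grassmann_exp,
    grassmann_log,
    orthonormalize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LemurRegression",
    "fit_offset",
    "fit_multicondition_pca",
    "embed_cells",
    "variance_explained",
]

# below this matrix size a full (deterministic, exact) SVD is cheap enough
_FULL_SVD_MAX = 600


def fit_offset(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares offset coefficients ``Gamma`` (G x K) of ``Y ~ Gamma X'``.

    With an intercept-only design this is the vector of row-wise means.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    k = X.shape[1]
    sol, _, rank, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    if rank < k:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < K={k})"
        )
    return sol.T


def _svd_basis(m: np.ndarray, p: int, seed: int) -> np.ndarray:
    """Top-``p`` left singular subspace of ``m`` with deterministic column signs."""
    if min(m.shape) <= _FULL_SVD_MAX or p > 0.2 * min(m.shape):
        u, _, _ = np.linalg.svd(m, full_matrices=False)
        u = u[:, :p]
    else:
        u, _, _ = randomized_svd(
            m, n_components=p, n_oversamples=20, n_iter=7, random_state=seed
        )
    return _fix_column_signs(u)


def _distinct_rows(X: np.ndarray):
    """Unique design rows (lexicographic order) and the per-cell inverse index."""
    rows, inverse = np.unique(np.round(X, 12), axis=0, return_inverse=True)
    return rows, inverse


class LemurRegression(BaseEstimator, TransformerMixin):
    """Multi-condition PCA with condition-dependent subspaces.

    Parameters
    ----------
    n_embedding
        Latent dimension P (default 30).
    design
        Optional default design specification stored for reuse; the design
        is normally passed to :meth:`fit` directly.
    test_fraction
        Fraction of cells excluded from all parameter estimation and
        reserved for downstream held-out testing (default 0.5).  The fitted
        embedding still covers every cell.
    pseudo_count
        Pseudo-count of the shifted-log transform when the estimator is
        handed raw counts via :func:`lemur.preprocessing.shifted_log_transform`
        upstream (stored for provenance only).
    random_state
        Seed for the train/test split and randomized SVDs.

    Attributes
    ----------
    base_point_ : GrassmannPoint
        Shared base subspace ``o`` (G x P).
    tangents_ : ndarray of shape (G, P, K)
        Tangent tensor ``B``; slice k is a horizontal tangent at ``o``.
    gamma_ : ndarray of shape (G, K)
        Linear offset coefficients.
    W_ : ndarray of shape (P, P, K)
        Alignment tensor; ``S(x) = I + sum_k x_k W_[:, :, k]``.
    W0_ : ndarray of shape (P, K)
        Alignment offset; ``s0(x) = W0_ @ x``.
    embedding_ : ndarray of shape (P, C)
        Aligned latent coordinates ``Z'`` of all cells (training and test).
    test_mask_ : ndarray of shape (C,), bool
        True for held-out cells.
    """

    def __init__(
        self,
        n_embedding: int = 30,
        design=None,
        test_fraction: float = 0.5,
        pseudo_count: float = 1.0,
        random_state: int = 0,
    ):
        self.n_embedding = n_embedding
        self.design = design
        self.test_fraction = test_fraction
        self.pseudo_count = pseudo_count
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y=None, design=None):
        """Fit the model on a cells x genes matrix.

        ``X`` follows the scikit-learn samples x features orientation
        (cells x genes); internally the genes x cells convention is used.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (cells x genes)")
        n_cells, n_genes = X.shape
        if design is None:
            design = self.design
        design_arr = as_design_array(design, n_cells)
        if isinstance(design, DesignMatrix):
            self.design_matrix_ = design
        else:
            self.design_matrix_ = DesignMatrix(design_arr)
        p = int(self.n_embedding)
        if not 0 < p < min(n_genes, n_cells):
            raise ValueError(
                f"n_embedding={p} must satisfy 0 < P < min(G={n_genes}, C={n_cells})"
            )
        if not 0.0 <= self.test_fraction <= 0.95:
            raise ValueError("test_fraction must be in [0, 0.95]")

        Y = np.ascontiguousarray(X.T)
        rng = np.random.default_rng(self.random_state)
        n_test = int(round(self.test_fraction * n_cells))
        test_mask = np.zeros(n_cells, dtype=bool)
        if n_test:
            test_mask[rng.choice(n_cells, size=n_test, replace=False)] = True
        self.test_mask_ = test_mask
        train = ~test_mask

        Xtr = design_arr[train]
        Ytr = Y[:, train]
        self.gamma_ = fit_offset(Ytr, Xtr)
        resid = Ytr - self.gamma_ @ Xtr.T
        seed = int(self.random_state)
        o_basis = _svd_basis(resid, p, seed)
        self.base_point_ = GrassmannPoint(o_basis)

        rows, inverse = _distinct_rows(Xtr)
        n_rows = rows.shape[0]
        k = design_arr.shape[1]
        tangents = np.zeros((n_rows, n_genes, p))
        weights = np.zeros(n_rows)
        for j in range(n_rows):
            cells_j = np.flatnonzero(inverse == j)
            weights[j] = cells_j.size
            tangents[j] = self._condition_tangent(resid[:, cells_j], p, seed + j)

        # weighted least squares of tangents on distinct design rows;
        # exact for one-hot designs, min-norm otherwise
        sw = np.sqrt(weights)
        a = rows * sw[:, None]
        rhs = tangents.reshape(n_rows, -1) * sw[:, None]
        sol, _, _, _ = np.linalg.lstsq(a, rhs, rcond=None)
        self.tangents_ = np.moveaxis(sol.reshape(k, n_genes, p), 0, -1)

        self.W_ = np.zeros((p, p, k))
        self.W0_ = np.zeros((p, k))
        self._basis_cache = {}
        self.n_features_in_ = n_genes
        self._design_all = design_arr
        self._z_raw = self._project(Y, design_arr)
        self.embedding_ = self._z_raw.copy()
        self.alignment_groups_ = None
        return self

    def _condition_tangent(self, resid_j: np.ndarray, p: int, seed: int) -> np.ndarray:
        """Tangent coordinates of one condition's P-dim subspace at the base point.

        Conditions with fewer than 2P cells are unstable for a P-dimensional
        PCA; their tangent is shrunk toward zero (toward the shared base
        subspace) in proportion to the cell count.  Conditions with fewer
        than P cells additionally have their basis completed with base-point
        directions.
        """
        o = self.base_point_.basis
        n_j = resid_j.shape[1]
        if n_j >= p:
            basis = _svd_basis(resid_j, p, seed)
        else:
            u, s, _ = np.linalg.svd(resid_j, full_matrices=False)
            r = int(np.sum(s > max(resid_j.shape) * np.finfo(float).eps * max(s[0], 1e-300)))
            partial = u[:, :r]
            fill = o - partial @ (partial.T @ o)
            u2, s2, _ = np.linalg.svd(fill, full_matrices=False)
            basis = _fix_column_signs(np.hstack([partial, u2[:, : p - r]]))
        try:
            tangent = grassmann_log(self.base_point_, orthonormalize(basis))
        except np.linalg.LinAlgError:
            warnings.warn(
                "condition subspace nearly orthogonal to the base point; "
                "shrinking its tangent to zero"
            )
            return np.zeros_like(o)
        shrink = 1.0
        if n_j < 2 * p:
            shrink = n_j / (2.0 * p)
            warnings.warn(
                f"condition with only {n_j} cells (< 2P = {2 * p}): tangent "
                f"shrunk toward the base subspace by factor {shrink:.3f}"
            )
        return shrink * tangent.coords

    # --------------------------------------------------------- linear pieces

    def condition_basis(self, design_row: np.ndarray) -> np.ndarray:
        """Orthonormal basis ``R(x)`` for one design row (cached)."""
        x = np.asarray(design_row, dtype=float).ravel()
        key = np.round(x, 12).tobytes()
        cached = self._basis_cache.get(key)
        if cached is not None:
            return cached
        coords = np.einsum("gpk,k->gp", self.tangents_, x)
        point = grassmann_exp(
            self.base_point_, TangentVector(coords, self.base_point_)
        )
        self._basis_cache[key] = point.basis
        return point.basis

    def offset(self, design_row: np.ndarray) -> np.ndarray:
        """Linear offset ``gamma(x) = Gamma @ x``."""
        return self.gamma_ @ np.asarray(design_row, dtype=float).ravel()

    def alignment_matrix(self, design_row: np.ndarray) -> np.ndarray:
        """``S(x) = I + sum_k x_k W[:, :, k]``."""
        x = np.asarray(design_row, dtype=float).ravel()
        p = self.n_embedding
        return np.eye(p) + np.einsum("pqk,k->pq", self.W_, x)

    def alignment_offset(self, design_row: np.ndarray) -> np.ndarray:
        """``s0(x) = W0 @ x``."""
        return self.W0_ @ np.asarray(design_row, dtype=float).ravel()

    # ------------------------------------------------------------ embedding

    def _project(self, Y: np.ndarray, design: np.ndarray) -> np.ndarray:
        """Raw projections ``R(x)' (Y - gamma(x))`` for genes x cells input."""
        rows, inverse = _distinct_rows(design)
        z = np.empty((self.n_embedding, Y.shape[1]))
        for j, x in enumerate(rows):
            idx = np.flatnonzero(inverse == j)
            r = self.condition_basis(x)
            z[:, idx] = r.T @ (Y[:, idx] - self.offset(x)[:, None])
        return z

    def _align_coords(self, z_raw: np.ndarray, design: np.ndarray) -> np.ndarray:
        """Aligned coordinates ``Z' = S^{-1}(x) (z_raw - s0(x))``."""
        if not np.any(self.W_) and not np.any(self.W0_):
            return z_raw.copy()
        rows, inverse = _distinct_rows(design)
        z = np.empty_like(z_raw)
        for j, x in enumerate(rows):
            idx = np.flatnonzero(inverse == j)
            s = self.alignment_matrix(x)
            if np.linalg.cond(s) > 1e10:
                raise np.linalg.LinAlgError(
                    f"alignment S(x) numerically singular for design row {x}"
                )
            z[:, idx] = np.linalg.solve(
                s, z_raw[:, idx] - self.alignment_offset(x)[:, None]
            )
        return z

    def transform(self, X=None, design=None) -> np.ndarray:
        """Aligned latent coordinates, cells x P.

        With ``X=None`` the stored training-time embedding of all cells is
        returned; otherwise new cells are embedded with their design rows.
        """
        self._check_fitted()
        if X is None:
            return self.embedding_.T
        X = np.asarray(X, dtype=float)
        design_arr = as_design_array(design, X.shape[0])
        z_raw = self._project(np.ascontiguousarray(X.T), design_arr)
        return self._align_coords(z_raw, design_arr).T

    def refresh_embedding(self) -> None:
        """Recompute the stored embedding after alignment parameters change."""
        self.embedding_ = self._align_coords(self._z_raw, self._design_all)

    # ------------------------------------------------------------ prediction

    def predict_at(self, z_aligned: np.ndarray, design_row: np.ndarray) -> np.ndarray:
        """Expression (genes x n) for aligned coordinates at one design row.

        ``Yhat = R(x) S(x) Z' + gamma(x) + R(x) s0(x)`` — defined for any
        coordinates, including synthetic interpolated cells.
        """
        self._check_fitted()
        z_aligned = np.atleast_2d(np.asarray(z_aligned, dtype=float))
        if z_aligned.shape[0] != self.n_embedding:
            z_aligned = z_aligned.T
        x = np.asarray(design_row, dtype=float).ravel()
        r = self.condition_basis(x)
        s = self.alignment_matrix(x)
        return r @ (s @ z_aligned + self.alignment_offset(x)[:, None]) + self.offset(x)[:, None]

    def predict(self, X=None, design=None, new_design=None) -> np.ndarray:
        """Counterfactual expression of cells at ``new_design`` (cells x genes).

        Cells are embedded under their own observed design rows and decoded
        at ``new_design`` (a single K-vector applied to every cell, or one
        row per cell).  ``new_design=None`` reconstructs each cell in its
        own condition (the model's denoised observation).
        """
        self._check_fitted()
        if X is None:
            z = self.embedding_
            design_arr = self._design_all
        else:
            z = self.transform(X, design=design).T
            design_arr = as_design_array(design, z.shape[1])
        n = z.shape[1]
        if new_design is None:
            target = design_arr
        else:
            target = np.asarray(new_design, dtype=float)
            if target.ndim == 1:
                target = np.broadcast_to(target, (n, target.size))
        out = np.empty((n, self.n_features_in_))
        rows, inverse = _distinct_rows(np.asarray(target, dtype=float))
        for j, x in enumerate(rows):
            idx = np.flatnonzero(inverse == j)
            out[idx] = self.predict_at(z[:, idx], x).T
        return out

    # ------------------------------------------------------------- metrics

    def variance_explained(self, X=None, design=None) -> float:
        """``1 - ||Y - Yhat||_F^2 / ||Y - rowmeans(Y)||_F^2``."""
        self._check_fitted()
        if X is None:
            raise ValueError("pass the data matrix (cells x genes)")
        X = np.asarray(X, dtype=float)
        yhat = self.predict(X, design=design)
        resid = X - yhat
        centered = X - X.mean(axis=0, keepdims=True)
        denom = float(np.sum(centered**2))
        if denom == 0:
            raise ValueError("variance of Y is zero; variance explained undefined")
        return 1.0 - float(np.sum(resid**2)) / denom

    def _check_fitted(self) -> None:
        if not hasattr(self, "base_point_"):
            raise RuntimeError("model is not fitted; call fit() first")


# ------------------------------------------------------------------ wrappers


def fit_multicondition_pca(
    Y: np.ndarray,
    X,
    n_embedding: int,
    random_state: int = 0,
    test_fraction: float = 0.0,
) -> LemurRegression:
    """Fit the multi-condition PCA on a genes x cells matrix ``Y``."""
    Y = np.asarray(Y, dtype=float)
    est = LemurRegression(
        n_embedding=n_embedding,
        test_fraction=test_fraction,
        random_state=random_state,
    )
    return est.fit(Y.T, design=X)


def embed_cells(fit: LemurRegression, Y: np.ndarray, X) -> np.ndarray:
    """Latent coordinates (P x n) of genes x cells data under design ``X``."""
    return fit.transform(np.asarray(Y, dtype=float).T, design=X).T


def variance_explained(fit: LemurRegression, Y: np.ndarray, X) -> float:
    return fit.variance_explained(np.asarray(Y, dtype=float).T, design=X)
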