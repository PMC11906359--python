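"""Counterfactual expression prediction and the differential-expression delta.

For any cell the fitted model predicts how its expression profile would look
in any condition that can be encoded as a design row.  The per-gene,
per-cell differential-expression statistic of a contrast (A, B) is the
difference of two such predictions, ``Delta = Yhat_B - Yhat_A``, computed on
the variance-stabilized scale and reported as a predicted log fold change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import LemurRegression

__all__ = [
    "Contrast",
    "DeltaMatrix",
    "predict_expression",
    "compute_delta",
    "interpolate_latent",
]


@dataclass
class Contrast:
    """A pair of design rows whose predicted expression difference is tested."""

    row_a: np.ndarray
    row_b: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.row_a = np.asarray(self.row_a, dtype=float).ravel()
        self.row_b = np.asarray(self.row_b, dtype=float).ravel()
        if self.row_a.shape != self.row_b.shape:
            raise ValueError("contrast rows must have equal length")
        if not self.label:
            self.label = f"{self.row_b.tolist()} vs {self.row_a.tolist()}"

    def check_in_span(self, design: np.ndarray) -> None:
        """Warn (not error) if a contrast row extrapolates beyond observed rows."""
        design = np.asarray(design, dtype=float)
        _, s, vt = np.linalg.svd(design, full_matrices=False)
        basis = vt[s > 1e-10 * max(s[0], 1e-300)]  # row-space basis
        for name, row in (("row_a", self.row_a), ("row_b", self.row_b)):
            resid = row - basis.T @ (basis @ row)
            if np.linalg.norm(resid) > 1e-8 * max(1.0, np.linalg.norm(row)):
                warnings.warn(
                    f"contrast {name} {row.tolist()} lies outside the span of "
                    "observed design rows; predictions extrapolate"
                )


@dataclass
class DeltaMatrix:
    """Genes x cells matrix of predicted expression differences for a contrast."""

    values: np.ndarray
    contrast: Contrast

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("delta values must be finite")


def predict_expression(
    fit: LemurRegression, z_aligned: np.ndarray, design_row: np.ndarray
) -> np.ndarray:
    """Expression (genes x n) decoded from aligned coordinates at one design row."""
    return fit.predict_at(z_aligned, design_row)


def compute_delta(fit: LemurRegression, contrast: Contrast) -> DeltaMatrix:
    """``Delta[:, c] = Yhat(z'_c, row_b) - Yhat(z'_c, row_a)`` for every cell."""
    fit._check_fitted()
    contrast.check_in_span(fit._design_all)
    z = fit.embedding_
    if np.array_equal(contrast.row_a, contrast.row_b):
        return DeltaMatrix(np.zeros((fit.n_features_in_, z.shape[1])), contrast)
    pred_b = fit.predict_at(z, contrast.row_b)
    pred_a = fit.predict_at(z, contrast.row_a)
    return DeltaMatrix(pred_b - pred_a, contrast)


def interpolate_latent(
    z_start: np.ndarray, z_end: np.ndarray, n_points: int
) -> np.ndarray:
    """Evenly spaced convex combinations (P x n_points), endpoints included.

    Synthetic cells on the segment can be decoded at any design row, giving
    expression predictions along a latent-space path (for example between
    two anchor cells of a developmental trajectory).
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    z_start = np.asarray(z_start, dtype=float).ravel()
    z_end = np.asarray(z_end, dtype=float).ravel()
    if z_start.shape != z_end.shape:
        raise ValueError("endpoints must have equal dimension")
    t = np.linspace(0.0, 1.0, n_points)
    return z_start[:, None] * (1 - t)[None, :] + z_end[:, None] * t[None, :]
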