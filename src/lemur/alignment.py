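"""Affine alignment of latent coordinates across conditions.

Matching sets (landmarks, or any external clustering whose groups span
several conditions) declare which cells from different conditions are
intended to be "the same".  The alignment finds, per condition, an affine
transformation ``S(x), s0(x)`` of the latent coordinates such that the
aligned coordinates ``Z' = S^{-1}(x) (Z - s0(x))`` of each matching set
collapse onto the set's mean latent position, with a ridge penalty pulling
the transformation toward the identity.

Because the objective is nonlinear in ``S`` (it enters through its inverse),
the fit targets the inverse map directly: for each distinct design row a
ridge-regularized affine regression ``z -> H1 z + h0`` of set means onto
member coordinates is solved in closed form, and ``S(x) = H1^{-1}``,
``s0(x) = -H1^{-1} h0`` are converted to the design-linear parameterization
``S(x) = I + sum_k x_k W[:, :, k]``, ``s0(x) = W0 @ x`` by a weighted linear
solve across the distinct design rows.  For saturated (one-hot) designs this
surrogate attains the optimum of the original problem as the ridge weight
goes to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import LemurRegression, _distinct_rows

logger = logging.getLogger(__name__)

__all__ = ["MatchingSets", "fit_alignment", "apply_alignment", "alignment_objective"]


@dataclass
class MatchingSets:
    """Disjoint sets of cell indices, each spanning at least two conditions.

    Sets confined to a single condition carry no alignment information and
    are dropped (with a logged count) during validation against a design.
    """

    sets: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sets = [np.asarray(s, dtype=int) for s in self.sets]
        seen: set[int] = set()
        for s in self.sets:
            overlap = seen.intersection(s.tolist())
            if overlap:
                raise ValueError(f"matching sets are not disjoint (cells {sorted(overlap)[:5]})")
            seen.update(s.tolist())

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    def validate_against(self, design: np.ndarray) -> "MatchingSets":
        """Drop sets spanning fewer than two distinct design rows."""
        _, inverse = _distinct_rows(np.asarray(design, dtype=float))
        kept, dropped = [], 0
        for s in self.sets:
            if np.max(s) >= len(inverse) or np.min(s) < 0:
                raise IndexError("matching set index out of range")
            if len(np.unique(inverse[s])) >= 2:
                kept.append(s)
            else:
                dropped += 1
        if dropped:
            logger.warning("dropped %d matching set(s) confined to a single condition", dropped)
        return MatchingSets(kept)

    @classmethod
    def from_labels(cls, labels: np.ndarray, design: np.ndarray | None = None) -> "MatchingSets":
        """Build sets from a per-cell label vector (NaN/None labels ignored)."""
        labels = np.asarray(labels)
        sets = []
        for lab in pd_unique_ordered(labels):
            if lab is None or (isinstance(lab, float) and np.isnan(lab)):
                continue
            sets.append(np.flatnonzero(labels == lab))
        out = cls(sets)
        if design is not None:
            out = out.validate_against(design)
        return out


def pd_unique_ordered(values: np.ndarray):
    seen = []
    for v in values:
        if v not in seen:
            seen.append(v)
    return seen


def default_lambda(groups: MatchingSets) -> float:
    """Scale-free default ridge weight: 0.01 x number of matched cells."""
    n = sum(len(s) for s in groups.sets)
    return max(0.01 * n, 1e-12)


def fit_alignment(
    fit: LemurRegression,
    groups: MatchingSets,
    lam: float | None = None,
) -> LemurRegression:
    """Fill ``fit.W_`` / ``fit.W0_`` from matching sets; returns ``fit``.

    With zero sets the alignment is the identity (W = 0, W0 = 0).
    """
    fit._check_fitted()
    design = fit._design_all
    groups = groups.validate_against(design)
    p = fit.n_embedding
    k = design.shape[1]
    if groups.n_sets == 0:
        fit.W_ = np.zeros((p, p, k))
        fit.W0_ = np.zeros((p, k))
        fit.refresh_embedding()
        return fit
    if lam is None:
        lam = default_lambda(groups)
    if lam <= 0:
        raise ValueError("lambda must be positive")

    z = fit._z_raw
    member = np.concatenate(groups.sets)
    set_id = np.concatenate(
        [np.full(len(s), e) for e, s in enumerate(groups.sets)]
    )
    means = np.stack([z[:, s].mean(axis=1) for s in groups.sets])  # E x P

    rows, inverse = _distinct_rows(design)
    n_rows = rows.shape[0]
    h1 = np.tile(np.eye(p), (n_rows, 1, 1))
    h0 = np.zeros((n_rows, p))
    covered = np.zeros(n_rows, dtype=bool)
    cond_of_member = inverse[member]
    for j in range(n_rows):
        sel = cond_of_member == j
        if not np.any(sel):
            continue
        covered[j] = True
        zc = z[:, member[sel]]                       # P x n_j
        target = means[set_id[sel]].T                # P x n_j
        # ridge affine regression of (target - z) on [z; 1], pulled to zero
        n_j = zc.shape[1]
        aug = np.vstack([zc, np.ones((1, n_j))])     # (P+1) x n_j
        gram = aug @ aug.T + lam * np.eye(p + 1)
        coef = np.linalg.solve(gram, aug @ (target - zc).T).T   # P x (P+1)
        h1[j] = np.eye(p) + coef[:, :p]
        h0[j] = coef[:, p]
        if np.linalg.cond(h1[j]) > 1e10:
            raise np.linalg.LinAlgError(
                f"fitted alignment map singular for condition row {rows[j]}"
            )

    # gauge fixing: a global affine transformation applied to every condition
    # does not change cross-condition matching but can collapse the latent
    # space onto the set means; remove it by normalizing with the
    # member-weighted mean map, so the average alignment is the identity
    weights = np.array([np.sum(cond_of_member == j) for j in range(n_rows)], dtype=float)
    wsum = weights[covered].sum()
    h1_bar = np.einsum("j,jpq->pq", weights[covered], h1[covered]) / wsum
    h0_bar = np.einsum("j,jp->p", weights[covered], h0[covered]) / wsum
    h1_bar_inv = np.linalg.inv(h1_bar)
    for j in np.flatnonzero(covered):
        h1[j] = h1_bar_inv @ h1[j]
        h0[j] = h1_bar_inv @ (h0[j] - h0_bar)
    use = covered
    s_targets = np.stack([np.linalg.inv(h1[j]) - np.eye(p) for j in range(n_rows)])
    s0_targets = np.stack([-np.linalg.inv(h1[j]) @ h0[j] for j in range(n_rows)])
    sw = np.sqrt(weights[use])
    a = rows[use] * sw[:, None]
    rhs = np.concatenate(
        [s_targets[use].reshape(use.sum(), -1), s0_targets[use]], axis=1
    ) * sw[:, None]
    sol, _, _, _ = np.linalg.lstsq(a, rhs, rcond=None)
    fit.W_ = np.moveaxis(sol[:, : p * p].reshape(k, p, p), 0, -1)
    fit.W0_ = sol[:, p * p :].T
    fit.alignment_groups_ = groups
    fit.refresh_embedding()
    return fit


def apply_alignment(fit: LemurRegression, Z: np.ndarray, X) -> np.ndarray:
    """Aligned coordinates ``Z' = S^{-1}(x)(Z - s0(x))`` for P x n input."""
    Z = np.asarray(Z, dtype=float)
    design = np.atleast_2d(np.asarray(X, dtype=float))
    return fit._align_coords(Z, design)


def alignment_objective(
    fit: LemurRegression,
    groups: MatchingSets,
    lam: float,
    W: np.ndarray | None = None,
    W0: np.ndarray | None = None,
) -> float:
    """Value of the alignment objective at given (or fitted) parameters."""
    W = fit.W_ if W is None else W
    W0 = fit.W0_ if W0 is None else W0
    saved = fit.W_, fit.W0_
    try:
        fit.W_, fit.W0_ = W, W0
        z = fit._align_coords(fit._z_raw, fit._design_all)
        total = 0.0
        zr = fit._z_raw
        for s in groups.sets:
            m = zr[:, s].mean(axis=1)
            total += float(np.sum((z[:, s] - m[:, None]) ** 2))
        total += lam * (float(np.sum(W0**2)) + float(np.sum(W**2)))
    finally:
        fit.W_, fit.W0_ = saved
    return total
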