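"""Cluster-free differential-expression neighborhoods and pseudobulk tests.

For each gene, a *neighborhood* — a half-space of the aligned latent space
with a consistently signed delta — is selected on training cells by scanning
random one-dimensional projections, and its differential expression is then
tested on held-out cells only, by aggregating raw counts per sample
(pseudobulking) and applying a negative-binomial likelihood-ratio test (or
an ordinary linear model on averaged variance-stabilized values).  Selecting
on one half of the cells and testing on the other makes the resulting
p-values free of selection bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "Neighborhood",
    "DEResult",
    "sample_directions",
    "select_neighborhoods",
    "neighborhood_membership",
    "pseudobulk_aggregate",
    "nb_glm_lrt",
    "lm_test",
    "bh_adjust",
    "run_de_pipeline",
]


@dataclass
class Neighborhood:
    """A half-space neighborhood: membership is a threshold on one projection."""

    gene_id: str
    direction: np.ndarray  # unit vector in latent space
    threshold: float
    side: int  # +1: projection >= threshold, -1: projection <= threshold
    score: float  # selection z-score on training cells
    cell_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def contains(self, z: np.ndarray) -> np.ndarray:
        """Boolean membership for P x n latent coordinates."""
        t = self.direction @ np.asarray(z, dtype=float)
        return t >= self.threshold if self.side > 0 else t <= self.threshold


@dataclass
class DEResult:
    """Per-gene statistics table plus the selected neighborhoods and provenance."""

    table: pd.DataFrame
    neighborhoods: dict
    config: object = None
    contrast: object = None
    fit: object = None


# ----------------------------------------------------------------- selection


def sample_directions(p: int, n_dir: int, seed: int) -> np.ndarray:
    """``n_dir`` i.i.d. uniform unit vectors in R^p (rows), seeded."""
    if n_dir < 1:
        raise ValueError("n_dir must be >= 1")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n_dir, p))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _scan_one_ordering(csum_abs: np.ndarray, sd: np.ndarray, min_cells: int):
    """Best prefix size and score per gene for one ordering of the cells.

    ``csum_abs`` is |cumulative delta| per gene along the ordering.
    """
    n_cells = csum_abs.shape[1]
    ns = np.arange(min_cells, n_cells + 1)
    scores = csum_abs[:, min_cells - 1 :] / (sd[:, None] * np.sqrt(ns)[None, :])
    k = np.argmax(scores, axis=1)
    return k + min_cells, scores[np.arange(scores.shape[0]), k]


def select_neighborhoods(
    delta_train: np.ndarray,
    z_train: np.ndarray,
    directions: np.ndarray | None = None,
    min_cells: int = 10,
    selection_procedure: str = "zscore",
    gene_ids=None,
) -> list:
    """Best half-space neighborhood per gene from training cells.

    For every direction ``v`` and both ends of the ordering by
    ``t_c = v . z'_c``, each prefix with at least ``min_cells`` members is
    scored ``z(N) = |sum_{c in N} delta_c| / (sd(delta) sqrt(|N|))``; the
    best-scoring (direction, end, threshold) triple defines the
    neighborhood.  Genes with zero delta variance get ``None`` (no signal).

    With ``selection_procedure='contrast'`` a single gene-specific direction
    proportional to ``sum_c delta_c z'_c`` is scanned instead of the shared
    random directions.
    """
    delta_train = np.asarray(delta_train, dtype=float)
    z_train = np.asarray(z_train, dtype=float)
    g, n_train = delta_train.shape
    p = z_train.shape[0]
    if n_train < min_cells:
        raise ValueError(f"need at least min_cells={min_cells} training cells")
    if gene_ids is None:
        gene_ids = [f"gene_{i}" for i in range(g)]
    sd = delta_train.std(axis=1, ddof=1)
    valid = sd > 0
    sd_safe = np.where(valid, sd, 1.0)

    best_score = np.full(g, -np.inf)
    best_dir = np.zeros((g, p))
    best_thresh = np.zeros(g)
    best_side = np.zeros(g, dtype=int)

    def update(t, v_rows):
        """Scan both ends of ordering(s) by t; v_rows is (g, p) or (1, p)."""
        for side in (+1, -1):
            order = np.argsort(-side * t, axis=-1, kind="stable")
            if t.ndim == 1:
                d_sorted = delta_train[:, order]
                t_sorted = t[order]
            else:
                d_sorted = np.take_along_axis(delta_train, order, axis=1)
                t_sorted = np.take_along_axis(t, order, axis=1)
            csum_abs = np.abs(np.cumsum(d_sorted, axis=1))
            size, score = _scan_one_ordering(csum_abs, sd_safe, min_cells)
            score = np.where(valid, score, -np.inf)
            upd = score > best_score
            if not np.any(upd):
                continue
            best_score[upd] = score[upd]
            best_side[upd] = side
            rows = v_rows if v_rows.shape[0] > 1 else np.broadcast_to(v_rows, (g, p))
            best_dir[upd] = rows[upd]
            if t.ndim == 1:
                best_thresh[upd] = t_sorted[size[upd] - 1]
            else:
                best_thresh[upd] = t_sorted[upd, size[upd] - 1]

    if selection_procedure == "contrast":
        v = delta_train @ z_train.T  # (g, p)
        norms = np.linalg.norm(v, axis=1, keepdims=True)
        v = np.divide(v, norms, out=np.zeros_like(v), where=norms > 0)
        update(np.einsum("gp,pc->gc", v, z_train), v)
    else:
        if directions is None:
            raise ValueError("zscore selection needs sampled directions")
        for v in np.atleast_2d(directions):
            update(v @ z_train, v[None, :])

    out = []
    for i in range(g):
        if not valid[i] or not np.isfinite(best_score[i]):
            logger.debug("gene %s: zero delta variance, no neighborhood", gene_ids[i])
            out.append(None)
        else:
            out.append(
                Neighborhood(
                    gene_id=str(gene_ids[i]),
                    direction=best_dir[i].copy(),
                    threshold=float(best_thresh[i]),
                    side=int(best_side[i]),
                    score=float(best_score[i]),
                )
            )
    return out


def neighborhood_membership(nbh: Neighborhood, z: np.ndarray) -> np.ndarray:
    """Boolean membership of P x n coordinates in a neighborhood."""
    return nbh.contains(z)


# ---------------------------------------------------------------- pseudobulk


def pseudobulk_aggregate(
    values: np.ndarray,
    cells: np.ndarray,
    sample_ids: np.ndarray,
    mode: str = "sum",
    sample_levels=None,
):
    """Aggregate member cells per sample: sums (counts) or means (values).

    Returns the genes x samples aggregate and the per-sample member-cell
    counts; samples with zero member cells are kept with count 0.
    """
    values = np.asarray(values)
    cells = np.asarray(cells)
    if cells.dtype == bool:
        cells = np.flatnonzero(cells)
    if cells.size == 0:
        raise ValueError("empty cell set")
    sample_ids = np.asarray(sample_ids)
    if sample_levels is None:
        sample_levels = np.unique(sample_ids)
    member_samples = sample_ids[cells]
    agg = np.zeros((values.shape[0], len(sample_levels)))
    n_cells = np.zeros(len(sample_levels), dtype=int)
    for s, level in enumerate(sample_levels):
        idx = cells[member_samples == level]
        n_cells[s] = idx.size
        if idx.size:
            agg[:, s] = values[:, idx].sum(axis=1)
            if mode == "mean":
                agg[:, s] /= idx.size
    return agg, n_cells


# ------------------------------------------------------- negative binomial


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB2 log-likelihood; ``alpha`` per gene (overdispersion)."""
    r = 1.0 / np.maximum(alpha, 1e-12)[:, None]
    mu = np.maximum(mu, 1e-12)
    return np.sum(
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu)),
        axis=1,
    )


def _irls(y, x, offsets, alpha, n_iter=60, tol=1e-12):
    """Batched IRLS for a log-link count GLM; ``alpha=0`` rows are Poisson.

    y: (g, s); x: (s, k); offsets: (g, s); alpha: (g,).  Returns beta (g, k).
    """
    g, s = y.shape
    k = x.shape[1]
    mean_rate = np.maximum(np.mean(y * np.exp(-offsets), axis=1), 1e-8)
    eta = np.log(mean_rate)[:, None] + offsets
    beta = np.linalg.lstsq(x, (eta - offsets).T, rcond=None)[0].T
    eye = np.eye(k) * 1e-10
    for _ in range(n_iter):
        eta = np.clip(beta @ x.T + offsets, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = eta - offsets + (y - mu) / mu
        xtwx = np.einsum("sk,gs,sl->gkl", x, w, x) + eye
        rhs = np.einsum("sk,gs->gk", x, w * z)
        new_beta = np.linalg.solve(xtwx, rhs[..., None])[..., 0]
        if np.max(np.abs(new_beta - beta)) < tol:
            beta = new_beta
            break
        beta = new_beta
    return beta


def _apl(y, mu, alpha, x):
    """Cox-Reid adjusted profile log-likelihood of the dispersion.

    The adjustment ``-0.5 log det(X' W X)`` counteracts the downward bias of
    plain ML dispersion estimates with few samples, which would otherwise
    make the likelihood-ratio test anticonservative.
    """
    ll = _nb_loglik(y, mu, alpha)
    if x is None:
        return ll
    w = mu / (1.0 + alpha[:, None] * mu)
    xtwx = np.einsum("sk,gs,sl->gkl", x, w, x) + 1e-10 * np.eye(x.shape[1])
    _, logdet = np.linalg.slogdet(xtwx)
    return ll - 0.5 * logdet


def _eb_dispersion(y, mu, x, prior_n=10.0, lo=1e-8, hi=1e3, n_grid=120):
    """Empirical-Bayes dispersion: gene-wise APL shrunk toward the common curve.

    Maximizes ``APL_g(alpha) + prior_n * mean_g APL_g(alpha)`` over a log
    grid — the moderation used by pseudobulk GLM tools, which stabilizes
    gene-wise dispersions when only a handful of samples are available and
    keeps the chi-square LRT calibrated.  ``prior_n`` is the weight of the
    common curve in gene-equivalents.
    """
    grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    apl = np.empty((y.shape[0], n_grid))
    for i, a in enumerate(grid):
        apl[:, i] = _apl(y, mu, np.full(y.shape[0], a), x)
    obj = apl + prior_n * apl.mean(axis=0, keepdims=True)
    return np.maximum(grid[np.argmax(obj, axis=1)], lo)


def _ml_dispersion(y, mu, x=None, lo=1e-8, hi=1e4, n_iter=60):
    """Per-gene dispersion maximizing the (Cox-Reid adjusted) likelihood.

    Golden-section search on log alpha; ``x=None`` gives the unadjusted ML
    estimate.
    """
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.full(y.shape[0], np.log(lo))
    b = np.full(y.shape[0], np.log(hi))
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _apl(y, mu, np.exp(c), x)
    fd = _apl(y, mu, np.exp(d), x)
    for _ in range(n_iter):
        swap = fc > fd
        b = np.where(swap, d, b)
        a = np.where(~swap, c, a)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc = _apl(y, mu, np.exp(c), x)
        fd = _apl(y, mu, np.exp(d), x)
    alpha = np.exp((a + b) / 2.0)
    return np.maximum(alpha, lo)


def nb_glm_lrt(
    pseudo_counts: np.ndarray,
    sample_design: np.ndarray,
    contrast_index: int,
    offsets: np.ndarray | None = None,
    prior_n: float = 10.0,
    cox_reid: bool = True,
    reference: str = "chi2",
):
    """Per-gene negative-binomial likelihood-ratio test on pseudobulk counts.

    Fits a log-link NB GLM with per-gene maximum-likelihood dispersion
    (floored at 1e-8; Cox-Reid adjusted and empirical-Bayes moderated
    toward the common dispersion by default, see ``_eb_dispersion``) under
    the full design and the design with the contrast column dropped; the
    two-sided p-value is the chi-square(1) upper tail of twice the
    log-likelihood difference (``reference='f'`` refers it to F(1, S-K)
    instead).  ``prior_n=0, cox_reid=False`` gives the unmoderated plain-ML
    variant.  Returns a DataFrame with ``lfc`` (log2, from the contrast
    coefficient), ``p_value`` and a ``flagged`` column marking genes that
    fell back to a (near-)Poisson fit.
    """
    y = np.asarray(pseudo_counts, dtype=float)
    x = np.asarray(sample_design, dtype=float)
    g, s = y.shape
    k = x.shape[1]
    if s < k + 1:
        raise ValueError(f"need at least K+1={k + 1} samples, got {s}")
    if offsets is None:
        offsets = np.zeros((g, s))
    else:
        offsets = np.broadcast_to(np.asarray(offsets, dtype=float), (g, s)).copy()
    if not np.all(np.isfinite(offsets)):
        raise ValueError("offsets must be finite")

    # profile likelihood: alternate coefficient fits and dispersion estimation
    alpha = np.zeros(g)
    beta = _irls(y, x, offsets, alpha)
    adj = x if cox_reid else None
    for _ in range(2):
        mu = np.exp(np.clip(beta @ x.T + offsets, -30, 30))
        if prior_n > 0:
            alpha = _eb_dispersion(y, mu, adj, prior_n=prior_n)
        else:
            alpha = _ml_dispersion(y, mu, adj)
        beta = _irls(y, x, offsets, alpha)

    x_red = np.delete(x, contrast_index, axis=1)
    beta_red = _irls(y, x_red, offsets, alpha)

    mu_full = np.exp(np.clip(beta @ x.T + offsets, -30, 30))
    mu_red = np.exp(np.clip(beta_red @ x_red.T + offsets, -30, 30))
    ll_full = _nb_loglik(y, mu_full, alpha)
    ll_red = _nb_loglik(y, mu_red, alpha)
    stat = np.maximum(2.0 * (ll_full - ll_red), 0.0)

    bad = ~(np.isfinite(stat) & np.all(np.isfinite(beta), axis=1))
    if np.any(bad):
        # Poisson fallback for non-converged genes
        alpha_p = np.full(bad.sum(), 1e-8)
        bf = _irls(y[bad], x, offsets[bad], np.zeros(bad.sum()))
        br = _irls(y[bad], x_red, offsets[bad], np.zeros(bad.sum()))
        muf = np.exp(np.clip(bf @ x.T + offsets[bad], -30, 30))
        mur = np.exp(np.clip(br @ x_red.T + offsets[bad], -30, 30))
        stat[bad] = np.maximum(
            2.0 * (_nb_loglik(y[bad], muf, alpha_p) - _nb_loglik(y[bad], mur, alpha_p)),
            0.0,
        )
        beta[bad] = bf
        alpha[bad] = 1e-8

    if reference == "f":
        p = stats.f.sf(stat, 1, s - k)
    elif reference == "chi2":
        p = stats.chi2.sf(stat, df=1)
    else:
        raise ValueError("reference must be 'f' or 'chi2'")
    lfc = beta[:, contrast_index] / np.log(2.0)
    return pd.DataFrame(
        {
            "lfc": lfc,
            "p_value": p,
            "dispersion": alpha,
            "flagged": bad,
        }
    )


def lm_test(pseudo_means: np.ndarray, sample_design: np.ndarray, contrast_index: int):
    """Per-gene ordinary least squares with a two-sided t-test on one coefficient."""
    y = np.asarray(pseudo_means, dtype=float)
    x = np.asarray(sample_design, dtype=float)
    g, s = y.shape
    k = x.shape[1]
    if s <= k:
        raise ValueError(f"need more samples ({s}) than design columns ({k})")
    pinv = np.linalg.pinv(x)
    beta = y @ pinv.T  # (g, k)
    resid = y - beta @ x.T
    dof = s - k
    sigma2 = np.sum(resid**2, axis=1) / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    coef = beta[:, contrast_index]
    se = np.sqrt(sigma2 * xtx_inv[contrast_index, contrast_index])
    scale = np.maximum(np.abs(y).max(axis=1), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coef / se
    # (numerically) zero residual variance: a zero coefficient is exactly
    # null, a nonzero one infinitely significant
    degenerate = se <= 1e-10 * scale
    tstat[degenerate] = np.where(
        np.abs(coef[degenerate]) < 1e-8 * scale[degenerate], 0.0, np.inf
    )
    p = 2.0 * stats.t.sf(np.abs(tstat), df=dof)
    return pd.DataFrame(
        {
            "lfc": beta[:, contrast_index] / np.log(2.0),
            "p_value": p,
            "t": tstat,
            "flagged": np.zeros(g, dtype=bool),
        }
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN entries preserved)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


# ------------------------------------------------------------- full pipeline


def _contrast_reparam(sample_design: np.ndarray, contrast_vec: np.ndarray):
    """Rotate the design so the last coefficient equals ``contrast_vec . beta``.

    Returns the rotated design and the index of the contrast column.
    """
    k = sample_design.shape[1]
    d = np.asarray(contrast_vec, dtype=float)
    # invertible T with last row d'; complement rows from the orthogonal basis
    basis = np.linalg.svd(d[None, :])[2]
    t = np.vstack([basis[1:], d[None, :]])
    x_new = sample_design @ np.linalg.inv(t)
    return x_new, k - 1


def run_de_pipeline(dataset, design, contrast, config=None, groups=None) -> DEResult:
    """The four-step workflow: fit, delta, neighborhood selection, pseudobulk test.

    The model is fitted on training cells only; the differential-expression
    delta is computed for every cell; per-gene half-space neighborhoods are
    selected on training cells; and the significance test aggregates
    held-out cells per sample within each neighborhood, comparing the two
    conditions of the contrast with a negative-binomial LRT on summed raw
    counts (or an OLS t-test on averaged variance-stabilized values).
    BH adjustment is applied across genes with a testable neighborhood.
    """
    from .config import RunConfig
    from .datatypes import as_design_array
    from .model import LemurRegression
    from .prediction import compute_delta
    from .alignment import MatchingSets, fit_alignment
    from .preprocessing import size_factors_normed_sum, shifted_log_transform

    if config is None:
        config = RunConfig()
    if "sample_id" not in dataset.cell_meta.columns:
        raise ValueError("cell_meta must contain a 'sample_id' column")
    design_arr = as_design_array(design, dataset.n_cells)

    test_method = config.test_method
    if dataset.counts is None and test_method == "nb_lrt":
        logger.warning("no raw counts available; falling back to test_method='lm'")
        test_method = "lm"
    if dataset.counts is not None:
        sf = size_factors_normed_sum(dataset.counts)
        values = (
            dataset.values
            if dataset.values is not None
            else shifted_log_transform(dataset.counts, sf, config.pseudo_count)
        )
    else:
        values = dataset.values

    est = LemurRegression(
        n_embedding=config.n_embedding,
        test_fraction=config.test_fraction,
        random_state=config.seed,
    ).fit(values.T, design=design_arr)
    if groups is None and config.align_n_clusters:
        # emulate an externally supplied maximum-diversity clustering:
        # k-means on the unaligned embedding, clusters spanning >= 2
        # conditions become the matching sets
        from sklearn.cluster import KMeans

        labels = KMeans(
            n_clusters=config.align_n_clusters, n_init=3, random_state=config.seed
        ).fit_predict(est.embedding_.T)
        groups = MatchingSets(
            [np.flatnonzero(labels == i) for i in range(config.align_n_clusters)]
        )
    if groups is not None:
        fit_alignment(est, groups, lam=config.lambda_align)

    delta = compute_delta(est, contrast).values
    train = ~est.test_mask_
    test = train if config.test_on_train else est.test_mask_

    # selection and membership both use the model's latent coordinates Z'
    z_member = est.embedding_

    directions = None
    if config.selection_procedure == "zscore":
        directions = sample_directions(config.n_embedding, config.n_directions, config.seed)
    nbhs = select_neighborhoods(
        delta[:, train],
        z_member[:, train],
        directions=directions,
        min_cells=config.min_cells,
        selection_procedure=config.selection_procedure,
        gene_ids=dataset.gene_ids,
    )

    sample_ids = np.asarray(dataset.cell_meta["sample_id"])
    sample_levels = np.unique(sample_ids)
    # per-sample design rows (samples must be nested within conditions)
    sample_rows = np.zeros((len(sample_levels), design_arr.shape[1]))
    for s, level in enumerate(sample_levels):
        rows_s = design_arr[sample_ids == level]
        if not np.allclose(rows_s, rows_s[0]):
            raise ValueError(f"sample {level!r} spans multiple design rows")
        sample_rows[s] = rows_s[0]
    contrast_vec = contrast.row_b - contrast.row_a
    x_rot, c_idx = _contrast_reparam(sample_rows, contrast_vec)

    test_idx = np.flatnonzero(test)
    g = dataset.n_genes
    counts_mode = test_method == "nb_lrt"
    mat = dataset.counts if counts_mode else values
    totals = None
    if counts_mode:
        # robust size-factor totals: exclude the most differential genes so
        # implanted/real fold changes do not contaminate the offsets (the
        # same role trimming plays in TMM normalization)
        keep = np.ones(g, dtype=bool)
        if 0.0 < config.offset_trim < 1.0:
            strength = np.abs(delta[:, train]).mean(axis=1)
            cutoff = np.quantile(strength, 1.0 - config.offset_trim)
            keep = strength <= cutoff
        totals = mat[keep].sum(axis=0)

    # gather per-gene pseudobulk rows; batch genes with identical retained samples
    agg = np.zeros((g, len(sample_levels)))
    ncell = np.zeros((g, len(sample_levels)), dtype=int)
    tested = np.zeros(g, dtype=bool)
    n_member = np.zeros(g, dtype=int)
    test_samples = sample_ids[test_idx]
    sample_code = np.searchsorted(sample_levels, test_samples)
    for i, nbh in enumerate(nbhs):
        if nbh is None:
            continue
        member = nbh.contains(z_member[:, test_idx])
        idx = test_idx[member]
        n_member[i] = idx.size
        if idx.size == 0:
            continue
        codes = sample_code[member]
        ncell[i] = np.bincount(codes, minlength=len(sample_levels))
        agg[i] = np.bincount(codes, weights=mat[i, idx], minlength=len(sample_levels))
        if not counts_mode:
            with np.errstate(invalid="ignore"):
                agg[i] = np.where(ncell[i] > 0, agg[i] / np.maximum(ncell[i], 1), 0.0)
        tested[i] = True
        nbh.cell_ids = dataset.cell_ids[
            np.concatenate([np.flatnonzero(train)[nbh.contains(z_member[:, train])], idx])
        ]

    lfc = np.full(g, np.nan)
    pval = np.full(g, np.nan)
    flagged = np.zeros(g, dtype=bool)
    patterns = {}
    for i in np.flatnonzero(tested):
        key = tuple(np.flatnonzero(ncell[i] > 0))
        patterns.setdefault(key, []).append(i)
    for key, gene_idx in patterns.items():
        keep = np.asarray(key)
        x_sub = x_rot[keep]
        if np.linalg.matrix_rank(x_sub) < x_sub.shape[1] or x_sub.shape[0] < x_sub.shape[1] + (
            1 if counts_mode else 1
        ):
            logger.warning(
                "dropping %d gene(s): pseudobulk design not testable with samples %s",
                len(gene_idx),
                keep.tolist(),
            )
            continue
        gi = np.asarray(gene_idx)
        y_sub = agg[gi][:, keep]
        if counts_mode:
            # per-gene offsets: normed-sum size factors of the neighborhood
            # pseudobulk totals of the retained samples
            tot = np.zeros((len(gi), len(keep)))
            for row, i in enumerate(gi):
                member = nbhs[i].contains(est.embedding_[:, test_idx])
                codes = sample_code[member]
                t_all = np.bincount(
                    codes, weights=totals[test_idx[member]], minlength=len(sample_levels)
                )
                tot[row] = t_all[keep]
            sf_pb = np.maximum(tot / np.maximum(tot.mean(axis=1, keepdims=True), 1e-12), 1e-8)
            res = nb_glm_lrt(y_sub, x_sub, c_idx, offsets=np.log(sf_pb))
        else:
            res = lm_test(y_sub, x_sub, c_idx)
        lfc[gi] = res["lfc"].to_numpy()
        pval[gi] = res["p_value"].to_numpy()
        flagged[gi] = res["flagged"].to_numpy()

    table = pd.DataFrame(
        {
            "gene": dataset.gene_ids,
            "lfc": lfc,
            "p_value": pval,
            "adj_p_value": bh_adjust(pval),
            "n_cells": n_member,
            "score": [nbh.score if nbh is not None else np.nan for nbh in nbhs],
            "flagged": flagged,
        }
    )
    return DEResult(
        table=table,
        neighborhoods={n.gene_id: n for n in nbhs if n is not None},
        config=config,
        contrast=contrast,
        fit=est,
    )
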