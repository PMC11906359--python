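"""Synthetic benchmark data and evaluation metrics.

The benchmark generator emulates a multi-sample, multi-condition single-cell
count experiment: cells live on a latent backbone (a Gaussian mixture in a
low-dimensional space) that drives baseline expression through random gene
loadings; each cell belongs to one sample nested in one synthetic condition;
counts are Gamma-Poisson with per-cell size factors.  Differentially
expressed genes carry an implanted log2 fold change restricted to the
treatment-condition cells of one k-means cluster of the backbone — smaller
clusters receive larger effects — while null genes have no condition effect
(but do carry sample-level random effects and backbone structure, like real
genes that are not differential).

The metrics cover the benchmark read-outs: gene-level FDP/TPR, group
labeling by changed-cell fraction, k-NN condition mixing, the adjusted Rand
index, and L2 prediction-error summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .datatypes import CellDataset, DesignMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_benchmark_counts",
    "make_toy_two_gene",
    "knn_mixing",
    "adjusted_rand_index",
    "fdp_tpr_gene_level",
    "label_cell_groups",
    "prediction_l2_metrics",
]


@dataclass
class SimConfig:
    """Benchmark simulation settings.

    Defaults reproduce the benchmark's study conditions: 2,000 null plus 200
    differential genes, two synthetic conditions with three samples of 300
    cells each, Gamma-Poisson overdispersion 0.2, sample-effect standard
    deviation 0.1, and log2 fold changes {0.5, 1, 2, 4} implanted into
    k-means clusters with k in {2, 3, 10, 20} (larger effects into the
    smaller clusters).
    """

    n_genes_null: int = 2000
    n_genes_de: int = 200
    n_conditions: int = 2
    samples_per_condition: int = 3
    cells_per_sample: int = 300
    overdispersion: float = 0.2
    lfc_levels: tuple = (0.5, 1.0, 2.0, 4.0)
    cluster_counts: tuple = (2, 3, 10, 20)
    sample_effect_sd: float = 0.1
    baseline_mean: float = 1.0
    baseline_sd: float = 1.5
    baseline_range: tuple = (-2.0, 6.0)
    backbone_dim: int = 10
    backbone_components: int = 5
    backbone_loading_sd: float = 0.25
    size_factor_sdlog: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")
        for name in ("n_genes_null", "n_conditions", "samples_per_condition", "cells_per_sample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if any(l <= 0 for l in self.lfc_levels):
            raise ValueError("lfc_levels must be positive")
        if len(self.lfc_levels) != len(self.cluster_counts):
            raise ValueError("lfc_levels and cluster_counts must have equal length")


@dataclass
class SimTruth:
    """Per-gene ground truth: DE flag, effect size, and the affected cell set."""

    table: pd.DataFrame  # gene, is_de, lfc, k_clusters, cluster_id
    affected_cells: dict = field(default_factory=dict)  # gene -> int index array
    backbone: np.ndarray | None = None  # latent coordinates, backbone_dim x C


def _gamma_poisson(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson draws with mean ``mu`` and variance ``mu + alpha mu^2``."""
    shape = 1.0 / alpha
    lam = rng.gamma(shape, scale=mu * alpha)
    return rng.poisson(lam)


def simulate_benchmark_counts(cfg: SimConfig):
    """Simulate the benchmark dataset.

    Returns ``(CellDataset, DesignMatrix, SimTruth)``.  The design matrix is
    intercept plus a 0/1 treatment indicator.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_conditions * cfg.samples_per_condition
    c = n_samples * cfg.cells_per_sample
    g = cfg.n_genes_null + cfg.n_genes_de

    # latent backbone: Gaussian mixture with uneven component weights
    weights = np.arange(1, cfg.backbone_components + 1, dtype=float)
    weights /= weights.sum()
    comp = rng.choice(cfg.backbone_components, size=c, p=weights)
    centers = rng.normal(0.0, 3.0, size=(cfg.backbone_components, cfg.backbone_dim))
    phi = centers[comp] + rng.normal(0.0, 1.0, size=(c, cfg.backbone_dim))

    # cells are i.i.d. draws from the backbone, so assigning samples in blocks
    # is equivalent to a random assignment of cells to samples/conditions
    sample_of_cell = np.repeat(np.arange(n_samples), cfg.cells_per_sample)
    condition = sample_of_cell // cfg.samples_per_condition  # 0 = control, 1.. = treatment
    treated = (condition > 0).astype(float)

    # k-means partitions of the backbone, one per cluster count
    clusterings = {}
    for k in cfg.cluster_counts:
        km = KMeans(n_clusters=k, n_init=3, random_state=cfg.seed)
        clusterings[k] = km.fit_predict(phi)

    lfc_of_k = dict(zip(cfg.cluster_counts, cfg.lfc_levels))

    beta0 = np.clip(
        rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=g), *cfg.baseline_range
    )
    # backbone loadings emulate the latent structure of real (non-implanted)
    # genes; the implanted genes follow the count model exactly — baseline
    # plus cluster-restricted effect plus sample effects — with no latent term
    loadings = rng.normal(0.0, cfg.backbone_loading_sd, size=(g, cfg.backbone_dim))
    loadings[cfg.n_genes_null :] = 0.0
    beta_samp = rng.normal(0.0, cfg.sample_effect_sd, size=(g, n_samples))

    is_de = np.zeros(g, dtype=bool)
    is_de[cfg.n_genes_null :] = True
    lfc = np.zeros(g)
    k_chosen = np.zeros(g, dtype=int)
    cluster_chosen = np.full(g, -1, dtype=int)
    affected = {}

    eta = (
        beta0[:, None]
        + loadings @ (phi.T / np.sqrt(cfg.backbone_dim))
        + beta_samp[:, sample_of_cell]
    )
    gene_ids = np.array(
        [f"null_{i}" for i in range(cfg.n_genes_null)]
        + [f"de_{i}" for i in range(cfg.n_genes_de)]
    )
    for gi in np.flatnonzero(is_de):
        k = int(rng.choice(cfg.cluster_counts))
        labels = clusterings[k]
        cl = int(rng.integers(0, k))
        k_chosen[gi] = k
        cluster_chosen[gi] = cl
        lfc[gi] = lfc_of_k[k]
        in_cluster = labels == cl
        affected[gene_ids[gi]] = np.flatnonzero(in_cluster)
        eta[gi] += lfc[gi] * (in_cluster & (treated > 0))

    sf = rng.lognormal(mean=0.0, sigma=cfg.size_factor_sdlog, size=c)
    sf /= sf.mean()
    mu = np.exp2(eta) * sf[None, :]
    counts = _gamma_poisson(rng, mu, cfg.overdispersion)

    meta = pd.DataFrame(
        {
            "sample_id": np.array([f"s{j}" for j in sample_of_cell]),
            "condition": np.where(treated > 0, "treatment", "control"),
        }
    )
    dataset = CellDataset(counts=counts, gene_ids=gene_ids, cell_meta=meta)
    design = DesignMatrix(
        np.column_stack([np.ones(c), treated]),
        column_names=["intercept", "treatment"],
        formula="~ condition",
    )
    truth = SimTruth(
        table=pd.DataFrame(
            {
                "gene": gene_ids,
                "is_de": is_de,
                "lfc": lfc,
                "k_clusters": k_chosen,
                "cluster_id": cluster_chosen,
            }
        ),
        affected_cells=affected,
        backbone=phi.T,
    )
    return dataset, design, truth


def make_toy_two_gene(n_cells: int = 200, seed: int = 0):
    """Stylized two-gene example: two cell groups, two conditions.

    Cells sit on a one-dimensional latent segment with a "left" and a
    "right" group; under treatment, gene 1 decreases for the left group only
    and gene 2 increases for the right group only.  Returns
    ``(CellDataset, DesignMatrix, labels)`` with labels columns ``group``
    and ``condition``.
    """
    if n_cells < 20:
        raise ValueError("need at least 20 cells")
    rng = np.random.default_rng(seed)
    group = rng.integers(0, 2, size=n_cells)  # 0 = left, 1 = right
    treated = rng.integers(0, 2, size=n_cells).astype(float)
    t = np.where(group == 0, -1.0, 1.0) + rng.normal(0.0, 0.15, size=n_cells)

    # control cells on one line in gene space; treatment cells on a rotated,
    # shifted line.  The treatment-minus-control difference is 0.9*(t-1) for
    # gene 1 (negative on the left, ~0 on the right) and 0.5*(t+1) for gene 2
    # (~0 on the left, positive on the right); the two slopes differ so the
    # condition subspaces genuinely rotate.
    base = np.vstack([3.0 + 0.8 * t, 3.0 + 0.8 * t])
    effect = np.vstack([0.9 * (t - 1.0), 0.5 * (t + 1.0)])
    values = base + effect * treated[None, :] + rng.normal(0.0, 0.05, size=(2, n_cells))

    meta = pd.DataFrame(
        {
            "sample_id": np.where(treated > 0, "s_trt", "s_ctrl"),
            "condition": np.where(treated > 0, "treatment", "control"),
            "group": np.where(group == 0, "left", "right"),
        }
    )
    dataset = CellDataset(
        values=values, gene_ids=np.array(["gene_1", "gene_2"]), cell_meta=meta
    )
    design = DesignMatrix(
        np.column_stack([np.ones(n_cells), treated]),
        column_names=["intercept", "treatment"],
        formula="~ condition",
    )
    return dataset, design, meta[["group", "condition"]]


# ------------------------------------------------------------------- metrics


def knn_mixing(
    embedding: np.ndarray,
    condition_labels,
    k: int = 20,
    test_mask: np.ndarray | None = None,
) -> float:
    """Mean number of a cell's k nearest neighbors sharing its condition.

    For balanced two-condition data an ideally mixed embedding scores k/2.
    With a ``test_mask``, neighbors of held-out cells are sought among
    training cells; otherwise among all other cells.
    """
    z = np.asarray(embedding, dtype=float)
    if z.shape[0] < z.shape[1]:
        z = z.T  # cells x dims
    labels = np.asarray(condition_labels)
    n = z.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    if test_mask is not None:
        test_mask = np.asarray(test_mask, dtype=bool)
        nn = NearestNeighbors(n_neighbors=k).fit(z[~test_mask])
        idx = nn.kneighbors(z[test_mask], return_distance=False)
        same = labels[~test_mask][idx] == labels[test_mask][:, None]
    else:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(z)
        idx = nn.kneighbors(z, return_distance=False)[:, 1:]  # drop self
        same = labels[idx] == labels[:, None]
    return float(same.sum(axis=1).mean())


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Permutation-model-adjusted Rand index of two labelings."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))


def fdp_tpr_gene_level(de_table: pd.DataFrame, truth: SimTruth, nominal: float = 0.1):
    """Observed false discovery proportion and true positive rate of gene calls."""
    merged = de_table.merge(truth.table, on="gene", validate="one_to_one")
    called = merged["adj_p_value"] < nominal
    called = called.fillna(False)
    n_called = int(called.sum())
    true_pos = int((called & merged["is_de"]).sum())
    fdp = (n_called - true_pos) / max(1, n_called)
    tpr = true_pos / max(1, int(merged["is_de"].sum()))
    return float(fdp), float(tpr)


def label_cell_groups(
    group: np.ndarray, changed_cells: np.ndarray, best_fraction_fallback: bool = False
) -> str:
    """Classify a cell group against the changed-cell set.

    Positive if more than 60% of the group's cells changed (and at least
    ten); negative if less than 10% changed; otherwise indeterminate.  The
    fallback (used when no group for a gene qualifies as positive) marks the
    group with the largest changed fraction as positive.
    """
    group = np.asarray(group)
    if group.size == 0:
        raise ValueError("empty group")
    changed = np.intersect1d(group, np.asarray(changed_cells))
    frac = changed.size / group.size
    if (frac > 0.6 and changed.size >= 10) or best_fraction_fallback:
        return "positive"
    if frac < 0.1:
        return "negative"
    return "indeterminate"


def prediction_l2_metrics(
    pred: np.ndarray, obs: np.ndarray, cell_types=None
) -> pd.DataFrame:
    """L2 distances between mean (and s.d.) profiles of prediction and observation.

    Computed over all cells and, when labels are given, per cell type.
    ``pred`` and ``obs`` are genes x cells on a shared gene set (the cell
    sets may differ, for example observed versus counterfactually predicted
    populations).
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    rows = []

    def dist(p_cols, o_cols, label):
        if p_cols.shape[1] == 0 or o_cols.shape[1] == 0:
            raise ValueError(f"empty cell type {label!r}")
        rows.append(
            {
                "cell_type": label,
                "l2_mean": float(
                    np.linalg.norm(p_cols.mean(axis=1) - o_cols.mean(axis=1))
                ),
                "l2_sd": float(
                    np.linalg.norm(p_cols.std(axis=1) - o_cols.std(axis=1))
                ),
            }
        )

    dist(pred, obs, "overall")
    if cell_types is not None:
        if isinstance(cell_types, tuple) and len(cell_types) == 2:
            ct_pred, ct_obs = cell_types
        else:
            ct_pred = ct_obs = np.asarray(cell_types)
        for label in np.unique(np.concatenate([np.unique(ct_pred), np.unique(ct_obs)])):
            dist(
                pred[:, np.asarray(ct_pred) == label],
                obs[:, np.asarray(ct_obs) == label],
                str(label),
            )
    return pd.DataFrame(rows)
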