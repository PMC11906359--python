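"""Readers/writers and design-matrix construction.

Supported input formats: AnnData ``.h5ad``, MatrixMarket directories
(``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``), and dense CSV
(genes x cells, gene IDs in the first column, cell IDs in the header).
All inputs are brought to the internal genes x cells orientation; AnnData's
cell x gene matrices are transposed at the boundary (logged).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CellDataset, DesignMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_dataset",
    "write_dataset_csv",
    "build_design",
    "natural_cubic_spline_basis",
    "write_results",
    "write_fit",
    "read_fit",
    "read_matching_sets",
]


def _dense(m) -> np.ndarray:
    return np.asarray(m.todense()) if hasattr(m, "todense") else np.asarray(m)


def read_dataset(path, fmt: str | None = None, counts_layer: str | None = None) -> CellDataset:
    """Read a dataset from h5ad, an MTX directory, or a dense CSV."""
    path = Path(path)
    if fmt is None:
        if path.suffix == ".h5ad":
            fmt = "h5ad"
        elif path.is_dir():
            fmt = "mtx_dir"
        else:
            fmt = "csv"
    if fmt == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        logger.info("transposing AnnData cell x gene matrix to genes x cells")
        x = _dense(adata.X).T
        counts = None
        if counts_layer and counts_layer in adata.layers:
            counts = _dense(adata.layers[counts_layer]).T
        elif adata.raw is not None:
            counts = _dense(adata.raw.X).T
        is_counts = counts is None and np.allclose(x, np.round(x)) and x.min() >= 0
        return CellDataset(
            counts=counts if counts is not None else (x if is_counts else None),
            values=None if is_counts and counts is None else x,
            gene_ids=adata.var_names.to_numpy(),
            cell_ids=adata.obs_names.to_numpy(),
            cell_meta=adata.obs.copy(),
        )
    if fmt == "mtx_dir":
        from scipy.io import mmread

        counts = _dense(mmread(path / "matrix.mtx"))
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].to_numpy()
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].to_numpy()
        if counts.shape == (len(barcodes), len(genes)) and len(genes) != len(barcodes):
            logger.info("transposing cell x gene MTX input to genes x cells")
            counts = counts.T
        meta_path = path / "cell_meta.tsv"
        meta = (
            pd.read_csv(meta_path, sep="\t", index_col=0).loc[barcodes]
            if meta_path.exists()
            else None
        )
        return CellDataset(counts=counts, gene_ids=genes, cell_ids=barcodes, cell_meta=meta)
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        mat = df.to_numpy(dtype=float)
        integral = np.allclose(mat, np.round(mat)) and mat.min() >= 0
        return CellDataset(
            counts=mat.astype(np.int64) if integral else None,
            values=None if integral else mat,
            gene_ids=df.index.to_numpy(),
            cell_ids=df.columns.to_numpy(),
        )
    raise ValueError(f"unknown format {fmt!r}")


def write_dataset_csv(dataset: CellDataset, path) -> None:
    mat = dataset.counts if dataset.counts is not None else dataset.values
    pd.DataFrame(mat, index=dataset.gene_ids, columns=dataset.cell_ids).to_csv(path)


# --------------------------------------------------------------------- design


def natural_cubic_spline_basis(
    x: np.ndarray, df: int, knots: np.ndarray | None = None
) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (no intercept column).

    Boundary knots at the min/max of ``x``, internal knots at quantiles.
    The basis is piecewise cubic, twice continuously differentiable, and
    linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if df == 1:
        return x[:, None]
    if knots is None:
        probs = np.linspace(0, 1, df + 1)
        knots = np.quantile(x, probs)
    knots = np.sort(np.asarray(knots, dtype=float))
    if len(np.unique(knots)) != len(knots):
        raise ValueError("spline knots must be distinct; too few unique covariate values")
    kk = len(knots)  # kk = df + 1

    def d(j, t):
        num = np.maximum(t - knots[j], 0.0) ** 3 - np.maximum(t - knots[-1], 0.0) ** 3
        return num / (knots[-1] - knots[j])

    cols = [x]
    for j in range(kk - 2):
        cols.append(d(j, x) - d(kk - 2, x))
    return np.column_stack(cols)


def build_design(
    cell_meta: pd.DataFrame,
    spec=None,
    spline: tuple | None = None,
) -> DesignMatrix:
    """Build a design matrix from metadata columns or an explicit matrix.

    ``spec`` is a formula-like string ``"~ col1 + col2"`` (categorical
    columns expand to treatment-coded indicators after an intercept;
    numeric columns enter as-is), an explicit numeric matrix, or ``None``
    (intercept only).  ``spline=(column, df)`` appends a natural cubic
    spline basis of a continuous covariate.
    """
    n = len(cell_meta)
    if spec is not None and not isinstance(spec, str):
        return DesignMatrix(np.asarray(spec, dtype=float))
    cols = [np.ones(n)]
    names = ["intercept"]
    terms = []
    if isinstance(spec, str):
        terms = [t.strip() for t in spec.lstrip("~ ").split("+") if t.strip()]
    for term in terms:
        if term in ("1", ""):
            continue
        if term not in cell_meta.columns:
            raise KeyError(f"column {term!r} not found in cell metadata")
        col = cell_meta[term]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
        else:
            levels = pd.unique(col.astype(str))
            for level in sorted(levels)[1:]:  # first level is the reference
                cols.append((col.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{term}[{level}]")
    if spline is not None:
        sp_col, sp_df = spline
        basis = natural_cubic_spline_basis(cell_meta[sp_col].to_numpy(dtype=float), sp_df)
        for j in range(basis.shape[1]):
            cols.append(basis[:, j])
            names.append(f"ns({sp_col},{sp_df})[{j}]")
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {x.shape[1]}); "
            f"collinear columns among {names}"
        )
    return DesignMatrix(x, column_names=names, formula=spec if isinstance(spec, str) else None)


# ---------------------------------------------------------------- fit archive


def write_fit(fit, path) -> None:
    """Serialize a fitted model to an HDF5 group."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("base_point", data=fit.base_point_.basis)
        f.create_dataset("tangents", data=fit.tangents_)
        f.create_dataset("gamma", data=fit.gamma_)
        f.create_dataset("W", data=fit.W_)
        f.create_dataset("W0", data=fit.W0_)
        f.create_dataset("embedding", data=fit.embedding_)
        f.create_dataset("z_raw", data=fit._z_raw)
        f.create_dataset("test_mask", data=fit.test_mask_)
        f.create_dataset("design", data=fit._design_all)
        f.attrs["n_embedding"] = fit.n_embedding
        f.attrs["test_fraction"] = fit.test_fraction
        f.attrs["random_state"] = fit.random_state
        f.attrs["pseudo_count"] = fit.pseudo_count


def read_fit(path):
    """Reload a fitted model written by :func:`write_fit`."""
    import h5py

    from .grassmann import GrassmannPoint
    from .model import LemurRegression

    with h5py.File(path, "r") as f:
        est = LemurRegression(
            n_embedding=int(f.attrs["n_embedding"]),
            test_fraction=float(f.attrs["test_fraction"]),
            pseudo_count=float(f.attrs["pseudo_count"]),
            random_state=int(f.attrs["random_state"]),
        )
        est.base_point_ = GrassmannPoint(f["base_point"][...])
        est.tangents_ = f["tangents"][...]
        est.gamma_ = f["gamma"][...]
        est.W_ = f["W"][...]
        est.W0_ = f["W0"][...]
        est.embedding_ = f["embedding"][...]
        est._z_raw = f["z_raw"][...]
        est.test_mask_ = f["test_mask"][...].astype(bool)
        est._design_all = f["design"][...]
    est.design_matrix_ = DesignMatrix(est._design_all)
    est._basis_cache = {}
    est.n_features_in_ = est.gamma_.shape[0]
    est.alignment_groups_ = None
    return est


# ------------------------------------------------------------------- results


def write_results(result, out_dir) -> None:
    """Write de_table.tsv, neighborhoods.tsv, fit.h5 and run_config.json.

    Gene ordering is deterministic: by adjusted p-value, then gene name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = result.table.sort_values(
        ["adj_p_value", "gene"], na_position="last", kind="stable"
    )
    table.to_csv(out / "de_table.tsv", sep="\t", index=False, float_format="%.6g")
    rows = []
    for gene in table["gene"]:
        nbh = result.neighborhoods.get(gene)
        if nbh is None:
            continue
        for cell in nbh.cell_ids:
            rows.append((gene, cell))
    pd.DataFrame(rows, columns=["gene", "cell_id"]).to_csv(
        out / "neighborhoods.tsv", sep="\t", index=False
    )
    if result.fit is not None:
        write_fit(result.fit, out / "fit.h5")
    cfg = result.config.to_dict() if hasattr(result.config, "to_dict") else {}
    cfg["version"] = _version_string()
    with open(out / "run_config.json", "w") as f:
        json.dump(cfg, f, indent=2, sort_keys=True)


def _version_string() -> str:
    try:
        from importlib.metadata import version

        return version("lemur-sc")
    except Exception:
        return "unknown"


def read_matching_sets(path, cell_ids: np.ndarray):
    """Read matching sets from a two-column TSV (cell_id, group_id)."""
    from .alignment import MatchingSets

    df = pd.read_csv(path, sep="\t")
    pos = {cid: i for i, cid in enumerate(cell_ids)}
    sets = []
    for _, sub in df.groupby(df.columns[1], sort=True):
        sets.append(np.array([pos[c] for c in sub[df.columns[0]]]))
    return MatchingSets(sets)
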