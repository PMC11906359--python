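"""Count preprocessing: size factors and the shifted-log variance stabilization."""

from __future__ import annotations

import numpy as np

__all__ = ["size_factors_normed_sum", "shifted_log_transform"]


def size_factors_normed_sum(counts: np.ndarray) -> np.ndarray:
    """Per-cell size factors: column totals divided by the mean column total.

    The returned factors average to 1.  Cells with a zero total have no
    defined scale and raise an error naming the offending columns.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    colsums = counts.sum(axis=0, dtype=float)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        raise ValueError(
            f"cannot compute size factors: cell(s) with zero total counts at "
            f"column index {zero[:10].tolist()}"
        )
    return colsums / colsums.mean()


def shifted_log_transform(
    counts: np.ndarray, size_factors: np.ndarray | None = None, pseudo_count: float = 1.0
) -> np.ndarray:
    """Variance-stabilizing transform ``log(count / size_factor + pseudo_count)``.

    With the default pseudo-count of 1 this is ``log1p`` of the
    size-normalized counts.
    """
    if pseudo_count <= 0:
        raise ValueError(f"pseudo_count must be positive, got {pseudo_count}")
    counts = np.asarray(counts, dtype=float)
    if size_factors is None:
        size_factors = size_factors_normed_sum(counts)
    size_factors = np.asarray(size_factors, dtype=float)
    if np.any(size_factors <= 0):
        raise ValueError("size factors must be positive")
    return np.log(counts / size_factors[np.newaxis, :] + pseudo_count)
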