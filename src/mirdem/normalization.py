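"""Quantile normalization and log2 transform of intensity matrices."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["NormalizedMatrix", "quantile_normalize", "log2_transform"]


@dataclass
class NormalizedMatrix:
    """Log2 expression matrix plus a provenance tag for the transform used."""

    probe_ids: list[str]
    sample_ids: list[str]
    log2_values: np.ndarray
    provenance: dict = field(default_factory=dict)


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Force every column onto the common rank-mean distribution.

    The value at rank r of column c is replaced by the mean over columns of
    the rank-r order statistics.  Ties within a column receive the mean of
    the reference values over their tied rank span, so the map is symmetric
    and deterministic.  After the transform all columns hold identical
    multisets of values, and applying it again is a no-op.

    Parameters
    ----------
    matrix : (probes, samples) array of non-negative finite reals.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] == 0 or m.shape[1] == 0:
        raise ValueError("expected a non-empty 2-D matrix")
    if not np.isfinite(m).all():
        raise ValueError("matrix contains NaN or infinite values")
    if (m < 0).any():
        raise ValueError("negative intensities are not allowed")

    reference = np.sort(m, axis=0).mean(axis=1)
    out = np.empty_like(m)
    for c in range(m.shape[1]):
        col = m[:, c]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        # walk tie runs in sorted order; each run gets the reference mean
        i = 0
        n = len(col)
        while i < n:
            j = i + 1
            while j < n and sorted_col[j] == sorted_col[i]:
                j += 1
            out[order[i:j], c] = reference[i:j].mean()
            i = j
    return out


def log2_transform(
    matrix: np.ndarray,
    offset: float = 1.0,
    probe_ids: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> NormalizedMatrix:
    """Elementwise ``log2(value + offset)``; the offset is recorded in the
    provenance so the transform is invertible."""
    m = np.asarray(matrix, dtype=float)
    if ((m + offset) <= 0).any():
        raise ValueError("value + offset must be positive everywhere")
    values = np.log2(m + offset)
    n_probes, n_samples = m.shape
    return NormalizedMatrix(
        probe_ids=list(probe_ids) if probe_ids is not None else [f"p{i}" for i in range(n_probes)],
        sample_ids=list(sample_ids) if sample_ids is not None else [f"s{i}" for i in range(n_samples)],
        log2_values=values,
        provenance={"method": "log2", "offset": float(offset)},
    )
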