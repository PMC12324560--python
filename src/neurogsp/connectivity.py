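"""Functional connectivity: Pearson correlation matrices and edge vectors.

The canonical edge order everywhere in the package is the strictly upper
triangle in row-major order (``np.triu_indices(R, 1)``).
"""

from __future__ import annotations

import logging

import numpy as np

from .types import ConnectivityMatrix, ParcellatedTimeSeries

logger = logging.getLogger(__name__)

__all__ = ["pearson_fc", "vectorize_upper", "devectorize", "edge_labels"]


def _ts_data(ts) -> np.ndarray:
    if isinstance(ts, ParcellatedTimeSeries):
        return ts.data
    return np.atleast_2d(np.asarray(ts, dtype=float))


def pearson_fc(ts, subject_id: str = "", min_sd: float = 0.0) -> ConnectivityMatrix:
    """Pearson correlation between every pair of regional time series.

    Regions whose temporal SD is at or below ``min_sd`` (default: exactly
    zero) are degenerate and get correlation 0 off-diagonal (logged); the
    diagonal is always 1.
    """
    x = _ts_data(ts)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 frames for a correlation matrix")
    sd = x.std(axis=0)
    degenerate = sd <= min_sd
    if np.any(degenerate):
        logger.warning(
            "pearson_fc: %d zero-variance region(s), correlations set to 0",
            int(degenerate.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x, rowvar=False)
    c = np.nan_to_num(c, nan=0.0)
    c[degenerate, :] = 0.0
    c[:, degenerate] = 0.0
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix(values=c, kind="fc", subject_id=subject_id)


def vectorize_upper(cm) -> np.ndarray:
    """Strictly-upper-triangle entries in row-major order, length R(R-1)/2."""
    m = cm.values if isinstance(cm, ConnectivityMatrix) else np.asarray(cm, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be a square matrix")
    iu, ju = np.triu_indices(m.shape[0], k=1)
    return m[iu, ju].copy()


def devectorize(vec: np.ndarray, diag_value: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` (diagonal filled with diag_value)."""
    vec = np.asarray(vec, dtype=float).ravel()
    # solve R(R-1)/2 = len
    r = int(round((1 + np.sqrt(1 + 8 * vec.size)) / 2))
    if r * (r - 1) // 2 != vec.size:
        raise ValueError(f"length {vec.size} is not R(R-1)/2 for any integer R")
    out = np.full((r, r), 0.0)
    iu, ju = np.triu_indices(r, k=1)
    out[iu, ju] = vec
    out += out.T
    np.fill_diagonal(out, diag_value)
    return out


def edge_labels(n_regions: int) -> list[str]:
    """Edge names 'i_j' (1-based region indices) in canonical order."""
    iu, ju = np.triu_indices(n_regions, k=1)
    return [f"{i + 1}_{j + 1}" for i, j in zip(iu, ju)]
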