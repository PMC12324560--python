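"""Cleaning of parcellated BOLD time series.

The pipeline starts from parcellated (time x region) matrices: initial-frame
discard, then a single joint least-squares projection per session removing
intercept, linear trend, motion confounds plus their first-order backward
differences, and a discrete-cosine high-pass basis (default cutoff 0.01 Hz).

A single combined regression is used rather than sequential detrend /
confound-regress / filter steps: sequential orthogonalization can reintroduce
variance already removed, while a joint projection is order-free and leaves
residuals exactly orthogonal to every regressor.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .types import ConfoundSet, ParcellatedTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "discard_initial_frames",
    "dct_highpass_basis",
    "nuisance_regress",
    "NuisanceRegressor",
]


def discard_initial_frames(
    ts: ParcellatedTimeSeries, n_discard: int = 6, per_session: bool = False
) -> ParcellatedTimeSeries:
    """Drop the first ``n_discard`` frames (scanner drift/equilibration).

    By default only the first session loses frames; ``per_session=True``
    discards at the start of every session.
    """
    if n_discard < 0:
        raise ValueError("n_discard must be nonnegative")
    if n_discard == 0:
        return ts
    lengths = list(ts.session_lengths)
    sessions = [ts.data[s] for s in ts.session_slices()]
    targets = range(len(sessions)) if per_session else [0]
    for i in targets:
        if n_discard >= lengths[i]:
            raise ValueError(
                f"cannot discard {n_discard} frames from a session of "
                f"{lengths[i]} frames"
            )
        sessions[i] = sessions[i][n_discard:]
        lengths[i] -= n_discard
    return ts.with_data(np.vstack(sessions), session_lengths=lengths)


def dct_highpass_basis(n_frames: int, tr: float, highpass_hz: float) -> np.ndarray:
    """Discrete-cosine columns spanning periods longer than 1/highpass_hz.

    Column k (k = 1..K) is cos(pi * k * (t + 1/2) / n) with frequency
    k / (2 * n * tr); all columns with frequency strictly below the cutoff
    are included. May be empty (shape (n, 0)) for short segments.
    """
    if highpass_hz <= 0:
        return np.empty((n_frames, 0))
    k_max = int(np.ceil(2 * n_frames * tr * highpass_hz)) + 1
    t = np.arange(n_frames)
    cols = []
    for k in range(1, k_max + 1):
        if k / (2 * n_frames * tr) >= highpass_hz:
            break
        cols.append(np.cos(np.pi * k * (t + 0.5) / n_frames))
    if not cols:
        return np.empty((n_frames, 0))
    return np.column_stack(cols)


def _backward_diff(x: np.ndarray) -> np.ndarray:
    """First-order backward difference, first row zero-padded."""
    d = np.zeros_like(x)
    d[1:] = np.diff(x, axis=0)
    return d


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            f"rank-deficient nuisance design ({rank}/{design.shape[1]}); "
            "using least-norm solution",
            stacklevel=3,
        )
    return y - design @ beta


def nuisance_regress(
    ts: ParcellatedTimeSeries,
    confounds: ConfoundSet | np.ndarray | None = None,
    highpass_hz: float = 0.01,
    detrend: bool = True,
    add_derivatives: bool = True,
) -> ParcellatedTimeSeries:
    """Joint confound regression + detrend + high-pass, per session.

    The design matrix per session is [intercept, linear trend, confounds,
    backward-difference confound derivatives, DCT high-pass basis]; each
    region's series is replaced by the residual of a single least-squares
    projection onto it. Residuals therefore have zero mean and are orthogonal
    to every regressor; applying the operation twice is a no-op.

    Sessions are processed independently (separate acquisitions) and then
    re-concatenated.
    """
    if confounds is not None and not isinstance(confounds, ConfoundSet):
        confounds = ConfoundSet(regressors=confounds)
    if confounds is not None and confounds.regressors.shape[0] != ts.n_frames:
        raise ValueError(
            f"confound rows {confounds.regressors.shape[0]} != "
            f"time-series frames {ts.n_frames}"
        )
    out_sessions = []
    for sl in ts.session_slices():
        y = ts.data[sl]
        n = y.shape[0]
        parts = [np.ones((n, 1))]
        if detrend:
            parts.append(np.linspace(-1.0, 1.0, n)[:, None])
        if confounds is not None:
            c = confounds.regressors[sl]
            parts.append(c)
            if add_derivatives:
                parts.append(_backward_diff(c))
        parts.append(dct_highpass_basis(n, ts.tr, highpass_hz))
        design = np.hstack(parts)
        out_sessions.append(_residualize(y, design))
    return ts.with_data(np.vstack(out_sessions), session_lengths=ts.session_lengths)


class NuisanceRegressor(BaseEstimator, TransformerMixin):
    """Stateless transformer applying frame discard + nuisance regression.

    Operates on a list of :class:`ParcellatedTimeSeries` (optionally paired
    with per-subject :class:`ConfoundSet` via ``confounds`` at transform
    time). Follows the scikit-learn transformer API so it can sit at the
    front of a pipeline; ``fit`` is a no-op.
    """

    def __init__(
        self,
        n_discard: int = 6,
        highpass_hz: float = 0.01,
        detrend: bool = True,
        add_derivatives: bool = True,
        per_session_discard: bool = False,
    ):
        self.n_discard = n_discard
        self.highpass_hz = highpass_hz
        self.detrend = detrend
        self.add_derivatives = add_derivatives
        self.per_session_discard = per_session_discard

    def fit(self, X, y=None):
        return self

    def transform(self, X, confounds=None):
        if confounds is None:
            confounds = [None] * len(X)
        if len(confounds) != len(X):
            raise ValueError("need one confound set (or None) per subject")
        out = []
        for ts, conf in zip(X, confounds):
            ts = discard_initial_frames(
                ts, self.n_discard, per_session=self.per_session_discard
            )
            if conf is not None and not isinstance(conf, ConfoundSet):
                conf = ConfoundSet(regressors=conf)
            if conf is not None and conf.regressors.shape[0] == ts.n_frames + self.n_discard:
                # confounds supplied for the un-discarded series
                conf = ConfoundSet(
                    regressors=conf.regressors[self.n_discard:], labels=conf.labels
                )
            out.append(
                nuisance_regress(
                    ts,
                    conf,
                    highpass_hz=self.highpass_hz,
                    detrend=self.detrend,
                    add_derivatives=self.add_derivatives,
                )
            )
        return out
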