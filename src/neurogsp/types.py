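"""Core data containers shared across the pipeline.

The pipeline operates on parcellated data only: per-subject BOLD matrices
(time × regions), structural connectomes (region × region weights), and a
cohort table (pandas DataFrame) carrying subject/family identifiers,
demographics and prediction targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParcellatedTimeSeries",
    "StructuralConnectome",
    "GraphSpectrum",
    "ConfoundSet",
    "ConnectivityMatrix",
    "FeatureVector",
    "Cohort",
    "FEATURE_NAMES",
    "feature_dim",
]

#: Canonical feature names. Region-wise features have dimension R, edge-wise
#: features R(R-1)/2.
FEATURE_NAMES = (
    "mean",
    "sd",
    "mssd",
    "falff",
    "fc",
    "psd",
    "sdi",
    "coupled_fc",
    "decoupled_fc",
)

_EDGE_FEATURES = frozenset({"fc", "coupled_fc", "decoupled_fc"})


def feature_dim(name: str, n_regions: int) -> int:
    """Declared dimensionality of a named feature at a given region count."""
    if name not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {name!r}; valid: {FEATURE_NAMES}")
    if name in _EDGE_FEATURES:
        return n_regions * (n_regions - 1) // 2
    return n_regions


@dataclass
class ParcellatedTimeSeries:
    """Per-subject BOLD matrix with acquisition metadata.

    Parameters
    ----------
    data : ndarray of shape (T, R)
        BOLD signal, rows are frames (sessions concatenated), columns regions.
    tr : float
        Repetition time in seconds.
    session_lengths : sequence of int, optional
        Frame count of each session; must sum to T. Defaults to a single
        session spanning all frames.
    subject_id : str
    """

    data: np.ndarray
    tr: float = 0.72
    session_lengths: Sequence[int] | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (frames x regions) array")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.session_lengths is None:
            self.session_lengths = [self.data.shape[0]]
        self.session_lengths = [int(n) for n in self.session_lengths]
        if any(n <= 0 for n in self.session_lengths):
            raise ValueError("session lengths must be positive")
        if sum(self.session_lengths) != self.data.shape[0]:
            raise ValueError(
                f"session_lengths sum {sum(self.session_lengths)} != "
                f"frame count {self.data.shape[0]}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def session_slices(self) -> list[slice]:
        """Row slices delimiting each session in ``data``."""
        bounds = np.concatenate([[0], np.cumsum(self.session_lengths)])
        return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]

    def with_data(self, data: np.ndarray,
                  session_lengths: Sequence[int] | None = None
                  ) -> "ParcellatedTimeSeries":
        return ParcellatedTimeSeries(
            data=data,
            tr=self.tr,
            session_lengths=list(session_lengths)
            if session_lengths is not None else None,
            subject_id=self.subject_id,
        )


@dataclass
class StructuralConnectome:
    """Symmetric nonnegative weight matrix with zero diagonal.

    ``weights`` carries normalized fiber-density-like edge weights;
    ``distances`` (optional) the inter-region Euclidean distances used by
    distance-binned consensus thresholding.
    """

    weights: np.ndarray
    distances: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if np.max(np.abs(w - w.T)) > 1e-12:
            raise ValueError("weights must be symmetric (tol 1e-12)")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have a zero diagonal")
        if np.min(w) < 0:
            raise ValueError("weights must be nonnegative")
        self.weights = w
        if self.distances is not None:
            self.distances = np.asarray(self.distances, dtype=float)
            if self.distances.shape != w.shape:
                raise ValueError("distances shape must match weights")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class GraphSpectrum:
    """Eigendecomposition of a normalized graph Laplacian.

    ``eigenvalues`` ascending in [0, 2] (graph frequencies), ``eigenvectors``
    the connectome harmonics as orthonormal columns ordered accordingly, and
    ``cutoff_index`` the low/high split: harmonics with index < cutoff_index
    form the low-frequency band.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    cutoff_index: int

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        r = self.eigenvalues.shape[0]
        if self.eigenvectors.shape != (r, r):
            raise ValueError("eigenvectors must be R x R")
        if np.any(np.diff(self.eigenvalues) < -1e-10):
            raise ValueError("eigenvalues must be ascending")
        if self.eigenvalues[0] < -1e-8 or self.eigenvalues[-1] > 2 + 1e-8:
            raise ValueError("normalized-Laplacian eigenvalues must lie in [0, 2]")
        gram = self.eigenvectors.T @ self.eigenvectors
        if np.max(np.abs(gram - np.eye(r))) > 1e-8:
            raise ValueError("eigenvectors must be orthonormal")
        if not (1 <= self.cutoff_index <= r - 1):
            raise ValueError("cutoff_index must be in [1, R-1]")

    @property
    def n_regions(self) -> int:
        return self.eigenvalues.shape[0]


@dataclass
class ConfoundSet:
    """Nuisance regressors aligned to a time series (T x C)."""

    regressors: np.ndarray
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.labels is None:
            self.labels = [f"confound_{i}" for i in range(self.regressors.shape[1])]
        if len(self.labels) != self.regressors.shape[1]:
            raise ValueError("label count must match regressor columns")


@dataclass
class ConnectivityMatrix:
    """Symmetric correlation matrix with unit diagonal."""

    values: np.ndarray
    kind: str = "fc"
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be square")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class FeatureVector:
    """Named per-subject feature array (length R or R(R-1)/2)."""

    name: str
    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.name not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {self.name!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def dim(self) -> int:
        return self.values.shape[0]


@dataclass
class Cohort:
    """A cohort: subject table plus per-subject time series and connectomes.

    ``table`` rows align positionally with ``timeseries`` and ``connectomes``.
    """

    table: pd.DataFrame
    timeseries: list[ParcellatedTimeSeries] = field(default_factory=list)
    connectomes: list[StructuralConnectome] = field(default_factory=list)
    distances: np.ndarray | None = None
    coords: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = len(self.table)
        for attr in ("timeseries", "connectomes"):
            seq = getattr(self, attr)
            if seq and len(seq) != n:
                raise ValueError(f"{attr} length {len(seq)} != table rows {n}")

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["subject_id"].to_numpy()

    @property
    def family_ids(self) -> np.ndarray:
        return self.table["family_id"].to_numpy()

    def subset(self, indices: np.ndarray) -> "Cohort":
        """Positional subset (new Cohort; arrays are shared, not copied)."""
        idx = np.asarray(indices)
        return Cohort(
            table=self.table.iloc[idx].reset_index(drop=True),
            timeseries=[self.timeseries[i] for i in idx] if self.timeseries else [],
            connectomes=[self.connectomes[i] for i in idx] if self.connectomes else [],
            distances=self.distances,
            coords=self.coords,
        )

    def with_timeseries(self, timeseries: list[ParcellatedTimeSeries]) -> "Cohort":
        return replace(self, timeseries=timeseries)
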