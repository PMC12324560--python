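"""Feature extractors in the scikit-learn transformer idiom.

Each extractor maps a :class:`~neurogsp.types.Cohort` to an
``(n_subjects, dim)`` feature matrix, where ``dim`` is R for region-wise
features (mean, sd, mssd, falff, psd, sdi) and R(R-1)/2 for edge-wise ones
(fc, coupled_fc, decoupled_fc).

Extractors that need no group model (`fit` is a no-op) are the purely
functional ones; the graph-signal-processing extractors carry real fitted
state: calling ``fit(cohort)`` builds the consensus structural connectome
and its Laplacian eigendecomposition **from the fitted subjects only**, so
using them inside a cross-validation loop automatically keeps test subjects
out of the consensus graph.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import gsp, regional
from .connectivity import pearson_fc, vectorize_upper
from .types import Cohort, ParcellatedTimeSeries, feature_dim

__all__ = [
    "RegionalMeanExtractor",
    "RegionalSDExtractor",
    "MSSDExtractor",
    "FALFFExtractor",
    "FCExtractor",
    "GraphPSDExtractor",
    "SDIExtractor",
    "CoupledFCExtractor",
    "DecoupledFCExtractor",
    "make_extractor",
    "EXTRACTORS",
]


def _timeseries(X) -> list[ParcellatedTimeSeries]:
    if isinstance(X, Cohort):
        if not X.timeseries:
            raise ValueError("cohort carries no time series")
        return X.timeseries
    return list(X)


class _TimeSeriesExtractor(BaseEstimator, TransformerMixin):
    """Base for stateless per-subject time-series features."""

    feature_name: str = ""

    def fit(self, X, y=None):
        self.n_regions_ = _timeseries(X)[0].n_regions
        return self

    def transform(self, X) -> np.ndarray:
        series = _timeseries(X)
        return np.vstack([self._one(ts) for ts in series])

    def _one(self, ts: ParcellatedTimeSeries) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class RegionalMeanExtractor(_TimeSeriesExtractor):
    """Temporal mean per region."""

    feature_name = "mean"

    def _one(self, ts):
        return regional.regional_mean(ts)


class RegionalSDExtractor(_TimeSeriesExtractor):
    """Sample SD per region (ddof=1)."""

    feature_name = "sd"

    def _one(self, ts):
        return regional.regional_sd(ts)


class MSSDExtractor(_TimeSeriesExtractor):
    """Mean squared successive difference (BOLD variability) per region."""

    feature_name = "mssd"

    def _one(self, ts):
        return regional.mssd(ts)


class FALFFExtractor(_TimeSeriesExtractor):
    """Fractional amplitude of low-frequency fluctuations per region."""

    feature_name = "falff"

    def __init__(self, low_band=(0.01, 0.08), mode="amplitude"):
        self.low_band = low_band
        self.mode = mode

    def _one(self, ts):
        return regional.falff(ts, low_band=tuple(self.low_band), mode=self.mode)


class FCExtractor(_TimeSeriesExtractor):
    """Vectorized upper triangle of the Pearson FC matrix."""

    feature_name = "fc"

    def _one(self, ts):
        return vectorize_upper(pearson_fc(ts, subject_id=ts.subject_id))


class _GSPExtractor(BaseEstimator, TransformerMixin):
    """Base for consensus-spectrum features.

    ``fit`` builds the distance-binned consensus connectome from the fitted
    cohort's structural matrices and decomposes its normalized Laplacian;
    fitted attributes are ``consensus_``, ``spectrum_``.
    """

    feature_name: str = ""

    def __init__(self, cutoff_index: int | None = None, n_bins: int = 50):
        self.cutoff_index = cutoff_index
        self.n_bins = n_bins

    def fit(self, X: Cohort, y=None):
        if not isinstance(X, Cohort) or not X.connectomes:
            raise ValueError("GSP extractors require a Cohort with connectomes")
        self.consensus_ = gsp.consensus_sc(
            X.connectomes, distances=X.distances, n_bins=self.n_bins
        )
        self.spectrum_ = gsp.spectrum_from_connectome(
            self.consensus_, cutoff_index=self.cutoff_index
        )
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "spectrum_")
        series = _timeseries(X)
        return np.vstack([self._one(ts) for ts in series])

    def _demeaned(self, ts: ParcellatedTimeSeries) -> np.ndarray:
        return ts.data - ts.data.mean(axis=0, keepdims=True)

    def _one(self, ts):  # pragma: no cover
        raise NotImplementedError


class GraphPSDExtractor(_GSPExtractor):
    """Graph power spectral density over the consensus harmonics."""

    def __init__(self, cutoff_index=None, n_bins=50, psd_mode="l2"):
        super().__init__(cutoff_index=cutoff_index, n_bins=n_bins)
        self.psd_mode = psd_mode

    feature_name = "psd"

    def _one(self, ts):
        coeff = gsp.gft(self._demeaned(ts), self.spectrum_)
        return gsp.graph_psd(coeff, mode=self.psd_mode)


class SDIExtractor(_GSPExtractor):
    """Structural decoupling index per region."""

    def __init__(self, cutoff_index=None, n_bins=50, log2=False, max_ratio=1e6):
        super().__init__(cutoff_index=cutoff_index, n_bins=n_bins)
        self.log2 = log2
        self.max_ratio = max_ratio

    feature_name = "sdi"

    def _one(self, ts):
        return gsp.sdi(
            ts.data, self.spectrum_, max_ratio=self.max_ratio, log2=self.log2
        )


class CoupledFCExtractor(_GSPExtractor):
    """FC of the low-pass (structure-coupled) graph-filtered signal."""

    feature_name = "coupled_fc"

    def _one(self, ts):
        return gsp.coupled_decoupled_fc(
            self._demeaned(ts), self.spectrum_, subject_id=ts.subject_id
        ).coupled_vector


class DecoupledFCExtractor(_GSPExtractor):
    """FC of the high-pass (structure-decoupled) graph-filtered signal."""

    feature_name = "decoupled_fc"

    def _one(self, ts):
        return gsp.coupled_decoupled_fc(
            self._demeaned(ts), self.spectrum_, subject_id=ts.subject_id
        ).decoupled_vector


EXTRACTORS = {
    "mean": RegionalMeanExtractor,
    "sd": RegionalSDExtractor,
    "mssd": MSSDExtractor,
    "falff": FALFFExtractor,
    "fc": FCExtractor,
    "psd": GraphPSDExtractor,
    "sdi": SDIExtractor,
    "coupled_fc": CoupledFCExtractor,
    "decoupled_fc": DecoupledFCExtractor,
}

GSP_FEATURES = frozenset({"psd", "sdi", "coupled_fc", "decoupled_fc"})


def make_extractor(name: str, **kwargs):
    """Instantiate the extractor for a canonical feature name."""
    try:
        cls = EXTRACTORS[name]
    except KeyError:
        raise ValueError(
            f"unknown feature {name!r}; valid: {sorted(EXTRACTORS)}"
        ) from None
    return cls(**kwargs)


def expected_dim(name: str, n_regions: int) -> int:
    return feature_dim(name, n_regions)
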