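"""Family-grouped nested-CV behavior prediction with permutation nulls.

The evaluation protocol: the cohort is split into ``n_splits`` random
train/test partitions with whole families kept on one side (test fraction
~15% of the available subjects; because families are indivisible the
realized sizes vary slightly). Within each training set a 3-fold
family-grouped inner CV selects hyperparameters of a standard-scaled model
(elastic net, linear kernel ridge, elastic-net logistic classifier, or
linear SVM); the refit model is scored on the held-out subjects with R²
(test-mean baseline) or accuracy. Significance is assessed against a
permutation null: targets reshuffled ``n_perms`` times per split with the
identical pipeline rerun, and a feature counts as significant when the mean
of the real metric distribution exceeds the 95th percentile of the pooled
null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.metrics import accuracy_score, r2_score
from sklearn.model_selection import BaseCrossValidator, GridSearchCV, GroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import GSP_FEATURES, make_extractor
from .preproc import NuisanceRegressor
from .types import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "FamilyShuffleSplit",
    "SplitScheme",
    "ModelSpec",
    "PredictionResult",
    "make_family_splits",
    "default_model_spec",
    "build_estimator",
    "fit_evaluate",
    "permutation_null",
    "significance",
    "summarize",
    "run_prediction",
]

MODEL_NAMES = ("elastic_net", "krr", "elastic_net_clf", "svm")
_CLASSIFIERS = frozenset({"elastic_net_clf", "svm"})


@dataclass
class SplitScheme:
    """One train/test partition with families kept whole."""

    split_id: int
    train_ids: np.ndarray  # positional indices
    test_ids: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.train_ids = np.asarray(self.train_ids, dtype=int)
        self.test_ids = np.asarray(self.test_ids, dtype=int)
        if np.intersect1d(self.train_ids, self.test_ids).size:
            raise ValueError("train and test sets overlap")


class FamilyShuffleSplit(BaseCrossValidator):
    """Random grouped train/test splits at a target test fraction.

    Like ``GroupShuffleSplit`` but targeting a test *subject* count rather
    than a group count: families (groups) are shuffled and greedily assigned
    to the test side until its size is as close as possible to
    ``test_frac * n``. Each of the ``n_splits`` draws is independent.
    """

    def __init__(self, n_splits: int = 10, test_frac: float = 0.15,
                 random_state: int = 0):
        self.n_splits = n_splits
        self.test_frac = test_frac
        self.random_state = random_state

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return self.n_splits

    def _iter_test_indices(self, X=None, y=None, groups=None):
        for _, test in self.split(X, y, groups):
            yield test

    def split(self, X, y=None, groups=None):
        if groups is None:
            raise ValueError("FamilyShuffleSplit requires groups (family ids)")
        groups = np.asarray(groups)
        n = groups.shape[0]
        if not (0 < self.test_frac < 1):
            raise ValueError("test_frac must lie in (0, 1)")
        fams, counts = np.unique(groups, return_counts=True)
        target = self.test_frac * n
        if counts.max() > (1 - self.test_frac) * n:
            raise ValueError(
                "one family exceeds the training capacity "
                f"({counts.max()} subjects > {(1 - self.test_frac) * n:.0f})"
            )
        for k in range(self.n_splits):
            rng = np.random.default_rng(
                np.random.SeedSequence(int(self.random_state), spawn_key=(k,))
            )
            order = rng.permutation(len(fams))
            test_count = 0
            in_test = np.zeros(len(fams), dtype=bool)
            for f in order:
                c = int(counts[f])
                # add the family if it brings us (weakly) closer to target
                if abs(test_count + c - target) <= abs(test_count - target):
                    in_test[f] = True
                    test_count += c
                if test_count >= target:
                    break
            mask = np.isin(groups, fams[in_test])
            yield np.flatnonzero(~mask), np.flatnonzero(mask)


def make_family_splits(
    cohort: Cohort | pd.DataFrame,
    n_splits: int = 10,
    test_frac: float = 0.15,
    seed: int = 0,
) -> list[SplitScheme]:
    """Thin wrapper over :class:`FamilyShuffleSplit` returning SplitSchemes."""
    table = cohort.table if isinstance(cohort, Cohort) else cohort
    groups = table["family_id"].to_numpy()
    splitter = FamilyShuffleSplit(
        n_splits=n_splits, test_frac=test_frac, random_state=seed
    )
    return [
        SplitScheme(split_id=i + 1, train_ids=tr, test_ids=te, seed=seed)
        for i, (tr, te) in enumerate(splitter.split(np.zeros(len(table)), groups=groups))
    ]


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """A model family with its hyperparameter grid and inner-CV setting."""

    name: str
    task: str
    hyper_grid: Mapping[str, Sequence] = field(default_factory=dict)
    inner_folds: int = 3

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; valid: {MODEL_NAMES}")
        expected = "classification" if self.name in _CLASSIFIERS else "regression"
        if self.task != expected:
            raise ValueError(f"model {self.name} is a {expected} model")
        if not self.hyper_grid:
            raise ValueError("hyper_grid must be non-empty")


_ALPHAS = np.logspace(-3, 3, 7)


def default_model_spec(name: str, inner_folds: int = 3,
                       small_grid: bool = False) -> ModelSpec:
    """Standard hyperparameter grids for the four model families.

    ``small_grid=True`` shrinks grids to 3 regularization strengths and one
    mixing ratio — intended for compact simulation studies.
    """
    alphas = np.logspace(-2, 2, 3) if small_grid else _ALPHAS
    ratios = [0.5] if small_grid else [0.1, 0.5, 0.9]
    task = "classification" if name in _CLASSIFIERS else "regression"
    grids = {
        "elastic_net": {"model__alpha": alphas, "model__l1_ratio": ratios},
        "krr": {"model__alpha": alphas},
        "elastic_net_clf": {"model__C": 1.0 / alphas, "model__l1_ratio": ratios},
        "svm": {"model__C": 1.0 / alphas},
    }
    if name not in grids:
        raise ValueError(f"unknown model {name!r}; valid: {MODEL_NAMES}")
    return ModelSpec(name=name, task=task, hyper_grid=grids[name],
                     inner_folds=inner_folds)


def build_estimator(spec: ModelSpec) -> Pipeline:
    """Standard-scaled pipeline for a model spec (grid applied separately)."""
    models: dict[str, BaseEstimator] = {
        "elastic_net": ElasticNet(max_iter=20000),
        "krr": KernelRidge(kernel="linear"),
        "elastic_net_clf": LogisticRegression(
            penalty="elasticnet", solver="saga", max_iter=5000, random_state=0
        ),
        "svm": SVC(kernel="linear"),
    }
    return Pipeline([("scale", StandardScaler()), ("model", models[spec.name])])


def _resolve_model(model: str | ModelSpec) -> ModelSpec:
    return default_model_spec(model) if isinstance(model, str) else model


def fit_evaluate(
    features: np.ndarray,
    targets: np.ndarray,
    split: SplitScheme,
    model: str | ModelSpec,
    families: np.ndarray,
    subject_ids: np.ndarray | None = None,
    train_ids: np.ndarray | None = None,
) -> float:
    """Nested-CV fit on one split; returns the held-out metric.

    Scaling (feature standardization and, for regression, target
    standardization) is fit on training subjects only; hyperparameters come
    from a family-grouped inner ``GroupKFold``; the refit model is scored on
    the test subjects with R² (1 - SSE/SST around the test mean) or accuracy.

    ``train_ids`` overrides the split's training set (used by the scaling
    experiments to subsample training subjects while keeping the test set).
    """
    spec = _resolve_model(model)
    x = np.asarray(features, dtype=float)
    y = np.asarray(targets)
    bad = ~np.all(np.isfinite(x), axis=1)
    if np.any(bad):
        who = (subject_ids[bad] if subject_ids is not None
               else np.flatnonzero(bad))
        raise ValueError(f"non-finite features for subjects: {list(who)[:10]}")

    tr = split.train_ids if train_ids is None else np.asarray(train_ids, int)
    te = split.test_ids
    x_tr, x_te = x[tr], x[te]
    y_tr, y_te = y[tr], y[te]
    groups_tr = np.asarray(families)[tr]

    pipe = build_estimator(spec)
    inner = GroupKFold(n_splits=spec.inner_folds)
    scoring = "accuracy" if spec.task == "classification" else "r2"
    search = GridSearchCV(
        pipe, dict(spec.hyper_grid), cv=inner, scoring=scoring, n_jobs=None,
        refit=True,
    )
    if spec.task == "regression":
        mu, sd = float(np.mean(y_tr)), float(np.std(y_tr))
        sd = sd if sd > 0 else 1.0
        search.fit(x_tr, (y_tr - mu) / sd, groups=groups_tr)
        pred = search.predict(x_te) * sd + mu   # back to original units
        return float(r2_score(y_te, pred))
    search.fit(x_tr, y_tr, groups=groups_tr)
    return float(accuracy_score(y_te, search.predict(x_te)))


def permutation_null(
    features_per_split: Sequence[np.ndarray] | np.ndarray,
    targets: np.ndarray,
    splits: Sequence[SplitScheme],
    model: str | ModelSpec,
    families: np.ndarray,
    n_perms: int = 100,
    seed: int = 0,
    train_ids_per_split: Sequence[np.ndarray] | None = None,
) -> np.ndarray:
    """Null metrics: targets reshuffled ``n_perms`` times per split.

    Each permutation reshuffles the target vector uniformly across *all*
    subjects (split membership fixed) and reruns the identical nested-CV
    pipeline; returns an (n_splits, n_perms) array. Features do not depend
    on the targets, so each split's precomputed feature matrix is reused.
    ``features_per_split`` may be a single matrix shared by all splits or
    one matrix per split (needed for the GSP features, whose consensus graph
    is refit per training set).
    """
    y = np.asarray(targets)
    n = y.shape[0]
    if isinstance(features_per_split, np.ndarray):
        features_per_split = [features_per_split] * len(splits)
    out = np.empty((len(splits), n_perms))
    for i, split in enumerate(splits):
        rng = np.random.default_rng(
            np.random.SeedSequence(int(seed), spawn_key=(7, split.split_id))
        )
        tr_ids = None if train_ids_per_split is None else train_ids_per_split[i]
        for p in range(n_perms):
            yp = y[rng.permutation(n)]
            out[i, p] = fit_evaluate(
                features_per_split[i], yp, split, model, families,
                train_ids=tr_ids,
            )
    return out


def significance(
    real_metrics: np.ndarray, null_metrics: np.ndarray
) -> tuple[float, bool]:
    """Permutation p-value and the 95th-percentile significance verdict.

    A feature is significant when the mean of the real metric distribution
    strictly exceeds the 95th percentile of the pooled null. The reported
    p-value is (1 + #{null >= real mean}) / (1 + #null).
    """
    real = np.asarray(real_metrics, dtype=float).ravel()
    null = np.asarray(null_metrics, dtype=float).ravel()
    if real.size == 0 or null.size == 0:
        raise ValueError("need non-empty real and null distributions")
    m = float(real.mean())
    p = (1.0 + float(np.sum(null >= m))) / (1.0 + null.size)
    return p, bool(m > np.percentile(null, 95))


@dataclass
class PredictionResult:
    """Outcome of one feature x target x model evaluation."""

    feature: str
    target: str
    model: str
    per_split_metric: np.ndarray
    null_metrics: np.ndarray  # (n_splits, n_perms); may be empty
    p_value: float | None
    significant: bool | None
    splits: list[SplitScheme] = field(default_factory=list)
    seed: int = 0

    @property
    def mean_metric(self) -> float:
        return float(np.mean(self.per_split_metric))


def summarize(results: Iterable[PredictionResult]) -> pd.DataFrame:
    """Per-row summary: mean, SD, median, Q1, Q3 of split metrics + p-value.

    Quantiles use linear interpolation (numpy default).
    """
    rows = []
    for r in results:
        m = np.asarray(r.per_split_metric, dtype=float)
        rows.append(
            {
                "feature": r.feature,
                "target": r.target,
                "model": r.model,
                "mean": m.mean(),
                "sd": m.std(ddof=1) if m.size > 1 else 0.0,
                "median": np.median(m),
                "q1": np.percentile(m, 25),
                "q3": np.percentile(m, 75),
                "p_value": r.p_value,
                "significant": r.significant,
            }
        )
    cols = ["feature", "target", "model", "mean", "sd", "median", "q1", "q3",
            "p_value", "significant"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_prediction(
    cohort: Cohort,
    feature: str,
    target: str,
    model: str | ModelSpec = "elastic_net",
    n_splits: int = 10,
    test_frac: float = 0.15,
    n_perms: int = 100,
    seed: int = 0,
    preprocess: bool | NuisanceRegressor = False,
    train_fraction: float = 1.0,
    feature_kwargs: Mapping | None = None,
) -> PredictionResult:
    """End-to-end evaluation of one feature/target/model combination.

    For every split the feature extractor is fit on the training subjects
    only (for GSP features this rebuilds the consensus connectome and its
    harmonics per training set) and applied to everyone; the nested-CV model
    is scored on the held-out subjects; the permutation null reruns the
    identical pipeline on reshuffled targets. ``train_fraction < 1``
    subsamples training families (scaling experiments), leaving the test
    set untouched.
    """
    from .scaling import subsample_train  # local import to avoid a cycle

    spec = _resolve_model(model)
    if preprocess:
        reg = preprocess if isinstance(preprocess, NuisanceRegressor) else NuisanceRegressor()
        cohort = cohort.with_timeseries(reg.transform(cohort.timeseries))

    table = cohort.table
    if target not in table.columns:
        raise ValueError(f"target {target!r} not in cohort table")
    y = table[target].to_numpy()
    families = table["family_id"].to_numpy()
    subject_ids = table["subject_id"].to_numpy()

    splits = make_family_splits(cohort, n_splits=n_splits,
                                test_frac=test_frac, seed=seed)
    fkw = dict(feature_kwargs or {})
    needs_refit = feature in GSP_FEATURES

    metrics = np.empty(len(splits))
    feats_per_split: list[np.ndarray] = []
    train_ids_per_split: list[np.ndarray] | None = [] if train_fraction < 1 else None
    shared_feat: np.ndarray | None = None
    for i, split in enumerate(splits):
        tr_ids = split.train_ids
        if train_fraction < 1:
            tr_ids = subsample_train(split, families, train_fraction,
                                     seed=seed).train_ids
            train_ids_per_split.append(tr_ids)
        if needs_refit or shared_feat is None:
            ext = make_extractor(feature, **fkw)
            ext.fit(cohort.subset(tr_ids))
            feat = ext.transform(cohort)
            if not needs_refit:
                shared_feat = feat
        else:
            feat = shared_feat
        feats_per_split.append(feat)
        metrics[i] = fit_evaluate(
            feat, y, split, spec, families, subject_ids=subject_ids,
            train_ids=tr_ids,
        )

    null = np.empty((len(splits), 0))
    p_value = significant = None
    if n_perms > 0:
        null = permutation_null(
            feats_per_split, y, splits, spec, families,
            n_perms=n_perms, seed=seed,
            train_ids_per_split=train_ids_per_split,
        )
        p_value, significant = significance(metrics, null)

    return PredictionResult(
        feature=feature,
        target=target,
        model=spec.name,
        per_split_metric=metrics,
        null_metrics=null,
        p_value=p_value,
        significant=significant,
        splits=splits,
        seed=seed,
    )
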