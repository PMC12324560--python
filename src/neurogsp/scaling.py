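"""Sample-size x scan-time scaling experiments.

The prediction pipeline is rerun over a grid of training-set fractions
(default 0.2..1.0 in steps of 0.2) and scan-time amounts in session units
(default 0.25, 0.5, 1, 2, 4 — the 0.25-session cell is 3.6 min of data at
1200 frames / TR 0.72 s, the full grid 57.6 min). Scan truncation always
starts at the beginning of session one and extends from there; the test
*subjects* are held constant across cells (only training families are
subsampled), while features of every subject are recomputed from the
truncated scans within a cell. Training subsets are nested across fractions
for a fixed seed, which smooths the learning curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .prediction import ModelSpec, SplitScheme, run_prediction
from .types import Cohort, ParcellatedTimeSeries

__all__ = [
    "DEFAULT_TRAIN_FRACTIONS",
    "DEFAULT_SESSION_AMOUNTS",
    "truncate_scan",
    "subsample_train",
    "ScalingGrid",
    "run_scaling",
    "heatmap_table",
    "curve_table",
]

DEFAULT_TRAIN_FRACTIONS = (0.2, 0.4, 0.6, 0.8, 1.0)
DEFAULT_SESSION_AMOUNTS = (0.25, 0.5, 1.0, 2.0, 4.0)


def truncate_scan(
    ts: ParcellatedTimeSeries, session_amount: float
) -> ParcellatedTimeSeries:
    """Keep the first ``floor(session_amount * frames_per_session)`` frames.

    ``session_amount`` is expressed in session units (0.25 = a quarter of
    one session); frames are counted from the start of session one across
    the concatenated sessions, and session boundaries are preserved so that
    per-session preprocessing still applies.
    """
    n_sessions = len(ts.session_lengths)
    if not (0 < session_amount <= n_sessions):
        raise ValueError(
            f"session_amount {session_amount} outside (0, {n_sessions}]"
        )
    frames_per_session = ts.session_lengths[0]
    keep = int(np.floor(session_amount * frames_per_session))
    if keep < 1:
        raise ValueError("session_amount keeps no frames")
    if keep >= ts.n_frames:
        return ts
    lengths: list[int] = []
    remaining = keep
    for n in ts.session_lengths:
        take = min(n, remaining)
        if take > 0:
            lengths.append(take)
        remaining -= take
        if remaining <= 0:
            break
    return ts.with_data(ts.data[:keep].copy(), session_lengths=lengths)


def subsample_train(
    split: SplitScheme,
    families: np.ndarray,
    fraction: float,
    seed: int = 0,
) -> SplitScheme:
    """Family-respecting random subset of the training set.

    Picks the prefix of a seed-shuffled family ordering whose cumulative
    subject count is closest to ``fraction * train size`` (ties toward the
    smaller set); the test set is untouched. Because the ordering depends
    only on (seed, split), subsets are nested across fractions: every
    subject kept at fraction f is kept at every f' > f.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return split
    families = np.asarray(families)
    tr = split.train_ids
    fams = pd.unique(families[tr])
    rng = np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=(11, split.split_id))
    )
    order = fams[rng.permutation(len(fams))]
    counts = np.array([np.sum(families[tr] == f) for f in order])
    cum = np.cumsum(counts)
    target = fraction * tr.size
    k = int(np.argmin(np.abs(cum - target)))  # argmin takes the first optimum
    if cum[k] == 0:
        raise ValueError("fraction too small: no family fits")
    chosen = set(order[: k + 1])
    new_train = tr[np.isin(families[tr], list(chosen))]
    return SplitScheme(
        split_id=split.split_id,
        train_ids=new_train,
        test_ids=split.test_ids,
        seed=split.seed,
    )


@dataclass
class ScalingGrid:
    """Grid definition plus the long-format results table."""

    train_fractions: Sequence[float] = DEFAULT_TRAIN_FRACTIONS
    session_amounts: Sequence[float] = DEFAULT_SESSION_AMOUNTS
    results: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if any(not (0 < f <= 1) for f in self.train_fractions):
            raise ValueError("train fractions must lie in (0, 1]")
        if any(s <= 0 for s in self.session_amounts):
            raise ValueError("session amounts must be positive")


def run_scaling(
    cohort: Cohort,
    feature: str,
    target: str,
    model: str | ModelSpec = "elastic_net",
    train_fractions: Sequence[float] = DEFAULT_TRAIN_FRACTIONS,
    session_amounts: Sequence[float] = DEFAULT_SESSION_AMOUNTS,
    n_splits: int = 10,
    test_frac: float = 0.15,
    seed: int = 0,
    preprocess: bool = False,
    feature_kwargs: Mapping | None = None,
) -> ScalingGrid:
    """Rerun the prediction pipeline on every (fraction, sessions) cell.

    Every cell uses the same split seed, so the test subjects are identical
    across cells and the (1.0, max sessions) cell reproduces the plain
    pipeline exactly. Features are recomputed from the truncated scans of
    *all* subjects within a cell (test scans are truncated too: the scan-time
    condition applies to the whole sample). Permutation nulls are skipped
    inside the grid.
    """
    grid = ScalingGrid(train_fractions=tuple(train_fractions),
                       session_amounts=tuple(session_amounts))
    n_sessions = len(cohort.timeseries[0].session_lengths)
    if max(grid.session_amounts) > n_sessions:
        raise ValueError(
            f"session amount {max(grid.session_amounts)} exceeds the "
            f"{n_sessions} available sessions"
        )
    rows = []
    test_sets: set[tuple] = set()
    for amount in grid.session_amounts:
        truncated = cohort.with_timeseries(
            [truncate_scan(ts, amount) for ts in cohort.timeseries]
        )
        for fraction in grid.train_fractions:
            try:
                res = run_prediction(
                    truncated, feature, target, model=model,
                    n_splits=n_splits, test_frac=test_frac, n_perms=0,
                    seed=seed, preprocess=preprocess,
                    train_fraction=fraction, feature_kwargs=feature_kwargs,
                )
            except Exception as exc:  # surface the failing cell
                raise RuntimeError(
                    f"scaling cell (fraction={fraction}, "
                    f"sessions={amount}) failed: {exc}"
                ) from exc
            test_sets.add(
                tuple(np.sort(np.concatenate([s.test_ids for s in res.splits])))
            )
            for s, m in zip(res.splits, res.per_split_metric):
                rows.append(
                    {
                        "feature": feature,
                        "target": target,
                        "model": res.model,
                        "train_fraction": fraction,
                        "session_amount": amount,
                        "split_id": s.split_id,
                        "metric": m,
                    }
                )
    assert len(test_sets) == 1, "test subjects must be constant across cells"
    grid.results = pd.DataFrame(rows)
    return grid


def heatmap_table(grid: ScalingGrid, stat: str = "mean") -> pd.DataFrame:
    """Fractions x session-amounts table of the mean (or sd) metric."""
    agg = {"mean": "mean", "sd": "std"}[stat]
    return grid.results.pivot_table(
        index="train_fraction", columns="session_amount", values="metric",
        aggfunc=agg,
    )


def curve_table(grid: ScalingGrid, tr: float = 0.72,
                frames_per_session: int = 1200) -> pd.DataFrame:
    """Metric vs total scan time (minutes), one row per grid cell.

    Mean metric with the +-SD band over splits, plus the scan time implied
    by the session amount.
    """
    g = grid.results.groupby(
        ["feature", "target", "model", "train_fraction", "session_amount"],
        as_index=False,
    )["metric"].agg(["mean", "std"]).reset_index(drop=True)
    g["scan_minutes"] = g["session_amount"] * frames_per_session * tr / 60.0
    return g
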