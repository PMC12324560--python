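"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the shape of a large family-structured resting-state
cohort: subjects nested in families, four resting-state sessions per subject
(1200 frames at TR = 0.72 s by default), R-region structural connectomes
whose edge probability decays with inter-region distance, BOLD series with a
controllable split of energy between low and high graph-frequency bands of
each subject's own connectome harmonics, and prediction targets generated as
noisy functions of chosen feature matrices with a known signal fraction.

All randomness flows from one master seed through named substreams
(cohort / sc / ts / targets), so each component regenerates reproducibly on
its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse.csgraph as csgraph
import scipy.spatial.distance as ssd

from . import gsp
from .features import make_extractor
from .types import Cohort, ParcellatedTimeSeries, StructuralConnectome

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "generate_cohort",
    "generate_sc",
    "generate_timeseries",
    "generate_targets",
    "make_dataset",
]

_STREAMS = {"cohort": 0, "sc": 1, "ts": 2, "targets": 3}


def substream(seed: int, name: str, *extra: int) -> np.random.Generator:
    """Named reproducible substream of a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=(_STREAMS[name], *map(int, extra)))
    )


@dataclass
class CohortSpec:
    """Shape of a synthetic cohort.

    Defaults mirror a large young-adult resting-state study: four sessions
    of 1200 frames at TR = 0.72 s over 274 regions, ages 22-37, families of
    size 1-4 with weights {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}.
    """

    n_subjects: int
    n_regions: int = 274
    n_sessions: int = 4
    frames_per_session: int = 1200
    tr: float = 0.72
    family_size_distribution: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}
    )
    age_range: tuple[float, float] = (22.0, 37.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.frames_per_session < 16:
            raise ValueError("frames_per_session must be >= 16")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_regions < 4:
            raise ValueError("n_regions must be >= 4")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        sizes = list(self.family_size_distribution)
        weights = np.array([self.family_size_distribution[s] for s in sizes], float)
        if len(sizes) == 0 or np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("family_size_distribution must be nonnegative weights")
        if any(int(s) < 1 for s in sizes):
            raise ValueError("family sizes must be >= 1")


@dataclass
class EffectSpec:
    """A target generated as a noisy function of one feature basis.

    ``signal_fraction`` is the proportion of target variance carried by the
    (standardized) linear combination of the basis features; the rest is
    Gaussian noise orthogonalized against the signal, so the realized
    fraction matches the nominal one exactly in-sample. ``spectral_band``
    restricts the random weights to harmonics below/above the graph cutoff
    (meaningful for the harmonic-indexed ``psd`` basis; ignored with a log
    message otherwise). ``binary=True`` thresholds the latent score at its
    median, giving a balanced sex-like label.
    """

    target_name: str
    feature_basis: str
    signal_fraction: float
    spectral_band: str = "broadband"
    binary: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.signal_fraction < 1):
            raise ValueError("signal_fraction must lie in [0, 1)")
        if self.spectral_band not in ("low", "high", "broadband"):
            raise ValueError("spectral_band must be low/high/broadband")


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------

def _sample_family_sizes(spec: CohortSpec, rng: np.random.Generator) -> list[int]:
    sizes = np.array(sorted(spec.family_size_distribution), dtype=int)
    weights = np.array(
        [spec.family_size_distribution[int(s)] for s in sizes], dtype=float
    )
    weights = weights / weights.sum()
    out: list[int] = []
    total = 0
    while total < spec.n_subjects:
        s = int(rng.choice(sizes, p=weights))
        s = min(s, spec.n_subjects - total)  # trim the last family to fit
        out.append(s)
        total += s
    return out


def generate_cohort(spec: CohortSpec, holdout_size: int = 0) -> pd.DataFrame:
    """Cohort table: subject_id, family_id, sex, age, holdout flag.

    Families are sampled from the spec's size distribution and together
    cover all subjects; ages are uniform on the spec's range; sex is
    balanced (exactly floor(n/2) of one label). ``holdout_size`` subjects
    are flagged ``holdout=True`` (whole families where possible), leaving
    the remainder as the main-analysis partition.
    """
    rng = substream(spec.seed, "cohort")
    fam_sizes = _sample_family_sizes(spec, rng)
    n = spec.n_subjects
    family_ids = np.concatenate(
        [np.full(s, i) for i, s in enumerate(fam_sizes)]
    )
    sex = np.array(["F"] * (n // 2) + ["M"] * (n - n // 2))
    rng.shuffle(sex)
    age = rng.uniform(*spec.age_range, size=n).round(1)

    holdout = np.zeros(n, dtype=bool)
    if holdout_size > 0:
        if holdout_size >= n:
            raise ValueError("holdout_size must be smaller than the cohort")
        remaining = holdout_size
        fam_order = rng.permutation(len(fam_sizes))
        chosen: list[int] = []
        for f in fam_order:
            if fam_sizes[f] <= remaining:
                chosen.append(f)
                remaining -= fam_sizes[f]
            if remaining == 0:
                break
        mask = np.isin(family_ids, chosen)
        if remaining > 0:
            # no family small enough is left: split one family to hit the
            # exact count (rare; logged)
            logger.warning(
                "holdout: splitting a family to reach the exact hold-out size"
            )
            leftover = np.flatnonzero(~mask)[:remaining]
            mask[leftover] = True
        holdout = mask

    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:04d}" for i in range(n)],
            "family_id": [f"fam-{f + 1:04d}" for f in family_ids],
            "sex": sex,
            "age": age,
            "holdout": holdout,
        }
    )


# ---------------------------------------------------------------------------
# structural connectomes
# ---------------------------------------------------------------------------

def _template_graph(
    spec: CohortSpec, rng: np.random.Generator, density: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Distance-dependent template adjacency + coordinates.

    Regions sit uniformly in a 140 mm box; edges are the top-k pairs by
    exp(-d / lambda) * U score (k = density * n_pairs), unioned with the
    Euclidean minimum spanning tree so the template is always connected.
    """
    r = spec.n_regions
    coords = rng.uniform(0.0, 140.0, size=(r, 3))
    dist = ssd.squareform(ssd.pdist(coords))
    lam = np.median(dist[np.triu_indices(r, 1)]) / 2.0

    iu, ju = np.triu_indices(r, k=1)
    score = np.exp(-dist[iu, ju] / lam) * rng.uniform(size=iu.size)
    k = max(int(round(density * iu.size)), r - 1)
    keep = np.zeros(iu.size, dtype=bool)
    keep[np.argsort(score)[::-1][:k]] = True

    # weights: fiber-density-like, decaying with distance
    w = np.exp(-dist[iu, ju] / lam) * rng.lognormal(mean=0.0, sigma=0.5, size=iu.size)

    # union with the MST of the distance graph for connectedness
    mst = csgraph.minimum_spanning_tree(dist).toarray()
    mst_mask = (mst + mst.T)[iu, ju] > 0
    keep |= mst_mask

    adj = np.zeros((r, r))
    adj[iu[keep], ju[keep]] = w[keep]
    adj += adj.T
    return adj, dist, coords, mst_mask


def generate_sc(
    spec: CohortSpec,
    noise_level: float = 0.1,
    density: float = 0.25,
) -> tuple[list[StructuralConnectome], pd.DataFrame]:
    """Per-subject structural connectomes around one group template.

    Subject matrices perturb the template: weights are scaled by a lognormal
    multiplicative factor of spread ``noise_level`` and non-MST edges are
    dropped independently with probability ``min(0.3 * noise_level, 0.5)``
    (minimum-spanning-tree edges always survive, keeping every subject
    connected). ``noise_level = 0`` returns exact copies of the template.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be nonnegative")
    rng = substream(spec.seed, "sc")
    template, dist, coords, mst_mask = _template_graph(spec, rng, density)
    iu, ju = np.triu_indices(spec.n_regions, k=1)
    tvec = template[iu, ju]
    drop_p = min(0.3 * noise_level, 0.5)

    out: list[StructuralConnectome] = []
    for s in range(spec.n_subjects):
        srng = substream(spec.seed, "sc", s + 1)
        vec = tvec.copy()
        if noise_level > 0:
            vec = vec * np.exp(noise_level * srng.standard_normal(iu.size))
            drop = (srng.uniform(size=iu.size) < drop_p) & ~mst_mask
            vec[drop] = 0.0
        m = np.zeros_like(template)
        m[iu, ju] = vec
        m += m.T
        out.append(
            StructuralConnectome(
                weights=m, distances=dist, subject_id=f"sub-{s + 1:04d}"
            )
        )
    coords_df = pd.DataFrame(coords, columns=["x", "y", "z"])
    coords_df.insert(0, "region", np.arange(1, spec.n_regions + 1))
    return out, coords_df


# ---------------------------------------------------------------------------
# BOLD time series
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, k: int, rho: float) -> np.ndarray:
    """k unit-variance AR(1) series of length n (columns)."""
    innov = rng.standard_normal((n, k)) * np.sqrt(max(1.0 - rho**2, 1e-12))
    x = np.empty((n, k))
    x[0] = rng.standard_normal(k)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + innov[t]
    return x


def generate_timeseries(
    sc: StructuralConnectome,
    spec: CohortSpec,
    band_energy: Mapping[str, float] | None = None,
    seed: int | None = None,
    subject_index: int = 0,
    ar_rho: float = 0.3,
    ar_jitter: float = 0.05,
    baseline_scale: float = 1.0,
    cutoff_index: int | None = None,
) -> ParcellatedTimeSeries:
    """BOLD series with a prescribed graph-spectral energy profile.

    Graph-domain coefficients over the subject's own connectome harmonics
    are AR(1) processes (temporal autocorrelation ``ar_rho`` with a small
    per-subject jitter, so fALFF varies across subjects) with random
    per-harmonic amplitudes, plus a constant offset per harmonic (regional
    baseline). Per session, the low-band (harmonic index < R//2) and
    high-band blocks are rescaled so the energy split matches ``band_energy``
    exactly; the region-space signal is the inverse GFT.
    """
    band_energy = dict(band_energy or {"low": 0.5, "high": 0.5})
    f_low = float(band_energy.get("low", 0.0))
    f_high = float(band_energy.get("high", 0.0))
    if not np.isclose(f_low + f_high, 1.0, atol=1e-8) or min(f_low, f_high) < 0:
        raise ValueError("band_energy must be nonnegative and sum to 1")
    seed = spec.seed if seed is None else seed
    rng = substream(seed, "ts", subject_index)

    spectrum = gsp.spectrum_from_connectome(sc, cutoff_index=cutoff_index)
    r = spectrum.n_regions
    c = spectrum.cutoff_index
    rho = float(np.clip(ar_rho + ar_jitter * rng.standard_normal(), 0.0, 0.95))

    sigma = rng.lognormal(mean=0.0, sigma=0.4, size=r)     # per-harmonic amplitude
    beta = rng.standard_normal(r)                          # constant offsets
    band_mask = np.where(
        np.arange(r) < c, 1.0 if f_low > 0 else 0.0, 1.0 if f_high > 0 else 0.0
    )

    n_frames = spec.frames_per_session
    sessions = []
    for _ in range(spec.n_sessions):
        # fluctuating part: per-session demeaned, then band-scaled exactly
        coeff = _ar1(rng, n_frames, r, rho) * sigma[None, :]
        coeff -= coeff.mean(axis=0, keepdims=True)
        for sl, frac in ((slice(0, c), f_low), (slice(c, r), f_high)):
            block = coeff[:, sl]
            energy = float(np.sum(block**2))
            if frac == 0.0:
                coeff[:, sl] = 0.0
            elif energy > 0:
                coeff[:, sl] = block * np.sqrt(frac / energy)
        # constant regional baseline, restricted to the active bands so the
        # raw signal carries no energy in a zeroed band
        frame_scale = 1.0 / np.sqrt(n_frames * r)  # rms of the unit-energy part
        coeff = coeff + (baseline_scale * frame_scale * beta * band_mask)[None, :]
        sessions.append(gsp.igft(coeff, spectrum))
    data = np.vstack(sessions)
    return ParcellatedTimeSeries(
        data=data,
        tr=spec.tr,
        session_lengths=[spec.frames_per_session] * spec.n_sessions,
        subject_id=sc.subject_id or f"sub-{subject_index + 1:04d}",
    )


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------

def _zscore_columns(f: np.ndarray) -> np.ndarray:
    mu = f.mean(axis=0, keepdims=True)
    sd = f.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (f - mu) / sd


def generate_targets(
    cohort: pd.DataFrame,
    features: Mapping[str, np.ndarray],
    effects: Sequence[EffectSpec],
    seed: int = 0,
) -> pd.DataFrame:
    """Append target columns with known feature-linked effect sizes.

    For each effect, a weight vector drawn once per seed combines the
    (column-standardized) basis features into a latent score; the target is
    sqrt(s) * latent + sqrt(1-s) * noise with the noise residualized against
    the latent, so the in-sample signal fraction equals ``s`` exactly.
    Binary targets threshold the latent+noise score at its median.
    """
    out = cohort.copy()
    n = len(cohort)
    for k, eff in enumerate(effects):
        if eff.feature_basis not in features:
            raise ValueError(
                f"feature basis {eff.feature_basis!r} not in the provided "
                f"features {sorted(features)}"
            )
        rng = substream(seed, "targets", k)
        f = _zscore_columns(np.asarray(features[eff.feature_basis], dtype=float))
        if f.shape[0] != n:
            raise ValueError("feature rows must match cohort size")
        w = rng.standard_normal(f.shape[1])
        if eff.spectral_band != "broadband":
            if eff.feature_basis == "psd":
                cut = f.shape[1] // 2
                mask = np.zeros(f.shape[1], dtype=bool)
                if eff.spectral_band == "low":
                    mask[:cut] = True
                else:
                    mask[cut:] = True
                w = np.where(mask, w, 0.0)
            else:
                logger.info(
                    "spectral_band=%s ignored for non-harmonic basis %s",
                    eff.spectral_band, eff.feature_basis,
                )
        latent = f @ w
        lsd = latent.std()
        if lsd == 0:
            latent = rng.standard_normal(n)
            lsd = latent.std()
        latent = (latent - latent.mean()) / lsd

        noise = rng.standard_normal(n)
        if n > 1:
            noise = noise - latent * (latent @ noise) / (latent @ latent)
        nsd = noise.std()
        noise = noise / (nsd if nsd > 0 else 1.0)

        s = eff.signal_fraction
        y = np.sqrt(s) * latent + np.sqrt(1.0 - s) * noise
        if eff.binary:
            out[eff.target_name] = (y > np.median(y)).astype(int)
        else:
            out[eff.target_name] = y
    return out


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

def make_dataset(
    spec: CohortSpec,
    effects: Sequence[EffectSpec] = (),
    band_energy: Mapping[str, float] | None = None,
    noise_level: float = 0.1,
    holdout_size: int = 0,
    **ts_kwargs,
) -> Cohort:
    """Generate a complete cohort: table, connectomes, series, targets.

    Features needed as target bases are computed on the full cohort with the
    default extractors (GSP bases use a consensus spectrum over everyone —
    this is generation-time plumbing, not analysis).
    """
    table = generate_cohort(spec, holdout_size=holdout_size)
    connectomes, coords = generate_sc(spec, noise_level=noise_level)
    timeseries = [
        generate_timeseries(
            sc, spec, band_energy=band_energy, subject_index=i, **ts_kwargs
        )
        for i, sc in enumerate(connectomes)
    ]
    cohort = Cohort(
        table=table,
        timeseries=timeseries,
        connectomes=connectomes,
        distances=connectomes[0].distances,
        coords=coords,
    )
    if effects:
        needed = {e.feature_basis for e in effects}
        feats: dict[str, np.ndarray] = {}
        for name in needed:
            ext = make_extractor(name)
            ext.fit(cohort)
            feats[name] = ext.transform(cohort)
        cohort.table = generate_targets(
            cohort.table, feats, effects, seed=spec.seed
        )
    return cohort
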