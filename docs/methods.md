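# Methods

## Scope and model

`neurogsp` implements a brain-behavior prediction workflow for parcellated
resting-state fMRI in family-structured cohorts. The scientific object of
study is the comparison of nine per-subject feature sets — four regional
statistics (mean, SD, MSSD, fALFF), plain functional connectivity, and four
graph-signal-processing (GSP) features defined over a consensus structural
connectome (graph PSD, SDI, coupled and decoupled FC) — as predictors of
continuous and binary phenotypes, together with how prediction accuracy
scales with the number of training subjects and the amount of scan time.

The pipeline starts at the parcellated level (time x region matrices); no
volume-space processing, tractography, or parcellation of images is
performed.

## Preprocessing

Per subject: the first 6 frames of the first session are discarded
(scanner equilibration; a per-session variant is available), then each
session is cleaned by a single least-squares projection onto
`[intercept, linear trend, confounds, backward-difference confound
derivatives, DCT high-pass basis]`. The discrete-cosine columns span all
periods longer than `1 / f_hp` with `f_hp = 0.01` Hz by default. A single
joint regression is used instead of sequential detrend → regress → filter
because sequential orthogonalization can reintroduce removed variance; a
joint projection is order-free and leaves residuals exactly orthogonal to
every regressor (this also gives the idempotence and energy-contraction
properties the tests assert). Sessions are separate acquisitions and are
processed independently, then re-concatenated. Rank-deficient designs fall
back to the least-norm solution with a warning.

## Features

All features are computed per subject on the concatenated multi-session
series; the scan-time experiments control how much data enters by
truncation, not by changing the estimators.

- **mean, sd** — temporal mean and sample SD (ddof = 1) per region.
- **mssd** — mean squared successive difference,
  `MSSD = (1/(N-1)) Σ (x_{i+1} - x_i)^2`, the standard BOLD-variability
  statistic; shift-invariant, quadratic under rescaling.
- **falff** — fraction of FFT *amplitude* in 0.01–0.08 Hz over all
  positive-frequency amplitude, on the demeaned series. The original fALFF
  definition sums amplitudes (square-root power); a `power` mode squares
  them. Computed on concatenated sessions (per-session averaging would be a
  defensible alternative; concatenation is the package convention).
  Zero-variance regions yield 0 rather than an error so degenerate
  synthetic cases cannot abort a cohort run; the same convention (sd = 0,
  mssd = 0) applies to the other regional features.
- **fc** — Pearson correlation matrix, vectorized as the strictly upper
  triangle in row-major order (`R(R-1)/2` entries; 37401 at R = 274). This
  edge order is the single canonical convention across the package. No
  Fisher z-transform is applied before modeling.
- **GSP features** — see below.

## Graph signal processing

**Consensus connectome.** A group structural graph is built from the
training subjects' connectomes: candidate edges are partitioned into
`n_bins = 50` equal-count inter-region-distance bins; within each bin the
edges most consistently present across subjects are kept, with the kept
count matching the average per-subject edge count of that bin (ties broken
by mean weight, then edge index). Distance-binned thresholding prevents the
well-known bias of plain consensus masks toward short connections. The
binary mask is multiplied elementwise with the across-subject mean weight
matrix, preserving both the edge-length distribution and the weights. The
bin count is a configuration default; results are insensitive to it at the
densities the generator produces.

**Harmonics.** `L = I - D^{-1/2} A D^{-1/2}` (isolated nodes get an
identity row, keeping L symmetric PSD); its eigenvectors, ordered by
ascending eigenvalue (graph frequency, in [0, 2]), are the connectome
harmonics. Eigenvector signs are fixed deterministically (largest-magnitude
component made positive, first index on ties) so repeated runs agree
bitwise.

**GFT, PSD, filtering, SDI.** The graph Fourier transform projects each
frame onto the harmonics. The graph PSD of a subject is the temporal l2
norm of each graph coefficient series of the demeaned signal (`sqrt(Σ_t
x̂_k(t)^2)`); a mean-square mode exists for users who prefer energy per
frame — the l2 convention is the default because it matches the norm-based
SDI. Ideal low/high-pass filters zero the coefficients above/below the
cutoff index `c = floor(R/2)` (137 at R = 274), counting from the lowest
graph frequency; which side is inclusive is a convention, fixed and
configurable. Coupled/decoupled FC are Pearson FC of the low/high-pass
signals; a band with numerically vanishing content (relative SD below
1e-10 of the unfiltered scale) yields zero correlations rather than noise.
SDI is the per-region ratio of high- to low-pass temporal norms, reported
raw (a log2 option exists for compatibility with the original SDI
literature); a vanishing denominator maps to a configured maximum (1e6)
with a logged warning.

**Leakage.** The consensus graph and spectrum are fitted attributes of the
GSP extractors: `fit(cohort_subset)` sees training subjects only, so
cross-validation over extractors automatically rebuilds the consensus per
training set. A recomputation test asserts that permuting test subjects'
connectomes never changes the training consensus.

## Prediction protocol

Ten random train/test splits with whole families on one side and a test
fraction of 15% of the available subjects (family indivisibility makes
realized sizes vary; a greedy shuffled-family assignment gets as close as
possible). Within each training set, features are standardized (scaler fit
on training subjects only) and hyperparameters selected by 3-fold
family-grouped inner CV; the refit model is scored on the held-out
subjects. Models: elastic net (alpha log-grid 1e-3..1e3 x l1_ratio {0.1,
0.5, 0.9}), linear kernel ridge (alpha log-grid), elastic-net logistic
regression and linear SVM (C log-grid) for binary targets. A compact grid
(3 strengths, one mixing ratio) is provided for simulation studies. Inner
folds are family-grouped too — consistent leakage prevention even though
grouping matters less within a training set. Continuous targets are
standardized on the training set and predictions mapped back before
scoring, which stabilizes the grids without affecting the metric.

R² is `1 - SSE/SST` with SST around the *test-set* mean (the scikit-learn
convention); it can be negative on held-out data. Classification uses plain
accuracy (classes are balanced by construction in the generator).

**Permutation significance.** Targets are reshuffled uniformly across all
subjects 100 times per split (split membership fixed) and the identical
pipeline rerun, giving a 10 x 100 = 1000-value null. Features do not
depend on the targets, so each split's precomputed feature matrix is
reused — mathematically identical to recomputing it. A feature is
significant when the mean of its real metric distribution strictly exceeds
the 95th percentile of the pooled null; the reported p-value is
`(1 + #{null >= mean}) / (1 + #null)`. This mean-vs-percentile rule is
conservative under the null (the mean of ten draws concentrates), which
the type-I simulations confirm.

## Scaling experiments

Grid: training fractions 0.2–1.0 in steps of 0.2 x scan amounts 0.25, 0.5,
1, 2, 4 sessions (0.25 sessions = 300 frames = 3.6 min at TR 0.72 s).
Truncation always keeps a prefix starting at session one, respecting
session boundaries, with floor rounding (never exceeding acquired data),
and applies to **both** training and test subjects within a cell — the
scan-time condition is a property of the dataset, not of the training set
alone. Training families are subsampled with nested subsets across
fractions (prefix of a per-split shuffled family order), which reduces
curve variance; the test subjects are identical in every cell, and the
(1.0, all sessions) cell reproduces the plain pipeline bitwise. The
consensus connectome is recomputed per cell and per training set (strict
leakage rule).

## Synthetic cohorts

The generator produces the data structure the analysis assumes, not a
biophysical simulation:

- **Cohort table** — families sampled with size weights {1: 0.4, 2: 0.3,
  3: 0.2, 4: 0.1} (multi-member families make grouped splitting
  non-trivial, mirroring a twin/sibling cohort without claiming its exact
  distribution), balanced sex, ages uniform on 22–37. An optional hold-out
  flag marks a subject subset (whole families where possible) — e.g. 145
  of 979 subjects, leaving 834 for the main analysis.
- **Connectomes** — regions placed uniformly in a 140 mm box; template
  edges are the top-density pairs by `exp(-d/λ) x U` score (λ = half the
  median distance), unioned with the Euclidean MST so every graph is
  connected; weights decay with distance (lognormal x exponential).
  Subjects perturb the template multiplicatively (spread = `noise_level`)
  and drop non-MST edges with probability `0.3 x noise_level`; zero noise
  copies the template exactly. The distance-dependence gives the consensus
  procedure a real length confound to correct.
- **BOLD series** — graph-domain coefficients over the subject's own
  harmonics are AR(1) processes (ρ = 0.3 with a small per-subject jitter,
  so the temporal spectrum — and hence fALFF — carries inter-subject
  signal) with lognormal per-harmonic amplitudes; per session the demeaned
  low/high coefficient blocks are rescaled so the graph-band energy split
  matches the requested proportions *exactly* on the demeaned signal, and
  a constant regional baseline (restricted to the active bands) supplies
  mean-feature variation. The AR structure lives in the coefficients
  rather than being added in region space: the region signal is a fixed
  linear mix of AR(1) processes (temporally equivalent), and adding
  independent region-space noise afterwards would destroy the exact band
  placement the tests rely on.
- **Targets** — a weight vector drawn once per seed combines the
  column-standardized basis features into a latent score; the target is
  `sqrt(s) x latent + sqrt(1-s) x noise` with the noise residualized
  against the latent, so the in-sample signal fraction equals the nominal
  `s` exactly. Binary targets threshold at the median (balanced classes).
  Factor-score-like targets are standardized Gaussians; no distributional
  claims beyond that are made.

All randomness flows from one master seed through named substreams
(cohort / sc / ts / targets), so any component regenerates on its own.

**What passing tests show.** The generator reproduces the *statistical
structure* the pipeline must respect: family clustering, distance-dependent
graphs, controllable graph-band energy, known effect sizes. It does not
emulate head motion, physiological noise, hemodynamics, spatial
autocorrelation of real parcellations, or heavy-tailed phenotypes, so
passing tests certify the machinery (correctness, leakage control,
calibration), not expected effect sizes on real data.

## Simulation study sizes

The validation studies use deliberately compact conditions chosen once:

- Null/size study: 20 cohorts of n = 60 (R = 20, T = 120), 10 splits x 50
  reshuffles, compact elastic-net grid; empirical rejection rate compared
  to the 10% bound at nominal 5%.
- Power study: 20 cohorts of n = 800, signal fraction 0.3 on FC, kernel
  ridge with the compact alpha grid, 5 splits x 25 reshuffles. KRR is the
  natural estimator for a dense edge-weight signal and is the model this
  feature is paired with in the headline analysis.
- Recovery: cross-validated ridge on the generating basis at n = 800
  (5-fold CV averages out split noise); mean over three cohorts compared
  to the nominal fraction.
- Scaling: 20 cohorts of n = 150 with 4 x 60-frame sessions comparing the
  (1.0, 4) and (0.2, 0.25) cells.

## Numerical choices and edge cases

- Eigendecomposition via `scipy.linalg.eigh` with symmetrization and the
  deterministic sign convention above.
- Degenerate inputs: zero-variance regions (FC/fALFF), vanishing low-pass
  norms (SDI), empty DCT bases (very short sessions), rank-deficient
  nuisance designs, all-zero adjacency (error), single-subject consensus
  (identity) are all defined behaviours with tests.
- Ties in consensus ranking broken by (frequency, mean weight, edge index);
  in the family-split greedy assignment, a family is added when it brings
  the test count weakly closer to the target.
- Quantiles in summaries use linear interpolation (numpy default).

## Known limitations

- The consensus kept-count rule uses the group-mean density per distance
  bin; other quantiles are plausible readings of "preserving the edge
  distribution".
- The graph-PSD normalization ("l2 over time" vs mean-square) is a
  documented convention; both modes ship.
- Permutations ignore family structure (targets reshuffled uniformly);
  exchangeability is only approximate in related samples.
- The generator's effect sizes are free parameters; nothing links them to
  empirical heritabilities or behavioral reliabilities.
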