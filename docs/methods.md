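# Methods

## The generative model

The synthetic generator produces multi-subject, multi-session, multi-state
parcel-level BOLD data with planted structure at every level a downstream
stage estimates.

**Covariance.** The group target is a block correlation matrix: parcels are
assigned to `n_networks` contiguous, near-equal blocks; entries are
`within_network_r` (default 0.4) inside a block and `between_network_r`
(default 0.08) elsewhere, with a unit diagonal. These defaults are typical
of cleaned parcel-level resting FC, where within-network correlations sit
around 0.3–0.5 and between-network correlations near zero. Each subject's
covariance adds independent N(0, `subject_edge_sd`²) perturbations (default
SD 0.05) to the upper triangle, symmetrized, then projected back to a valid
correlation matrix by eigenvalue clipping at 1e-6 and rescaling to a unit
diagonal — the simplest reproducible positive-definite repair. A target
matrix that is not positive definite (e.g. a too-negative between-network
correlation) is rejected with the offending eigenvalue.

**Time courses.** A run of `T` frames is
`mean_profile + sd_profile ⊙ (x Lᵀ)` where `L` is the Cholesky factor of the
subject covariance and `x` is unit-variance AR(1) noise
(`x_t = φ x_{t−1} + √(1−φ²) z_t`, default φ = 0.4). The AR(1) term gives the
series realistic temporal autocorrelation that survives band-pass
filtering; the marginal per-parcel SD stays equal to `sd_profile`. Per-parcel
mean and SD profiles default to linear ramps over 600–1000 a.u. and
5–30 a.u. respectively — order-of-magnitude-plausible free parameters, not
estimates from any real dataset (no published per-parcel distribution was
available to copy).

**Task-evoked component.** Each task state has an event schedule and
per-condition FIR amplitude profiles (defaults: a smooth unimodal bump
peaking at 8 a.u. over the condition's bins; sustained/cue regressors at a
quarter of that). The evoked series is the FIR design matrix times those
amplitudes, added *only* to the engaged parcels (by default the parcels of
planted network 1 for motor, 2 for language, 3 for memory) — so variance
added outside the engaged set is exactly zero, and the evoked signal is
reproducible across sessions, which is what lets task states raise
split-half reliability locally. Amplitudes are specified per bin directly;
no hemodynamic shape is assumed anywhere.

**Schedules.** Motor runs hold two 15.4 s blocks of each of five movement
conditions in shuffled order; language runs hold two blocks each of a
coherence and a verbal task (30 trials apiece at 3.3 s spacing, flanked by
2.2 s cues and a 121 s sustained regressor, 44 s fixations between blocks);
memory runs present 24 stimuli of one type (face/scene/word by run index)
three times each with ISIs drawn uniformly from 0.5–4.9 s — the jitter
distribution is a documented choice, as only its range is conventionally
stated. Default run lengths (rest 818 frames ≈ 30 min at TR 2.2 s; motor
112; language 288; memory 150) were chosen to fit these schedules, since
published per-run task totals for this kind of design do not reconcile
exactly with the block structure; the block structure wins. Session
structure defaults to 1 rest, 2 motor, 2 language and 3 memory runs.

**Motion.** Framewise displacement is `|N(0.05, 0.02)|` mm baseline jitter
plus spikes of `U(0.25, 1.0)` mm with per-frame probability 0.05, giving a
censoring rate at the 0.20 mm threshold comparable to a compliant adult.
The FD trace is encoded as alternating-sign x-translation steps, so
recomputing Power-style FD from the six written motion parameters recovers
the planted trace exactly — a deliberate self-consistency hook for tests.

**Determinism.** Every run's RNG seed derives from
(dataset seed, subject, session, state, run) through `SeedSequence`, so the
same specification reproduces every file bit-identically and any single run
can be regenerated in isolation.

## Preprocessing choices

- FD uses the Power convention: sum of absolute frame-to-frame differences
  of three translations plus three rotations converted to arc length at a
  50 mm head radius; FD of the first frame is 0.
- Censoring is logical (a boolean mask) until frames are extracted, and it
  is idempotent.
- Cleaning regresses `[1, t, t²]` plus confounds by OLS *on retained frames
  only* and removes the fitted trend from the full grid; censored frames of
  the residual are then linearly interpolated before the zero-phase
  band-pass so spike discontinuities do not ring through the filter, and
  censored frames are dropped again for every downstream statistic.
- The band-pass is a forward–backward Butterworth (SOS), order 3 per
  direction. Order 3 rather than 2 keeps in-band power essentially intact
  (≈ 97% at 0.05 Hz for the 0.01–0.08 Hz band) while attenuating 0.2 Hz
  power by > 10⁵; an order-2 design leaks ~10% of in-band power, which
  distorts tSD comparisons.
- With no band-pass the cleaning step is an orthogonal projection (applying
  it twice equals applying it once); this is tested.
- Global signal regression appends the all-unit mean of the raw series as
  one confound column and is on by default.
- Volume matching truncates every (subject, session, state) to the global
  minimum retained total of the reference state (motor by default), keeping
  the earliest retained frames; which frames to keep after matching is a
  choice, and "earliest" is the reproducible one.
- The pipeline order is clean-then-parcellate; the two commute only when
  confounds are global, so the order is fixed and documented.

## Reliability statistics

- Connectomes are Pearson correlations of per-run mean-centered,
  concatenated retained frames; the diagonal is stored as 1 and excluded
  from all statistics; zero-variance units become NaN rows/columns (logged),
  never silent zeros.
- FC-TRC correlates raw r values across a connectivity row — no Fisher
  transformation, since the statistic is defined as a spatial correlation of
  connectomes as they stand.
- ICC(2,1) is estimated from two-way ANOVA mean squares; negative estimates
  are reported as computed and flagged (truncation is available but off);
  variance components are truncated at zero. A zero-variance table returns
  a missing value with a reason.
- Band edges: the conventional printed bands (0–0.4, 0.4–0.59, 0.6–0.74,
  ≥ 0.75) leave the intervals (0.59, 0.6) and (0.74, 0.75) unassigned; the
  implementation closes them deterministically as poor (−∞, 0.4],
  fair (0.4, 0.6), good [0.6, 0.75), excellent [0.75, ∞).
- Edge ICCs are computed over the upper triangle and aggregated to parcels
  as the mean over each parcel's incident edges — the vectorization and
  aggregation conventions are assumptions, flagged as such.

## Task GLMs

FIR designs are accumulated on a 0.1 s microtime grid (each event adds an
indicator to bin *b* over `[onset + b·w, onset + (b+1)·w)`), then box-car
averaged to the frame grid, so bins narrower than the frame interval
contribute fractional coverage; the convention was validated against a
1 ms-grid oracle. Censored frames are deleted from the OLS fit and set to
NaN in the residuals. Condition PEs are uniform `1/n_bins` averages of the
bin betas; aggregation up the hierarchy (run → session → subject → group,
then mean over conditions for a task-level map) is unweighted fixed-effects
averaging — PE magnitudes are what feeds the attribution model, so
mixed-effects inference at the group level is out of scope. Incorrect
behavioral responses are not modeled or excluded.

## Network assignment

Density thresholding keeps the `⌈d·E⌉` largest-weight upper-triangle edges
(signed value, not magnitude), with ties at the cutoff broken by lexical
(i, j) order; thresholds are nested across densities by construction. The
density grid is {2, 3, 4, 5}% — integer percents over the conventional 2–5%
range. The default community algorithm is igraph's Infomap (two-level map
equation, 1000 trials, seeded RNG); a Leiden modularity optimizer is the
pluggable deterministic alternative, and the consensus procedure is
algorithm-agnostic. Consensus follows the Lancichinetti–Fortunato loop:
co-assignment probability matrix → threshold at 0.5 (their default; the
parameter is exposed) → re-cluster → repeat until all partitions agree, up
to 20 iterations (a non-converged result is returned flagged). Communities
beyond the expected maximum (17 by default) are dissolved into the modal
retained network among their spatial neighbors; a parcel with no such
neighbor joins the globally largest network, logged.

## Attribution statistics

Parcel-wise OLS reports slope, R², an uncorrected two-sided p (as is
conventional for these maps; a Benjamini–Hochberg option exists but is off
by default), and the standardized beta, which in simple regression equals
the correlation (so β² = R², tested to 1e-12). For tSNR-style relationships
that are visibly nonlinear, a Spearman monotone-trend diagnostic is provided
as a programmatic stand-in for visual inspection — an addition, flagged as
such. The mixed model is fitted per parcel (one model per parcel, subjects ×
states as observations) with a subject random intercept by REML; PEs are
zeroed for rest rows first, then all predictors are standardized globally
across the fitting table (the intercept absorbs the induced shift). Fits at
the boundary (zero between-subject variance) fall back through a second
optimizer to a fixed-effects-only fit with zero random-intercept variance,
flagged singular.

## Problem sizes

The default specification mirrors the emulated study design (9 subjects ×
10 sessions, TR 2.2 s, the run counts above) with 170 parcels in 17
networks as a desk-scale stand-in for a 1000-parcel atlas. The recovery
experiments in `fcreliab.experiments` (used by both the test suite and
`scripts/acceptance.py`) run at:

- ICC recovery: 20 subjects × 2 halves × 500 edges per planted ratio
  ρ ∈ {0.2, 0.5, 0.8};
- FC-TRC vs scan length: 6 subjects, 60 parcels, two 4000-frame sessions,
  evaluated at 250 / 1000 / 4000 retained frames;
- task engagement and task regression: 9 subjects × 4 sessions, 60 parcels,
  rest + motor with the full censor/clean/match/split-half chain;
- mixed-model recovery: 9 subjects × 4 states × 12 parcels with planted
  β_tSD = 0.3, subject-intercept SD 0.1, noise SD 0.05;
- consensus recovery: 9 subjects, 170 parcels / 17 networks, 600-frame rest
  runs, densities 2–5%, 100 detection trials per density.

## What the synthetic data does and does not show

The generator plants exactly the structures the pipeline estimates, so
passing tests demonstrate that the implementation recovers what it claims
to recover — correlation structure, variance components, engaged-parcel
locality, evoked-signal removal, community structure — under Gaussian AR(1)
noise. It does not emulate physiological noise spectra, spatial
autocorrelation within parcels, susceptibility dropout, distance-dependent
motion artifacts, or session-level covariance drift; absolute levels of
tMean/tSNR are in arbitrary units. Quantitative results on real data (e.g.
specific β or R² values between signal maps and reliability) are therefore
out of reach by design: the package reproduces the *procedures* and their
qualitative signatures, not dataset-specific numbers.

## Known limitations

- Dense (grayordinate-level) analyses are supported by the same code paths
  but the default examples operate at parcel level; the 91,282-unit dense
  space is exercised only through I/O metadata.
- The >0.1 Hz phase-encode-direction motion filter used by some pipelines
  is not emulated (it requires raw motion spectra).
- Only ICC(2,1) is implemented; fingerprinting-style identification and
  other ICC variants are out of scope.
- Network names are a manual mapping (synthetic networks are numbered);
  automated matching to canonical network names is not attempted.
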