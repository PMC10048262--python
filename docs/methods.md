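# Methods

`libsquant` implements a complete chemometric workflow for quantifying
heavy metals (Cd, Cu, Pb) in plant material from laser-induced breakdown
spectroscopy (LIBS): a synthetic spectrum generator with known ground
truth, spectral preprocessing, a from-scratch partial least squares
engine, three wavelength-selection algorithms, three regression models,
and an evaluation grid that scores every (element, model, selector)
combination on disjoint calibration / validation / prediction subsets.

## The synthetic study

No public LIBS dataset of metal-spiked *Fritillaria* pellets exists, so
the package ships a generator whose defaults define the study conditions
used throughout the test suite.

**Concentration design.** 288 samples in 8 dose groups of 36 (a control
group plus seven treatments), with 12 plant-variety labels assigned
cyclically. Per group and element, concentrations are drawn from a normal
distribution with the design's group mean and standard deviation
(mg kg⁻¹), clipped at zero. Clipping rather than rejection sampling is
deliberate: at the design's mean-to-sd ratios the induced bias is
negligible (the test suite checks group means against the analytic
zero-truncated-normal expectation), and the draw stays a one-liner.
Group means per element span roughly 0.3–215 mg kg⁻¹ and co-increase
across groups, so the three analytes are strongly correlated between
groups — exactly the confound a per-element wavelength selector has to
cope with — while within-group variation is independent per element.

**Spectra.** The wavelength axis is 200–1000 nm at 0.5 nm (1601
channels); real spectrometer resolution for this kind of instrument is
not published, so the axis is a declared desk-scale choice, not an
inference. A noise-free spectrum is

```
I(λ) = B + Σ_lines s_e · c_e · strength · G(λ; λ0, σ) + Σ_matrix a_m · G(λ; λ_m, σ)
```

with `B = 100` (flat continuum), unit-area Gaussian profiles of width
σ = 0.3 nm, analyte lines at the library positions (Cd 214.44, 226.50,
441.56, 467.90, 573.80, 643.85 nm; Cu 324.09, 324.79 nm; Pb 280.00,
404.00, 405.70 nm), and six matrix decoy lines (Mg, Ca, Na, Hα, K) whose
amplitudes do not depend on the analyte dose. The Cu doublet overlaps at
σ = 0.3 nm, reproducing the within-element channel covariance that makes
variable selection non-trivial.

The sensitivity default is `s_e = 0.04` intensity-area per mg kg⁻¹ for
all three elements. This places analyte peaks at a few percent of the
continuum — the trace regime, where per-channel noise genuinely limits
single-channel calibration and pooling several lines pays off. It also
reproduces the error scale reported for LIBS heavy-metal quantification
in herbs (prediction RMSE of order 10 mg kg⁻¹ over 0–250 mg kg⁻¹
ranges); an earlier draft with peaks far above the continuum produced
errors an order of magnitude smaller than anything published and made
every selector trivially good, which defeats the point of the study.

**Noise and shot averaging.** Each single-shot spectrum is
`I(λ)·(1 + ε(λ)) + δ(λ)` clipped at zero, with per-channel multiplicative
shot noise ε ~ N(0, 0.1) and additive detector noise δ ~ N(0, 2). The
multiplicative term is per-channel, not a per-shot scalar: a scalar
factor would be cancelled exactly by area normalization, whereas real
point-to-point plasma fluctuations are only *reduced* by it. Every
sample's spectrum is the average of 80 shots (emulating a 4×4 crater
array with 5 accumulations), so the effective noise floor is
σ/√80 ≈ 1.1% multiplicative and 0.22 additive. The generator contains no
per-sample (pellet-level) noise term, so per-channel variance scales
exactly as 1/n_shots — a property the suite verifies — which means
passing tests say nothing about matrix effects or ablation heterogeneity
in real pellets.

**What the generator does not emulate.** No plasma physics
(Saha–Boltzmann populations, self-absorption), no baseline drift or
spectrometer stitching, no inter-element spectral interference beyond
what overlapping Gaussians produce. Results on this generator
demonstrate algorithmic correctness and the relative value of wavelength
selection under trace-regime noise; they are not a claim about any
specific instrument.

## Preprocessing

Spectra are area-normalized: each row is divided by its trapezoidal
integral over the wavelength axis (robust to axis-step changes, unlike a
plain channel sum). Normalization uses no training-set statistics, so it
can precede splitting without leakage, and it is idempotent and
scale-invariant by construction.

Samples are split 60 / 28 / 12% into calibration, validation and
prediction sets. Subset totals follow largest-remainder apportionment
(288 → 173/81/34). By default the split is stratified by dose group:
per-group cell counts are a controlled rounding of the group quotas
(floors plus greedy largest-remainder allocation under the fixed subset
totals), so the extreme concentration groups appear in all three subsets.
The validation set is purely reportorial — no model choice consults it.

## PLS engine

Single-response NIPALS with mean centering and no column autoscaling
(channels share intensity units; autoscaling would inflate empty
channels). For one response the weight step is closed-form (w ∝ X'y),
so each component costs two matrix–vector products plus a rank-one
deflation. P'W is unit upper triangular, so the rotation
R = W(P'W)⁻¹ yields the k-component coefficient vector as a prefix
contraction — one fit at A_max provides predictions for every smaller
count, which makes RMSECV over component counts cheap. Degenerate
handling: zero-variance columns get zero weight naturally; the fit stops
early (recorded) when the deflated covariance is numerically exhausted
(relative tolerance 1e-12), and fails loudly naming the columns only if
X carries no signal at all. RMSECV uses K folds (default 5) shared
across component counts; the best count is the smallest minimizer
(parsimony tie-break).

## Wavelength selectors

All three selectors see calibration rows only — selection is part of
model building, and letting it peek at validation or prediction rows
would leak. All three rank channels by |b| from a PLS fit at the
RMSECV-optimal component count, computed once per selector call. This
ranking depth matters: past the CV optimum, extra components chase
residual noise through low-variance channels whose original-scale
coefficients explode, and the ranking collapses onto empty background
channels.

**CARS** (competitive adaptive reweighted sampling), N = 50 runs. Per
run: fit PLS on a Monte-Carlo 80% row subsample restricted to surviving
channels; enforce the exponentially decreasing retention schedule
rᵢ = a·e^(−k·i) with a = (p/2)^(1/(N−1)), k = ln(p/2)/(N−1) (so r₁ = 1
and r_N = 2/p) by keeping the top ⌈rᵢ·p⌉ channels by |b|; then
adaptively reweight by drawing ⌈rᵢ·p⌉ channels with replacement with
probability ∝ |b| and keeping the unique hits; score the survivors by
5-fold RMSECV (one fold partition shared across all runs, minimized over
feasible component counts). The subset with the lowest RMSECV wins.
Because unique-of-weighted-draws shrinks faster than the schedule, the
survivor count typically reaches 2 before run 50; the schedule is then
truncated and logged, which only removes the flat tail of the trace.

**Random frog**, N = 1000 iterations. A subset chain starts at Q₀ = p/10
channels; each iteration proposes a candidate of size
Q* = |round(N(Q, 0.3·Q))| (at least 1) by dropping the bottom-ranked
inside channels or adding the top-ranked outside channels, accepts it if
its RMSECV does not exceed the current one and otherwise with
probability 0.1·RMSECV(cur)/RMSECV(cand), and counts N_j, the number of
iterations channel j sits in the retained subset. Selection
probabilities are P_j = N_j/N. The final subset is the top-k by P_j with
k ∈ {5, 10, …, min(p, 200)} minimizing RMSECV (smallest k on ties); a
plain probability threshold is available as a config switch.

**UVE** (uninformative variable elimination). The calibration matrix is
augmented with p noise columns (uniform, amplitude 1e-10 — the amplitude
is irrelevant because the criterion is scale-free, which the suite
checks); PLS coefficients are jackknifed leave-one-out, and each column
is scored by the stability c_j = mean(b_j)/sd(b_j) across replicates.
Real channels are kept when |c_j| exceeds the 99th percentile of the
noise-block |c| (the maximum is too unstable with p noise columns). A
zero coefficient sd maps to signed infinity and is logged.

Determinism: every selector is a pure function of (X, y, config, seed);
seeds are explicit arguments and no global random state is touched.
Exact column-permutation equivariance holds for UVE and is tested; for
CARS and random frog the seeded positional draws (initial subset,
resampling) act on column positions, so reordering columns changes which
variables the same random stream touches — their guaranteed invariant is
determinism, not equivariance.

## Regression models

A uniform fit/predict contract over three regressors, each carrying the
channel mask it was trained on:

* **PLSR** — the in-package engine; component count fixed or chosen by
  RMSECV ("auto", A ≤ 15, 5 folds).
* **SVR** — RBF kernel, C = 10, ε = 0.1, γ = 'scale' (these
  hyperparameters are design defaults, exposed in config). Channels are
  standardized for the kernel and the response standardized for ε; both
  transforms are undone on output. Without channel scaling, kernel
  distances on unit-area spectra are dominated by arbitrary intensity
  scale and full-spectrum SVR barely beats the mean predictor. Note the
  ε-tube leaves residuals up to ≈ 0.1 standard deviations unpenalized,
  which caps attainable R² slightly below 0.99 even on noiseless data.
* **GBM** — gradient boosting (LightGBM) with boosting_type='gbdt',
  num_leaves=31, max_depth=−1, learning_rate=0.1, n_estimators=100,
  pinned single-threaded and deterministic. Below 100 training samples a
  small-data mode lowers min_child_samples to 2, because the default
  leaf constraint yields constant predictions on tiny calibration sets.
  Variable importance is the average MSE-split improvement per variable
  across trees (total gain / split count), normalized to sum 1; a
  splitless model reports uniform importance and is flagged. As a
  piecewise-constant learner, GBM's noiseless prediction floor is set by
  calibration-point density (R² ≈ 0.97 at 192 samples, ≈ 0.99 at 288).

## Evaluation

R² is 1 − SSE/SST with SST about the mean of the reference values (the
squared-Pearson alternative is available via a switch; the two differ
whenever predictions are biased off the 45° line). RMSE carries
mg kg⁻¹. The full grid is 3 elements × 3 models × {full, CARS, RF, UVE}
= 36 cells sharing one split; per-cell predictions are persisted so every
reported metric is recomputable. A failing cell is recorded with its
error and skipped rather than aborting the grid. Descriptive statistics
of the design use the sample (n−1) variance.

Under the default study conditions the pipeline reproduces the
qualitative finding that motivates wavelength selection: full-spectrum
models (especially SVR, and PLSR to a lesser degree) are degraded by the
~1500 uninformative channels, while models on CARS/RF/UVE channels reach
prediction RMSEs around 8–17 mg kg⁻¹; the acceptance suite checks the
median improvement over 10 seeded replicates per element, and the
acceptance script prints the concrete numbers for one seed.

## Problem sizes and seeds

The suite's heavy studies run at the full default scale (288 × 1601):
line-recovery over 20 seeded replicates and the selected-vs-full
comparison over 10. Unit tests use a coarsened axis (2 nm step, 1 nm
lines, 48–192 samples) chosen so every library line still lands on the
grid. All stage seeds derive from one master seed via a stable CRC hash
of (seed, stage, element), so stages are decoupled and every run is
reproducible end to end.
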