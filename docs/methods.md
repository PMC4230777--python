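# Methods

`gliaglm` identifies directed functional connections in mixed neuron–glia
networks recorded by high-speed Ca²⁺ imaging. This note documents the model,
the estimation and selection machinery, the synthetic-data generator used for
validation, and the numerical and design choices a maintainer should know
about.

## The generative model

Activity is binned on a common grid (10 ms by default). Neuron *i* produces a
binary spike indicator nᵢ(t); glial cell *j* produces a continuous, per-cell
z-scored trace g_j(t). All cells are conditionally independent given the
shared history, which makes the likelihood a sum of per-cell terms.

**Neurons** follow a Bernoulli point process with a logistic link:

    P(nᵢ(t) = 1 | history) = σ( bᵢ + Σ_{i',τ≤T_NN} w_NN[i,i'](τ) n_{i'}(t−τ)
                                 + Σ_{j,τ≤T_GN} w_GN[i,j](τ) g_j(t−τ) ),

with σ the logistic function and bᵢ the spontaneous-rate intercept.

**Glia** follow a vector autoregression disturbed by white Gaussian noise:

    g_j(t) = c_j + Σ_{i,τ≤T_NG} w_NG[j,i](τ) nᵢ(t−τ)
                 + Σ_{j',τ≤T_GG} w_GG[j,j'](τ) g_{j'}(t−τ) + ε_j(t),
    ε_j(t) ~ N(0, σ²_j).

Each directed pair carries a **response function** w(τ) over lags
τ = 1..window. Lag 0 is excluded: interactions faster than one bin are
outside the model (a stated assumption, not an approximation error). The
first max(window) bins of any series are burn-in and enter no likelihood.

## Prior and MAP estimation

Each response function receives an independent quadratic log-prior

    log p(w) = − λ Σ_τ w(τ)² − η Σ_τ (w(τ+1) − w(τ))²  (+ const),

where λ controls L2-shrinkage ("sparseness" in the loose sense of small
kernels) and η penalises roughness in the lag direction. Intercepts and the
glial noise variance carry flat priors. λ and η are per-block (NN, GN, NG,
GG) and independent across directed pairs; coupling pairs is a possible
extension but the independent form is the natural reading of a per-kernel
penalty.

The log posterior decomposes per receiver cell, so MAP estimation is a set
of independent per-cell problems:

* **Neurons** — penalized logistic regression, strictly concave whenever any
  penalty is positive. The default optimizer is damped Newton (IRLS with an
  Armijo backtracking line search); L-BFGS on the identical objective is
  available as an independent backend and the two are cross-checked in the
  test suite. Convergence is certified by the max-norm of the gradient below
  `1e-6 · (1 + 1e-3 · n_rows)` — gradient entries are sums over rows, so an
  absolute threshold would be meaningless at 10⁵ observations. Near the
  optimum the objective improvement sits inside floating-point noise while
  the gradient can still shrink; a full Newton step that halves the gradient
  norm is therefore accepted even when the objective is fp-stuck.
* **Glia** — the objective is the quadratic cost ½‖y − Xθ‖² + θᵀPθ, whose
  unique minimizer solves (XᵀX + 2P)θ = Xᵀy. The penalty weights squared
  residuals directly; since glial traces are z-scored the residual scale is
  O(1) and λ, η keep a stable meaning across datasets. The noise variance is
  set to the mean squared training residual (its MLE under the flat prior).
* **Positivity-constrained glia** — the same quadratic cost under
  w_NG(τ) ≥ 0, solved exactly by a primal active-set method for
  bound-constrained QPs (finitely convergent for a strictly convex
  objective); the returned KKT residual is the max-norm of the projected
  gradient and is required to be < 1e-6.

Spike-history design columns are ~99% zeros at sub-hertz firing rates, so
the logistic fits use a column-partitioned design (dense intercept + glial
columns, sparse spike columns). This is an exact reformulation, roughly an
order of magnitude faster.

## Cross-validated likelihood and connection tests

The post-burn-in series is partitioned into K = 10 contiguous folds of
near-equal length (60 s folds at the reference 10-minute recording; the
method is blind to dependence on time scales longer than one fold). For a
candidate structure, each cell is refitted on K−1 folds and scored by its
mean per-bin held-out log-likelihood on the remaining fold. Folds partition
the *evaluated/trained* bins only: lagged features may reach across a fold
boundary, because discarding a burn-in per fold would waste data and the
partition argument applies to the modelled bins, not their histories.

A candidate connection is tested with a paired t-statistic over per-fold
held-out differences d_k:

    t = mean(d) / sqrt(s²/K),  s² the unbiased variance, df = K − 1,

one-sided at α = 0.05. Folds are not independent, so this is an admittedly
approximate reference distribution; the surrogate machinery below provides
the family-level control. Zero-variance difference vectors are flagged
degenerate (p undefined; the sign of the mean decides acceptance). No
per-pair multiple-testing correction is applied, by design.

The two cross-block directions are treated asymmetrically, following the
observation that the empty G→N block and the full N→G block are the
high-likelihood starting points:

* **G→N (grown from empty)** — pair (j → i) is tested by comparing M0 (no
  glia-to-neuron connections at all) with Mj (only glia j's connections
  present) on neuron i's held-out likelihood. Significant pairs are added
  greedily in decreasing-t order, and an addition is kept only if it also
  improves the receiving neuron's cross-validated likelihood under the
  structure grown so far — this makes the accepted-step likelihood trace
  non-decreasing by construction.
* **N→G (pruned from full)** — pair (i → j) is tested by removing that
  single connection from the full structure; it is kept only when the
  removal causes a significant held-out loss. A block-level variant (all
  neuron inputs to one glia vs none) is available as a diagnostic
  (`selection.test_ng_block`). Removing an insignificant pair can shave an
  insignificant amount of held-out likelihood; the monotonicity guarantee is
  deliberately claimed only for the additive phase.

N→N and G→G connections are never tested individually; the within-block
masks stay full (self-feedback included: refractoriness for neurons, slow
persistence for glia).

**Hyperparameters** (window sizes, λ, η) are tuned by exhaustive grid search
under tie constraints: the neuron-side parameters (T_NN = T_GN, tied λ, η)
maximize the neuron-wise cross-validated likelihood L^N of the full
structure, the glia-side parameters maximize L^G; the two sides decouple
because each side's likelihood involves only its own receivers. Default
grids: windows {10, 30, 50} bins, λ {0.1, 1, 10}, η {1, 10, 100} — these are
configuration defaults, to be adapted per preparation.

## Surrogate null tests

Per-pair t-tests say nothing about the *number* of detections under the
global null. Two surrogate constructions address this:

* **IAAFT** (iterated amplitude-adjusted Fourier transform) for glial
  traces: alternately impose the original Fourier amplitudes and the
  original value multiset (rank remapping) until the rank ordering is stable
  (cap 100 iterations). Amplitude preservation is exact — the surrogate is a
  permutation of the observed values — and the power spectrum matches to the
  iteration's convergence; cross-correlations with every other cell are
  destroyed. Constant traces are returned unchanged with a warning.
* **Circular shift** for spike trains: rotate by a uniform offset in
  [1, T−1], preserving spike count, circular ISI multiset, autocorrelation
  and self-dependence exactly. Each surrogated neuron gets an independent
  offset per replicate.

The **bulk-count test** replaces the target cell's series with a surrogate,
re-z-scores it, reruns the per-pair tests restricted to that cell, and
counts detections; over n replicates the p-value is the add-one fraction
(1 + #{null ≥ observed}) / (1 + n), which can never be exactly zero.
Hyperparameters stay fixed at the values tuned on the original data;
re-tuning inside every replicate would be computationally prohibitive and
would test a different null.

## Summaries

* **Strength matrix** — per-connection RMS of the response function,
  min–max-normalized within each of the four blocks separately (kernel
  magnitudes differ by orders of magnitude across blocks); max-abs scaling
  is available behind a flag.
* **Sign classification** — a connection is excitatory/inhibitory by the
  sign of the temporal average of its kernel; exactly-zero averages fall
  into a "null" category excluded from the positive-percentage summaries.
* **Average response** — per-lag mean and t-based 95% pointwise band over
  accepted kernels, plus a one-sample t-test on the temporal averages.
* **Median-distance test** — is the accepted G→N set spatially local? The
  observed median Euclidean distance over accepted (glia, neuron) pairs is
  compared against resampled sets that redraw, per glial cell, the same
  number of neurons uniformly without replacement; one-sided (smaller =
  local), add-one p-value.

## The synthetic-data generator

`simulate.build_scenario` + `simulate.simulate` run the generative model
forward and are the validation bed (the reference hippocampal recordings are
not publicly deposited). Defaults emulate the target preparation:

* 10 ms bins; baseline firing rates drawn log-uniformly from 0.2–0.8 Hz
  (inside the 0.03–1 Hz band of the reference recordings; a scenario is
  rejected if any implied baseline rate leaves the 0.01–2 Hz sanity band);
* response kernels are alpha-function bumps w(τ) ∝ (τ/τ_p)·exp(1 − τ/τ_p)
  peaking at mid-window (default window 8 bins), a smooth shape consistent
  with the smoothness prior;
* neuronal self-feedback is inhibitory (refractoriness, peak −2), glial
  self-feedback excitatory and slow (peak 0.1, VAR spectral radius checked
  < 1 via the companion form);
* cross-block kernels: G→N peak 0.15 (glial input modulates the spike rate
  severalfold without saturating the logistic), N→G peak 1.2 with a
  **negative** default sign. The negative default matters dynamically: with
  both cross-blocks excitatory the N→G→N loop is self-exciting and drives
  the network into saturation; the inhibitory direction matches the sign
  structure reported for this preparation and keeps the simulated network in
  the sub-hertz regime. Both signs and magnitudes are per-scenario knobs.
* randomness: one root seed spawns an independent child stream per cell, so
  removing the last cell leaves every other cell's draws bitwise unchanged.

What the generator does **not** emulate: Ca²⁺ indicator dynamics and
photon/shot noise (the movie-level fixtures used by the preprocessing tests
cover a simple version separately), slow non-stationarities, unobserved
common input, and interactions faster than one bin. Passing the validation
suite therefore shows the estimator is correct and well-calibrated *under
the model class*, not that the model class captures every property of real
recordings — the usual caveat for self-consistent simulation validation.

The headline validation (also recomputed by `scripts/acceptance.py`): on
8-neuron / 2-glia scenarios with planted cross-block connections and 1280 s
of simulated data (128,000 bins), the full pipeline's mean G→N
reconstruction accuracy over 10 seeded trials must reach at least 85%. The
reduced network size (8 + 2 rather than 48 + 6 cells) keeps a 10-trial run
in minutes on one core; accuracy is scored per possible pair, so the
statistic is comparable across network sizes.

## Preprocessing front end

Movies → ROIs → traces → spikes/glial series:

1. **ROI detection**: local maxima of the temporally averaged, spatially
   Gaussian-smoothed image; strict maxima within a disk of the minimum
   separation, plateaus resolved to the lowest row-major pixel, peaks below
   5% of the image range above the minimum discarded (suppresses the flat
   background), greedy acceptance by decreasing intensity. Deterministic by
   construction.
2. **Baseline estimation**: iterate — inliers are points within one SD of
   the current baseline; rebuild the baseline by linear interpolation
   through inliers with constant extrapolation at the ends; recompute the SD
   from the new residual — until the max baseline change < 1e-6 × trace SD
   (cap 50 iterations). The decomposition trace = baseline + residual is
   exact by construction. This doubles as detrending (photobleaching).
3. **Spike detection**: strict local maxima of the residual (ties to the
   earliest bin) exceeding `threshold_sd` × SD (default 3 — the reference
   description fixes a constant that is not printed, so this is an explicit
   knob). At most one spike per bin, binary output.
4. **Glial traces**: linear detrend → temporal Gaussian smoothing (default
   σ = 5 bins, likewise an explicit knob) → z-score, re-applied once to pin
   mean/variance to 0/1 within 1e-10.

Neuron-vs-glia ROI classification is deliberately *not* automated: in the
reference workflow it is a visual-inspection judgement (morphology,
brightness), so ROI kind is user-supplied metadata.

## Numerical conventions and edge cases

* Time bins are 0-indexed everywhere, including files.
* Column order in design matrices: intercept, then block (NN,GN for neurons;
  NG,GG for glia), sender ascending, lag ascending. The internal CV engine
  reorders to (intercept, glia, spikes) for the sparse split; the public
  `build_design` keeps the documented order.
* Probabilities from the logistic are clipped away from exact 0/1 only at
  the per-bin query API; the likelihood path works on the linear predictor
  and is overflow-safe via `logaddexp`.
* Degenerate inputs: constant traces (IAAFT, baseline), zero-variance delta
  vectors (t-tests), empty accepted sets (distance test) and all-outlier
  baselines raise or flag rather than returning silently wrong numbers.
* Per-cell fits are embarrassingly parallel in principle; the implementation
  runs them sequentially and is deterministic regardless of order (results
  depend only on per-cell sufficient statistics).

## Known limitations

* The t-reference distribution over folds ignores fold dependence (shared
  with the method being implemented); calibration is verified empirically in
  the test suite instead.
* Sub-bin (< 10 ms) interactions are invisible by assumption; interactions
  slower than one fold (60 s) are invisible by construction of the CV.
* The incremental search tests pairs through the M0/Mj and single-removal
  comparisons; it is not a full combinatorial search and inherits the usual
  greedy caveats when connections are strongly redundant.
* `validation_experiment` accuracy is a per-pair quantity; at very small
  networks single pair errors move the accuracy in large steps.
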