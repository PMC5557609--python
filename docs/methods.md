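# Methods

This note documents the models and estimators implemented in `decimix`,
the choices made where the design was genuinely open, and what the
synthetic benchmarks can and cannot certify about behaviour on real data.

## The factorization model

A fluorescence movie is flattened row-major to `Y ∈ R^{D×T}` (pixel
`d = row·W + col`). The generative model is

    Y = A C + b fᵀ + E

- `A` (`D×N`, ≥ 0): one spatial footprint per neuron, constrained to a
  square patch `P_n` around its center (`A(d,n) = 0` outside `P_n`), which
  enforces locality and sparsity by construction.
- `C` (`N×T`, ≥ 0): calcium concentration per neuron and frame.
- `b fᵀ`: rank-1 background — a spatial field `b ≥ 0` times a global
  intensity trace `f` (unconstrained in sign so offset-subtracted cameras
  are representable). Movies themselves may be negative; non-negativity is
  imposed only on `A`, `b`, `C`.
- `E`: zero-mean noise, independent across pixels, variance `σ_d²`.

Fitting minimizes `‖Y − AC − b fᵀ‖²` subject to these constraints. The
problem is biconvex; we use fast-HALS block coordinate descent with `b`
appended as an extra column of `A` and `f` as an extra row of `C`. Each
row/column update is the exact minimizer of the quadratic objective in
that block, clamped at zero (except the `f` row) and masked to its patch,
so the residual sum of squares (RSS) never increases. Updates consume
only `AᵀY` / `CYᵀ` and the `(N+1)²` Gram matrices.

## The multi-scale schedule

`fit_multiscale` runs, in order: temporal decimation by `k` (default 30,
frame-block means); greedy center detection on the decimated movie;
spatial decimation by `ly×lx` (default 3×3); patch construction; factor
initialization; `Ĩ` = 30 cheap alternating sweeps (one inner iteration
each) on the doubly decimated data; zero-order-hold upsampling of shapes
in space and of traces in time; and `I` = 5 full-resolution sweeps with 5
inner iterations each, stopping early when the relative RSS improvement
drops below 1e-4. Inner iteration counts follow the logic that early
coarse estimates change fast (alternate often, one inner pass) while
full-resolution cross-products are expensive (amortize them over more
inner passes).

Design choices in the schedule:

- The trace warm start returning to full resolution is a zero-order hold
  in time (each decimated value repeated `k` times, trailing frames held).
  A constant-per-neuron mean was rejected because it discards dynamics;
  the hold preserves each neuron's decimated mean and mirrors the spatial
  upsampling.
- Upsampled shapes are clipped to the full-resolution patches immediately,
  so the patch invariant holds at every point of the schedule.
- Components whose shape or trace collapses to zero norm are skipped and
  reported, never deleted, during fitting; deletion ("purging") belongs
  only to the one-phase baseline where it is the scientific observable.

### Initialization

- Per-pixel noise `σ_d`: square root of the mean periodogram power over
  the band [0.5, 1.0] of Nyquist. Calcium transients are slow, so this
  band is noise-dominated; the scaling is calibrated so i.i.d. Gaussian
  noise of std `s` estimates to `s`. Mean aggregation (not median) over
  the band.
- Greedy centers: mean-subtract, blur each frame with a Gaussian of width
  equal to the expected soma radius (reflection padding), then repeatedly
  take the pixel with maximal temporal energy of the blurred movie
  (row-major index on exact ties), refine a rank-1 shape/trace pair in a
  local window, subtract, and re-blur locally. `N` is user-supplied; no
  automatic order selection.
- Factors: `b` = per-pixel 20th temporal percentile, `f` = ones,
  Gaussian-bump shapes truncated to patches, traces read off the center
  pixels (background-subtracted, clamped at 0).

## Dynamics and deconvolution

Calcium follows AR(2) dynamics `c_t = γ₁c_{t−1} + γ₂c_{t−2} + s_t` with
non-negative spike magnitudes `s = Gc` (relaxed from integers), `G` the
banded unit-diagonal matrix with `−γ₁, −γ₂` on the subdiagonals.

**AR coefficient estimation.** The Yule–Walker system over lags
1 … p+5 is solved by least squares with the observation-noise variance
subtracted wherever lag 0 enters. A system using only lags ≥ 1 was
rejected: for AR(2) the information about the fast mode lives at lags
1–2, and excluding them leaves a nearly collinear regression (coefficient
errors ~0.2–0.4 at SNR 5 versus ~0.04 with the corrected system). Because
the AR signal itself leaks power into the high-frequency noise band, the
leakage implied by the current coefficients (innovation variance times
the mean in-band AR gain) is subtracted from the PSD noise estimate and
the system re-solved, 8 rounds. Near-flat or white traces return zeros
with a warning; results are clipped radially into the stable region.

**Single-trace deconvolution.** The parameter-free program

    min ‖Gc‖₁  s.t.  Gc ≥ 0,  ‖y − c‖² ≤ σ²T

is solved in the spike domain (`c = Hs`, `H` the impulse-response filter):
the penalized subproblem `min ½‖y − Hs‖² + λ‖s‖₁, s ≥ 0` is a
non-negative lasso handled by a Lawson–Hanson-style active-set method
whose restricted normal equations are assembled from truncated
impulse-response inner products (O(1) per Gram entry after an O(T)
precomputation) and whose full KKT check costs O(T) via causal/anticausal
filtering. An outer bisection on λ enforces the hard noise constraint to
1e-9 relative; the solver state persists across λ values, so each
re-solve touches only a few support changes. σ = 0 returns the exact
projection onto `{Gc ≥ 0}`. With no dynamics (γ = 0) the solution is the
closed-form soft threshold. Up to 16 KKT violators are admitted per pass;
the inner loop drops any that overshoot, which preserves correctness
while building large supports quickly.

**Matrix updates with noise constraints.** The temporal update
l2-normalizes shapes internally, projects the leave-one-out residual onto
each unit shape, estimates that trace's noise from its PSD, deconvolves
under the per-trace constraint, then refits `f` by least squares; the
caller's scale split is restored on exit. The spatial update minimizes
`‖A‖₁` per pixel over the components whose patch contains the pixel
(background unpenalized but non-negative — the printed objective
penalizes `A` only), bisecting the multiplier until the pixel's residual
constraint `‖Y(d,:) − A(d,:)C − b_d fᵀ‖ ≤ σ_d√T` is met within 0.1%.
Per-neuron σ is estimated from projected data, not propagated
analytically from pixel noise; unit-l2 shapes are assumed when
projecting.

**Interleaved acquisition.** Frames alternate between the unshifted
coarse grid (frame 0, 2, …) and a half-block-shifted grid. Shapes are
decimated per parity, traces fitted against both grids, and deconvolution
uses the parity-weighted constraint
`‖y_odd − c_odd‖²/σ²_odd + ‖y_even − c_even‖²/σ²_even ≤ T` with both noise
levels estimated from the corresponding parity's projected samples. AR
coefficients are estimated on all frames jointly. The half shift is
applied on both axes (the single-axis variant is available through the
offset argument).

## Two-phase demixing

`demix_lowres` holds decimated shapes fixed and runs (A) plain
non-negative trace updates to convergence, then (B) the constrained
temporal update. Phase A starts from zero traces and a unit background:
the problem is jointly convex in `(C, f)`, so the start only matters for
degenerate (collinear-shape) components — and there, warm-starting from
phase-1 traces would smuggle in information a real phase-2 acquisition
does not have. Component identity across decimation levels is inherited
from the phase-1 model; there is no matching step.

`run_one_phase` is the failure-prone baseline: shapes free, re-estimated
from the coarse movie by the sparse spatial update (initialized from the
decimated fine-scale fit, traces from the fine-scale fit), components
whose shape l2-norm falls below 1e-3 of its initial value are purged,
and survivors get refit traces. Purged components score correlation 0 in
recovery reports, and a constant candidate trace scores 0 by convention.

Ranking follows peak fluorescence × footprint compactness: after unit-l2
normalization of shapes, `score_n = max_t C(n,t) · ‖A(:,n)‖₄`, descending,
ties broken by index. ΔF/F divides `A(:,n)ᵀA(:,n) C(n,t)` by the
background projected onto the footprint, `A(:,n)ᵀ b f(t)`; the ratio is
invariant to the `(A, C)` scale split, and non-positive baselines are
flagged per frame.

## Synthetic data

No recordings ship with the package; `synthdata` generates ground-truth
scenes covering the study conditions:

- Footprints: isotropic Gaussian (cytosolic indicators) or annular
  (nuclear-localized), compact support (values < 1e-3 cut), placed by
  rejection sampling at a minimum separation, optionally with deliberately
  overlapping pairs or explicit centers.
- Traces: Poisson spike trains (default 0.02 spikes/frame ≈ 0.4 Hz at
  20 frames/s, sparse distinct transients) driven through the AR(2)
  recursion (default γ = (1.7, −0.712), GCaMP6-like decay at 20 Hz) or
  convolved with a supplied response kernel (`fit_response_kernel`
  recovers such kernels from paired fluorescence/spike data by least
  squares).
- Background: a smooth positive spatial field times a slow drift
  (±10% sinusoid plus 5% linear trend).
- Noise: i.i.d. Gaussian; offset Poisson (`P(ν + signal) − ν`, so the
  mean equals the noiseless movie and variance grows with the mean); or
  stratified residual reshuffling around a fitted model — per pixel,
  frames are ranked by reconstructed signal, split into 200 equal-count
  strata (ties by frame index), and residuals permuted within strata,
  preserving the per-pixel residual multiset exactly and the
  variance-vs-signal coupling up to stratum granularity.

**The standard benchmark scene** is a fixed-seed 128×128 grid with N = 40
neurons (four deliberately overlapping pairs at 4 px spacing), T = 1000
frames at 20 frames/s, and Gaussian noise with σ equal to half the median
peak pixel amplitude. Soma radius (3 px) and packing (≥ 8 px separations)
scale the geometry of a densely packed cortical two-photon field down to
this grid. Every neuron fires at least 3 spikes (rejection-resampled).

What the generator does *not* emulate — and hence what passing benchmarks
do not certify: correlated firing across neurons (spike trains are
independent), structured noise (neuropil contamination, motion, slow
drifts beyond rank 1), optics (no PSF), and bleaching. The most visible
consequence: the one-phase baseline degrades only mildly here (median
correlation 0.94 vs 0.95 for two-phase at 8×8 decimation, no purges),
because independent traces with accurately estimable white noise keep
the coarse spatial problem identifiable; on real recordings, correlated
activity and structured residuals make footprint re-estimation from
coarse data collapse much more dramatically. The merged-pair interleaving
benchmark reproduces the sharper mechanism directly: pairs confined to a
single 16×16 coarse pixel are unrecoverable by a single grid (median
correlation ≈ 0.5) and near-perfectly recovered with interleaving
(≈ 0.98).

## Numerical conventions

- Row-major 0-based pixel indexing everywhere; `(row, col)` order.
- Partial decimation blocks (borders, trailing frames) average only what
  they cover, so constants stay constant under any block size or offset.
- `subsample` temporal decimation takes the first frame of each block.
- Greedy peak ties break to the smaller row-major index; blurring uses
  reflection padding.
- Equal-count reshuffling strata; stratum membership by stable rank of
  the reconstructed signal.
- Random compression uses a single plain QR sketch (no power iterations).
- Active-set tolerances: Gram truncation at |h| < 1e-17, KKT tolerance
  1e-10 relative to the gradient scale, noise-constraint bisection to
  1e-9 relative.
- Benchmark problem sizes (128×128×1000 standard scene; 64×64×600
  interleaving scene; T = 3000 AR-recovery traces; T = 40 QP-oracle
  instances) were chosen so the full evaluation runs on a single CPU in a
  few minutes while leaving every effect it measures clearly resolved.

## Known limitations

- AR order is fixed per call (default 2); no automatic order selection,
  and kernel-based (non-AR) dynamics are supported in simulation but not
  in deconvolution.
- The one-phase baseline re-estimates shapes with a single spatial pass
  (plus purging) rather than alternating to convergence.
- `N` is user-supplied; detecting new neurons during phase 2 is not
  implemented.
- No motion correction, multi-channel, or volumetric containers.
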