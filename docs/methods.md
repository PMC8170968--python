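# Methods

## The predictor

One trial is a cue-aligned multichannel EEG segment `X ∈ R^{C×T}` with a
binary motor-imagery label.  Processing chains:

1. **Common average reference**, per trial: subtract the instantaneous
   channel mean from every sample.  Idempotent; requires `C ≥ 2`.
2. **Butterworth band-pass 7–30 Hz**, one wide band covering mu and beta
   rhythms.  The filter order is not dictated by the protocol; we use
   order 4 applied forward–backward (`sosfiltfilt`), which doubles the
   effective order and cancels group delay so that windows are not
   phase-shifted relative to the cue.  Both order and causality are
   configurable.
3. **Epoching** 0.5–2.5 s after the cue (200 samples at 100 Hz, 500 at
   250 Hz), half-open 0-based indexing `[cue + round(t₀·fs), cue +
   round(t₁·fs))` computed in pure integer arithmetic.  For pre-epoched
   input the same window is applied relative to the trial start, after
   filtering, so filter transients fall outside the analysis window.
4. **Delay windows.**  The epoch is cut into `n = 3` windows offset by
   `τ` samples.  Because only the stated epoch is extracted, the common
   window length is `L = T − (n−1)τ` (1.8 s at `τ = 10`, fs = 100 rather
   than the nominal 2.0 s); the alternative — extending the raw extraction
   beyond the epoch to keep `L = 2.0 s` — is available through the epoch
   window setting when a continuous record is supplied.  We prefer the
   truncating layout because it never consumes data outside the declared
   epoch.
5. **Six feature processes.**  CSP on each window (3 processes) and CSP on
   every channel-stacked window pair `[W_i; W_j]` (3 CSSP processes, `j >
   i`, fixed order (0,1), (0,2), (1,2) after the singles).  Each process:
   - per-trial covariance `XXᵀ/tr(XXᵀ)` (trace normalization removes
     trial-wise amplitude scale, standard CSP practice), averaged per
     class;
   - generalized eigenproblem `C⁺w = λ(C⁺+C⁻)w`; keep the `m = 3` largest
     and `m = 3` smallest eigenvectors (2m = 6 filters), normalized so
     `Wᵀ(C⁺+C⁻)W = I`, which simultaneously diagonalizes both class
     covariances;
   - 6 log-variance CSP features (sample variance, denominator `L−1`),
     which satisfy `Σ_k exp(f_k) = 1`;
   - 21 tangent-space features: the filtered-trial covariances are mapped
     at the Karcher mean of the *training* covariances,
     `s_i = upper(log(Σ̄^{-1/2} Σ_i Σ̄^{-1/2}))`, row-major upper triangle
     with off-diagonal entries × √2 so `‖s_i‖₂ = δ_R(Σ̄, Σ_i)`.  Test
     trials are projected with the stored training mean.
6. **Fusion and selection.**  The 6 × 27 = 162 features are ranked by
   Fisher score

   `F(i) = [(F̄ᵢ⁺ − F̄ᵢ)² + (F̄ᵢ⁻ − F̄ᵢ)²] / [s²ᵢ⁺ + s²ᵢ⁻]`

   with `N−1` variance denominators; the top `r = 10` are kept.  Columns
   carry provenance `(process, CSP|TSM, local index)` so selected indices
   map back to their source.  A feature with zero within-class variance in
   both classes but distinct class means is a perfect separator; its score
   is set to `+∞` (ranked first, with a warning), and a fully constant
   column scores 0.  Ties rank by ascending column index.
7. **Classifier.**  Selected features are z-scored with training-fold
   statistics (RBF kernels are scale-sensitive; the protocol is silent on
   standardization, so it is made explicit here), then an RBF-kernel SVM
   with cost `C = 1` and kernel width `γ = 1/(r · mean feature variance)`
   ≈ `1/r` after standardization.  Both are configurable.

## Delay selection and evaluation

`τ` is subject-dependent.  For each training fold, every `τ` in the grid
(default 1..round(0.1·fs) samples) is evaluated by an inner stratified
10-fold cross-validation of the complete pipeline; the `τ` with minimal
mean inner error wins and ties go to the smallest `τ` (cheaper for
real-time use).  Selection happens inside each outer training fold — the
stricter reading of "test samples are not used during parameter tuning".

Outer evaluation is repeated stratified k-fold (default 10 × 10-fold).
Folds are built by per-class round-robin after a seeded shuffle, so class
counts per fold differ by at most one; repeat `r` uses seed `seed + r`,
and inner CVs use seeds derived from (repeat, fold).  Reported measures:

- error rate = percentage of misclassified trials;
- Cohen's κ = `(p_a − p_e)/(1 − p_e)` from the confusion-matrix
  marginals, with `p_a = 1 → κ = 1`; the qualitative bands are
  < 0.20 Poor, 0.21–0.40 Fair, 0.41–0.60 Moderate, 0.61–0.80 Good,
  0.81–1.0 Very Good, and values in the printed gaps are assigned after
  rounding to two decimals.

No statistic fitted on data — spatial filters, Riemannian means, Fisher
ranks, the scaler, the SVM, and `τ` — ever sees a test fold.  The suite
probes this with a label-permutation test: destroying the label–signal
association must (and does) drive cross-validated error to chance.

## Numerical choices

- Matrix square roots, logs and exponentials go through symmetric
  eigendecompositions with an eigenvalue floor of 1e-12.
- Karcher mean: fixed-point iteration
  `Σ̄ ← Σ̄^{1/2} exp(mean_i log(Σ̄^{-1/2} Σ_i Σ̄^{-1/2})) Σ̄^{1/2}` with unit
  step, initialized at the arithmetic mean, stopping when the Frobenius
  norm of the mean log (the Riemannian gradient) reaches 1e-8, at most 50
  iterations; non-convergence returns the best iterate with a warning.
  On realistic inputs it converges in ~5 iterations.  Convergence degrades
  only when the number of spatial filters reaches the post-CAR rank
  (2m = C − 1): the smallest filter then lives in the reference null
  space, the trial covariances hit the regularization floor, and the
  whitened eigenvalue spread slows the iteration.  Use `C ≥ 2m + 2`
  channels (or fewer filter pairs) to stay clear of this regime.
- Covariances whose smallest eigenvalue is below 1e-12 × trace receive a
  ridge `1e-9 · tr(C)/d · I`; this keeps CSSP stacks with `τ = 0`
  (duplicated channels) and short windows solvable.
- CSP eigenvectors get a deterministic sign (first nonzero component
  positive) and a stable eigenvalue sort, so refits are bit-identical.
- A zero-variance filtered row (possible on degenerate inputs) is floored
  to the smallest positive float with a warning rather than erroring,
  since it occurs transiently inside inner CV on tiny folds.

## The synthetic generator

`generate_trials` emulates what the predictor assumes about sensorimotor
EEG: `K = 2` narrowband sources in the mu band (default 10–13 Hz, fixed
frequencies spread across the band, random phase per trial) are projected
onto fixed columns of a random orthonormal mixing matrix and superimposed
on spatially correlated background noise (white by default, optional 1/f).
Class `+1` scales even-indexed sources by `(1+δ)` and odd ones by `(1−δ)`;
class `−1` does the opposite — an ERD-like, class-dependent spatial
covariance in the filter band.  `snr` is the ratio of total source
variance to per-channel noise variance, and δ is derived from it so the
class band-power ratio at a boosted pattern is exactly `1 + snr`:
`δ = (√(1+snr) − 1)/(√(1+snr) + 1)`.  Defaults (100 trials/class, C = 10,
fs = 100 Hz, 3 s trials) mirror a typical competition subject at desk
scale.  Everything is driven by one seeded generator; the same seed gives
bit-identical output.

`generate_null_trials` runs the identical process with δ = 0 and random
labels (chance-level ground truth).  `generate_planted_lag_trials` builds
classes that differ only in the sign of a lagged echo of a broadband
source, `x = s(t) ± g·s(t−lag)`: instantaneous spatial covariance is
(nearly) class-blind while the lagged cross-covariance separates the
classes, giving the nested τ selection a recoverable ground truth.  The
echo's residual autocorrelation at the lag leaks a small instantaneous
power asymmetry (band-limited sources cannot be perfectly white), which
the tests bound rather than ignore.

What the generator does *not* emulate: volume-conduction forward models,
ocular/muscular artifacts, non-stationarity across a session, or realistic
1/f² spectra.  Passing tests therefore show the pipeline's statistical
machinery is correct and leak-free under its own assumptions — not that
any particular error rate will transfer to recorded EEG.

## Evaluation scale

The test-suite and acceptance runs use desk-scale problem sizes chosen to
exercise every code path with stable statistics: end-to-end runs use 200
trials/class, C = 10, fs = 100 Hz with a single CV repetition and the
delay fixed at 10 % of the sampling rate (the near-optimal value of the
protocol, making nested re-selection redundant there); the delay-recovery
study uses 30 trials/class, C = 8, a 4-point τ grid and 12 generator
seeds.  The full 10 × 10-fold protocol with the complete τ grid remains
the library default.

## Known limitations

- Binary classification only; multi-class CSP/TSM extensions are out of
  scope.
- One wide 7–30 Hz band; no per-subject filter-bank learning.
- The covariance ridge is the only shrinkage offered.
- The BCI Competition MAT loader covers the two continuous-format
  datasets; GDF recordings are not parsed.
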