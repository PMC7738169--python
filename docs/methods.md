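# Methods

This note documents the models, conventions, and numerical choices behind
`funcsearchlight`, and what the synthetic benchmark does and does not show.

## Shared response model

Each subject's preprocessed voxel × time matrix `X_i` (v_i × t, every voxel
z-scored in time) is modeled as `X_i = W_i S + E_i` with `W_i` (v_i × k)
orthonormal-columned and `S` (k × t) shared across subjects. Fitting is
deterministic alternating least squares:

* `S ← (1/n) Σ_i W_iᵀ X_i` — the least-squares shared response given the
  bases (using `W_iᵀW_i = I`);
* `W_i ← U Vᵀ` from the thin SVD of `X_i Sᵀ` — the orthogonal Procrustes
  solution per subject.

Bases are initialized from the QR factorization of a seeded standard-normal
matrix; the per-subject seed is derived from the subject *identifier*, so a
fit is invariant to the order in which subjects are supplied. The recorded
objective is the sum of squared Frobenius residuals `Σ_i ‖X_i − W_i S‖_F²`,
which both updates provably never increase; the trace is asserted
non-increasing on every fit. (The non-squared sum of norms is not the
quantity coordinate descent controls, which is why the squared form is the
one we track.) Default 10 iterations with early stop at a relative objective
change below 1e−6; on the problem sizes here the fit is converged well
before that.

`k` is chosen by time-segment matching: fit the SRM on the first half of the
timepoints, project the second half for all subjects, and ask for each
left-out subject whether each sliding window (default 14 s, converted to
TRs by rounding) of its projection is most correlated with the correct
window of the other subjects' average projection. Candidates overlapping the
test window are excluded from the argmax — the overlap convention is ours;
published descriptions of this procedure do not state one, and we do not
attempt to reproduce any particular printed chance constant that depends on
it.

## Functional space and neighborhoods

A voxel's functional coordinates are its row of `W_i` (or of the PCA loading
matrix). Rows with Euclidean norm below 1e−12 are dropped — such voxels
contribute nothing to the shared space. PCA spaces are computed by the
uncentered SVD of the voxel × time matrix: rows are already time-centered by
z-scoring, and skipping re-centering makes the voxel-pair cosine structure
exactly invariant to orthogonal rotations of the time axis. Component signs
follow the usual largest-loading-positive convention.

Functional searchlights are the center voxel plus its `j` nearest retained
voxels by cosine distance `1 − cos(u, v)` (well-defined because zero-norm
rows were dropped). The search is exact: batched dense distance computation
with an argpartition preselection whose boundary ties are resolved by a full
(distance, voxel id) sort, so equidistant neighbors are always taken in
ascending-id order. Including the center makes a `j = 342` functional
searchlight match the 343 voxels of a radius-3 anatomical cube; `j = 124`
matches radius 2. Anatomical searchlights are cubes of side `2r+1`
intersected with the mask; edge centers keep only in-mask members. A yoked
mode truncates each functional searchlight's ordered member list to the
matched anatomical searchlight's size, for controls where the two methods
must use identical voxel counts.

## Kernels

* **Buffered RSA.** The searchlight RSM is the Pearson correlation between
  the member-pattern vectors of every TR pair. Only upper-triangular pairs
  separated by more than `buffer_trs` (default 10) are retained, removing
  autocorrelation-inflated pairs; the retained count is
  `C(t,2) − Σ_{d=1..b}(t−d)`. The statistic is the Pearson correlation of
  the retained entries of the brain and model RSMs. Pearson is used at both
  orders.
* **Embedding decoding.** Ridge regression (default penalty 1.0, exposed in
  config) maps searchlight voxels to embedding dimensions on the training
  TRs; predictions for the test TRs and the actual embeddings are averaged
  within consecutive-TR bins (mean vector per bin, not concatenation), and
  accuracy is the fraction of rows of the bin × bin correlation matrix whose
  argmax is the diagonal. Chance is `1/n_bins` exactly: within any fixed set
  of actual bins the argmax probabilities of an independent-noise prediction
  sum to one across candidates, so the diagonal hit rate averages to
  `1/n_bins`.
* **Category decoding.** Stratified n-fold (default 3) cross-validated
  linear SVM (scikit-learn `LinearSVC`, C = 1) on block-averaged localizer
  examples; block patterns average the TRs of each block after a fixed
  2-TR hemodynamic shift (exposed in config). With 8 examples per category
  and 3 folds, per-fold category counts are 3/3/2 — stratification keeps
  them within one of each other; exact equality is arithmetically
  impossible. The cross-validated permutation mean sits a fraction of a
  percentage point below 1/6 for this reason (fold-imbalance anti-learning),
  a property of the estimator rather than a defect.

## Engine and chance estimation

`run_searchlight` maps any kernel over any neighborhood map; results are
independent of worker count and evaluation order, kernel failures at
individual centers are recorded as missing values with reasons (excluded
from top-percent summaries), and more than 10% failures aborts the run. The
RSA path is specialized: each center's retained RSM vector is computed once
(batched by neighborhood size, single-precision batched matrix products) and
correlated against the model RSM vector of every requested temporal shift —
rolling the model features leaves the brain RSMs untouched, which makes the
100-shift rolling null cheap. Rolling the features rather than the brain
data is equivalent by symmetry of the misalignment.

Chance for a searchlight type is the mean over nonzero circular shifts
(multiples of `shift_unit`, default 10 TRs; shifts that are multiples of t
are skipped) of the same top-percent summary, re-selected per shift. Percent
improvement is `100·((f−f₀)−(a−a₀))/(a−a₀)` for top-percent statistics f, a
and their type-specific chances f₀, a₀. Group inference bootstraps subjects
with replacement (default 10,000 draws); the 95% CI is the [2.5, 97.5]
percentile interval, significance requires the lower bound above 0, and the
reported tail probability is floored at `1/n_boot`. Per-subject improvement
ratios are unstable whenever the anatomical searchlight sits near its own
chance level, so sweep-level summaries use the cohort-pooled ratio
(improvement of averaged chance-corrected statistics).

## Synthetic data

The generator emulates multi-subject movie-watching BOLD with a planted,
spatially controllable signal:

* **Signal placement.** White noise on the mask's bounding grid is smoothed
  with a Gaussian kernel (σ = FWHM/(2√(2 ln 2))) *before* masking (avoiding
  edge bias toward the mask border), and the `n_signal` in-mask voxels with
  the highest field values are selected. Low FWHM approaches uniform
  sampling (distributed signal); high FWHM clusters the selection (localized
  signal).
* **Signal content.** One feature unit drives each signal voxel. The shared
  feature series is smooth (Gaussian-smoothed white noise, timescale 3 TRs)
  and rank-limited (default latent rank 8): the DNN-layer activations these
  features stand in for are strongly correlated across units, and it is this
  low effective rank that lets similarly-tuned voxels cluster in the learned
  space. Mutually uncorrelated units would give every signal voxel a random
  loading direction and no cosine structure to find. Unit time courses are
  convolved with a double-gamma HRF (response gamma peaking at 6 s,
  undershoot gamma at 16 s, 1/6 undershoot ratio, peak-normalized) and
  scaled so the convolved peak equals `psc/100 × baseline` (0.5% of baseline
  100 by default; standard-deviation scaling is available as an option).
* **Noise.** Parametric stand-in for realistic scanner noise: baseline 100,
  spatially smoothed white noise (FWHM 2 voxels, re-normalized to unit
  marginal variance), AR(1) temporal dynamics (ρ = 0.3, stationary
  variance), amplitude `sd`. The default `sd = 0.125` (0.125% of baseline)
  is the scaled-down operating point: the full-scale studies this package
  models fit the shared space on roughly 37× more subject-timepoints than
  the default 4-subject, 100-training-TR cohort, so the per-sample
  contrast-to-noise is raised by about √37 ≈ 6 relative to a full-scale
  0.5%-signal-on-1-2%-noise regime to keep the planted structure equally
  recoverable. At these settings the median correlation between a signal
  voxel's time series and its HRF-convolved unit is ≈ 0.84.

Everything is reproducible bitwise from `(spec, seed)`; per-subject streams
are spawned from one seed sequence.

**What the benchmark shows — and does not.** The dispersion experiment
(4 subjects, 16³ solid mask, t = 200 with a 100-TR SRM training half,
128 signal voxels, k = 40, radius-2 searchlights matched by j = 124,
5 rolling shifts, FWHM sweep) verifies the method's *mechanism*: functional
searchlights beat anatomical ones when — and because — signal is
distributed, and the advantage shrinks as signal localizes. These problem
sizes are the package's own desk-scale choices. The generator does not
reproduce scanner drift families, physiological noise, subject motion,
anatomical variability, or template-derived scanner-noise taxonomies, and a
solid cuboid mask has no cortical geometry; passing here shows the pipeline
is correct and the mechanism operates as claimed, not that any particular
effect size will be observed on real data.

## Degenerate inputs and numerical conventions

Zero-variance voxels are dropped at load (counts logged), never imputed.
Constant TR patterns make an RSM undefined: the kernel raises with the TR
index, and the engine records the center as missing. Cosine ties are broken
by ascending voxel id; bin-ranking argmax ties (measure-zero) resolve to the
first index. The GRF selection breaks value ties by ascending voxel id.
Metric maps round-trip through NIfTI at float precision with the mask's
affine carried through untouched; no resampling is ever performed
(registration is upstream of this package).

## Known limitations

* SRM assumes temporally aligned stimulation across subjects; for designs
  without such alignment, use the PCA space (fit within subject).
* The deterministic SRM here does not implement probabilistic/Bayesian
  variants.
* Within-hemisphere analyses are expressed by supplying a hemisphere mask;
  there is no special code path.
* The engine parallelizes with a process pool at desk scale; cluster/MPI
  execution is out of scope.
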