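# Methods

This note documents the models, conventions and numerical choices behind
`eegsa`, and what the synthetic cohort does and does not emulate.

## Signal model and spectral conventions

A recording is a set of equally long µV series, one per channel, each
channel assigned to a scalp region (F, C, P, T, O).  Spectral estimation
uses the plain DFT periodogram

    X(w) = Σ_{t=0}^{N−1} x(t)·exp(−j2πwt/N),
    S(w) = Δt²/(NΔt)·|X(w)|² = |X(w)|²/(N·f_s),   Δt = 1/f_s,

which satisfies the Parseval identity Σ_w S(w) = Δt·Σ_t x(t)² (asserted in
the tests to 1e−9).  No taper or segment averaging is applied: the ratio
metrics divide powers estimated under identical conditions, so a window
correction would cancel.

**Bands.** The canonical integer band edges (δ 1–4, θ 5–8, α 9–14,
β 15–30, γ 31–59 Hz) leave 1-Hz gaps into which DFT bins of short epochs
would fall.  Bands are therefore made contiguous as half-open intervals
[lo, hi+1): δ [1,5), θ [5,9), α [9,15), β [15,31), γ [31,60).  Band power
sums S(w) over the positive-frequency bins inside the interval; DC is
excluded and each bin is counted once.

**Ratio metrics and region averaging.** The five metrics θ/β, α/β,
θ/(α+θ), (α+θ)/β, (α+θ)/(α+β) are formed from band powers averaged
arithmetically over a region's channels (powers first, ratio second; the
ratio of averages is stabler than the average of ratios when channel
powers differ in scale).  A zero denominator (β = 0 or α+θ = 0) raises an
error instead of silently producing 0 or infinity.

**Preprocessing.** Mains interference is removed with a second-order IIR
notch (default 50 Hz, Q = 30, zero-phase forward–backward application).
The artifact rule — any sample with |v| > 200 µV on any channel — is
applied after the notch; the flag is dilated to the containing
non-overlapping 5-s block, and any sliding window overlapping a flagged
sample is discarded.

**Feature extraction.** Features are computed in 5-s windows with 50 %
overlap (both configurable).  Each window is split into 1-s sub-epochs;
each (metric, region) value is computed per sub-epoch, and the window's
feature is the mean (column code M) or the median (code P) over the five
sub-epoch values.  The within-window sample over which mean/median are
taken is a modelling choice — a single 5-s estimate has no within-window
distribution — and 1-s sub-epochs give a 1-Hz frequency resolution, the
coarsest grid that still separates the θ/α boundary.  Columns are named
`<region><M|P><metric index>` with indices 1 = α/β, 2 = θ/(α+θ),
3 = (α+θ)/β (the correlated trio), extended by 4 = θ/β and
5 = (α+θ)/(α+β) when the full metric set is extracted.

## Synthetic cohort generator

Each channel is a sum of one sinusoid per band, placed at an integer
frequency near the band center (3, 7, 12, 23, 45 Hz) so a 1-s DFT captures
it in a single bin and the analytic tone power A²/2 makes band-power
bookkeeping exact; plus 1/f-amplitude-shaped Gaussian noise (default
SD 5 µV), a 50 Hz line component (default 2 µV) and Poisson-placed
half-sine artifact pulses (0.2–0.5 s, peaks 250–400 µV, default 0.5
events/minute) which deliberately exceed the 200 µV rejection rule.  The
generator is a pure function of (spec, group, subject id, seed); artifact
placement uses an independent child stream of the seed so the event count
is reproducible in isolation.

**Calibration.** Given targets for α/β and (α+θ)/β, the θ/α/β powers are
fixed up to scale (P_α = (α/β)·P_β, P_θ = ((α+θ)/β − α/β)·P_β), so
empirical region ratios converge to the targets as duration grows; with
noise off, a 10-minute recording lands within 5 % (asserted in tests).
The five published group-mean metrics are not jointly realizable from
three band powers (they are mutually inconsistent as a set), so two of
them anchor the calibration and the rest follow.

**Default cohort.** The default spec plants group differences only in the
frontal and central α/β, θ/(α+θ) and (α+θ)/β — the pairs the screening
stage is supposed to find.  This requires θ-power = β-power in every
group/region: that is the unique construction under which θ/β ≡ 1 and
(α+θ)/(α+β) ≡ 1 carry no group information while the trio moves with the
α power.  Group α/β levels use the published frontal/central group means
(0.457 vs 0.752 in F, 0.462 vs 0.812 in C); parietal/occipital levels are
identical across groups.  Between-subject scatter draws each subject's
α/β target from a normal with the published α/β standard deviations.
Default session length is 300 s per subject — long enough for ~118
overlapped 5-s epochs and several stacked classifier inputs per subject —
and 2 channels per region (the montage is configuration, not
reproduction).

**What the generator does not emulate:** physiological artifact morphology
(ocular/cardiac templates), non-stationary band power, cross-channel
correlation structure beyond shared region tones, volume conduction, or
electrode noise heterogeneity.  Passing tests therefore demonstrate that
the pipeline recovers planted spectral group structure under realistic
noise and artifact rates — not that real pilot EEG is classifiable at any
particular accuracy.

## Correlation screening

Subjects, not epochs, are the permutation units: epochs within a subject
are strongly dependent, and the group comparison is over 13 vs 12
subject-level metric means.  The test statistic is Welch's t (n−1 sample
variances); the two-sided p-value shuffles group labels over the pooled
subjects with an additive-one correction (p ≥ 1/(n_perm+1), never 0);
n_perm defaults to 10,000.  If both group variances vanish the statistic
is 0 for equal means and signed infinity otherwise.  Comparisons are
reported at two significance tiers (0.05 and 0.1); selection uses the
lenient 0.1 so a pair at p ≈ 0.07 — the frontal α/β case — is retained.
Selection is restricted to the frontal/central regions by default;
significant parietal/occipital pairs are reported but not selected.  Each
selected (metric, region) pair contributes its mean and median feature,
giving 12 names when the full trio passes in both regions.

## Random-forest stage

The forest is a bagged ensemble of scikit-learn CART trees with explicit
bootstrap bookkeeping: each tree draws n indices with replacement, its
out-of-bag (OOB) complement is stored, and the ensemble predicts by
majority vote (exact ties go to the negative class).  "Adding noise" to a
feature is implemented as permuting that feature's values within each
tree's OOB set — the standard reading — and the importance is the mean
per-tree OOB error increase; trees with an empty OOB set are skipped and
the tree count adjusted.

Grid search maximizes 5-fold stratified CV accuracy over
n_estimators × max_depth; the package default grid
({5,10,15,20,30,50} × {2,4,6,8,10,15,20}) keeps a single-CPU search fast,
and any denser grid can be passed explicitly.  Ties prefer the smaller,
then shallower, forest.

Backward elimination drops the current lowest-importance feature (ties:
lexicographically last name, logged), refits, and records the out-of-fold
normalized RMSE and RE at each retained count — 11 trace entries from 12
features.  The RMSE here is the non-standard normalized form
√(Σ(y_obs−y_pred)²/Σ(y_obs−ȳ_pred)²) with ȳ_pred the prediction mean; a
conventional RMSE is provided for reference but never drives elimination.
RE is defined as mean absolute error over the observed-label range (plain
MAE for 0/1 labels).  The retained set is the RMSE-minimizing count, ties
resolved toward the larger count.

## PCA combination

Features are z-scored and the correlation matrix eigendecomposed —
the unit-norm loading constraint Σ_j e_ij² = 1 presumes correlation-matrix
PCA, and the ratio features have heterogeneous scales.  Components are
sorted by decreasing eigenvalue; each loading row is oriented so its
largest-magnitude entry is positive (a reproducible sign convention).
Contribution_j = eigenvalue_j/Σ·100 %; the retained count k is the
smallest cumulative contribution ≥ the threshold (default 87.7 %), or a
fixed k when configured (fixed k wins if both are set).  Composite weights
w_i = c_i/Σ_{j≤k} c_j are positive, non-increasing and sum to one; applied
to the reference contribution column they reproduce all six reference
composite coefficients to ±0.0001.

On the default synthetic cohort the first component typically carries
~85–90 % of the variance, so k = 1: all twelve features are driven by one
latent α-level factor per region plus epoch noise.  Real EEG features are
less collinear, which is why a six-component solution can arise there;
the selection rule is identical in both cases.

## PCA-fused CNN

Inputs are 13×20 maps: the k component scores of 20 consecutive
same-subject epochs as columns (rows beyond k zero-padded), each
component min-max scaled to [0,1] using its range over the whole score
matrix — scaling per component globally, not per sample, so between-group
level differences survive.  Stacks advance by a configurable stride
(pipeline default 5 epochs, i.e. overlapping stacks, for more training
samples).

The network is two blocks of (valid 5×5 convolution, stride 1 → ReLU →
3×3 max pooling at stride 1 with −inf same-padding, so the small maps keep
their extent) followed by a fully connected two-unit softmax head.  After
each convolution the activated map is flattened, projected onto the top-m
principal directions (m = 2 by default) of a warm-up batch of activations
— uncentered SVD, frozen thereafter — reconstructed, reshaped and added
point by point to the pooled map.  Uncentered PCA keeps the fusion purely
linear, so zero bases reduce the network *exactly* to the plain CNN: the
ablation identity the tests assert, and how the "plain CNN" comparison arm
is built.  Two convolution blocks fit the 13×20 extent; more would exhaust
it.

Training is plain SGD (no momentum): w ← w − ε(∂J/∂w + λw) with ε = 0.1,
λ = 10⁻⁴, mini-batches of 20, a stratified 75/25 train/test split, and the
loss-triggered schedule: if the epoch-mean training loss rises by more
than 25 % over the previous epoch, ε is halved before the next update.
Iterations count mini-batches.  Gradients are hand-derived; a kink-aware
finite-difference check (coordinates whose two-stencil estimates disagree
straddle a ReLU/pooling kink and are skipped) verifies them to < 1e−4
relative error.

## Evaluation

The positive class is the at-risk (low-SA) state.  Confusion counts use
the standard definitions; ACC, TPR, TNR,
MCC, F1 and Cohen's kappa by their textbook formulas, with undefined
ratios reported as NaN rather than 0.  ROC points come from the full
threshold sweep; AUC is the normalized Mann–Whitney U (pair-ranking
probability, ties ½), exactly equal to the O(n²) pairwise oracle.

`compare_methods` trains the plain forest (all features), the plain CNN
(z-scored unreduced features, fusion off) and the full hybrid on identical
repeated splits.  Two split modes exist: `epoch` (stratified over epochs;
epochs of one subject may appear on both sides, which inflates absolute
accuracy through subject identity) and `subject` (whole subjects held
out).  For the same reason the chance-level control used in the acceptance
checks shuffles labels at the *sample* level — a subject-level shuffle
under epoch splits lets the classifier recover the shuffled label through
subject identity, which is a leakage artifact, not signal.

## Reported problem sizes

The acceptance script uses: 120-s recordings for the ten-seed screening
recovery runs, a 300-s 13-vs-12 cohort for the end-to-end run, 500
simulations for the type-I calibration and 200 for power (n_perm = 199
within each simulation), and five shuffled repeats for the chance control.
These sizes are the package defaults for a single-CPU reproduction; all
converge visibly tighter with larger values.

## Known limitations

* The synthetic cohort's feature collinearity makes PCA retain one
  component; the six-component regime of less collinear data is exercised
  only by the arithmetic-chain tests.
* Epoch-level splitting reproduces the source protocol but leaks subject
  identity; subject-level splitting is provided and recommended for any
  real-data use.
* EDF I/O is not provided; recordings interchange as the documented CSV
  dialect (`label@region` headers) plus YAML generator specs.
* The elimination trace on strongly separable data is flat (many exact
  importance ties); the tie rule keeps it deterministic, but the retained
  set is then driven by the RMSE trace noise floor rather than real
  importance differences.
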