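# Methods

`nirtaste` re-implements a non-destructive Vis-NIR calibration workflow for
apple fruit chemistry: predict titratable acidity (TA) and the taste index
(TSS/TA) from reflectance spectra, using metaheuristic wavelength selection
and a tuned shallow neural network, with partial least squares regression
(PLSR) as the statistical baseline. This note describes the models, the
synthetic data the package is validated on, and the numerical choices that
were genuinely open.

## Data model

A spectrum is a row of reflectance intensities on a strictly increasing
wavelength grid; the default grid is 200–1100 nm at 1.2 nm resolution (751
points), matching the instrument class the workflow targets.
Reference-normalised reflectance above 1 is allowed, non-positive values are
not. Chemistry references carry TA (titration scale, dimensionless here;
typical value ≈ 0.55), TSS in °Brix, and the derived taste index
TSS/TA, validated to 1e−9 relative on construction. The 150-sample study
design is three harvest stages of 50 fruit; stage labels are carried as
metadata and used only by the statistics module, because the stage effect on
chemistry is non-significant and regression pools all samples.

## Preprocessing

Three stages, in fixed order, each acting on one spectrum at a time:

1. **Absorbance**: A = log10(1/R). Base 10 is the absorbance convention in
   NIR spectroscopy (the Beer–Lambert linearisation).
2. **SNV** (standard normal variate): centre and scale each spectrum to mean
   0, sd 1 with the sample (n−1) standard deviation. Removes additive offset
   and multiplicative scatter; a multiplicative factor in reflectance is an
   additive offset in absorbance, so SNV cancels the generator's scatter
   model exactly.
3. **Median smoothing**: running median, default window 5 (mild smoothing at
   1.2 nm resolution), reflect padding so length is preserved.

Optional wavelength trimming runs before everything and is off by default.
The chain is per-sample, hence equivariant to sample reordering.

## MLP core

Hidden architecture: 1–3 layers, first layer 1–25 neurons, deeper layers
0–25 (0 = absent, and forces deeper layers absent); a single linear output
unit is always appended. The 13 transfer functions of the classic
shallow-network vocabulary are implemented elementwise with exact
derivatives (`radbasn` normalises across the layer and uses the full
chain-rule coupling); hard-threshold transfers are available for evaluation
but excluded from gradient search because their derivative is zero almost
everywhere.

Trainers: `traingd` (batch gradient descent), `traingdm` (+ classical
momentum), `trainrp` (Rprop without backtracking, Δ0 = 0.07, Δ ∈ [1e−6, 50],
η± = 1.2/0.5), `trainbfg` (BFGS via scipy.optimize on the packed parameter
vector; above 400 parameters the memory-limited L-BFGS variant is used
because a dense inverse-Hessian update is O(n³) per iteration), and
`trainbr` (Rprop on MSE + λ‖w‖², with λ selected on the validation split
from {1e−4, 1e−3, 1e−2}). Other trainer names from the source vocabulary are
rejected rather than silently aliased. The weight/bias *learning function*
names are accepted and recorded as metadata only: batch trainers do not
consult them.

Inputs and the target are z-scored with training-split statistics inside
`train_mlp`; predictions are de-standardised. Early stopping monitors
validation MSE with a patience counter (default 30 epochs) and the returned
weights are those of the best-validation epoch. Initialisation is uniform
(−1, 1)/√fan_in from a seeded generator, so identical (data, architecture,
config, seed) reproduce identical weights bit for bit for the hand-written
trainers.

## Firefly wavelength selection

Candidates are fixed-size subsets of k grid indices, carried as continuous
positions in index space. Brightness is inverse fitness; fitness is the
validation MSE of a judge model trained on the candidate's channels:

* **ANN judge** (production): the fixed 18/6 tansig network trained with
  Rprop, averaged over 2 restarts to damp initialisation noise.
* **Ridge judge** (deterministic): closed-form ridge regression
  (α = 1e−3 on standardised columns), used for oracle tests and large seed
  sweeps where thousands of evaluations are needed.

Movement follows the standard attraction rule
x_i ← x_i + β0·exp(−γ r²)(x_j − x_i) + α(u − 0.5), applied for every
brighter firefly j, followed by round-to-grid, clamp, and
nearest-free-index duplicate repair. α decays geometrically per iteration.
The brightest firefly additionally performs coordinate-wise random walks
(three per coordinate per iteration), half of them local at scale α and
half resampling the walked coordinate uniformly over the grid. This
intensification preserves already-found channels while letting stray
coordinates cross the grid; a full-vector walk cannot do both, and without
it the swarm reliably finds only a subset of the planted channels on the
751-channel grid. The search runs separately per k in `k_range` and the
winner is the lowest fitness with a parsimony tie-break: within 1% relative
fitness of the minimum, the smallest k wins.

Defaults (m = 20, T = 50, β0 = 1, γ = 1/grid²,α = 0.5 decaying ×0.97) are
standard settings scaled to index space. The recovery analyses in the test
suite use a larger budget (m = 30, T = 250, α = 30 decaying ×0.99,
γ = 20/grid²) because needle-in-haystack subset recovery on 751 channels
needs both long-range exploration and weak long-range attraction.

Selection-stage fitness uses a dedicated 60/40 train/validation split
(`selection_split`), not the 60/10/30 modelling split: subset comparison
across thousands of candidates is noise-dominated with only 15 validation
samples. The replicated evaluation afterwards uses the 60/10/30 protocol
unchanged.

## PSO architecture tuning

The mixed space (widths × transfers × trainer × learning-function tag) is
relaxed to an 8-dimensional box; integer dimensions decode by rounding,
categorical ones by flooring onto the vocabulary index, and a zero width
truncates deeper layers, giving a canonical trailing-zero-free architecture.
Velocity/position updates are the standard inertia + cognitive + social rule
(w = 0.72, c1 = c2 = 1.49, velocity clamped to 20% of the box width —
constriction-equivalent values). Divergent or untrainable particles score
+∞ with a warning instead of aborting the search.

Two design points matter in practice:

* **Per-restart resplitting.** A particle's fitness averages validation MSE
  over `fitness_reps` restarts, and each restart redraws the 60/40 split of
  the pooled tuning rows. Early stopping already optimises against the
  validation split; scoring a *fixed* split therefore systematically
  flatters high-capacity architectures (they can sit arbitrarily close to
  the validation optimum). Redrawing the split makes the fitness an honest
  out-of-sample estimate and empirically reverses the ranking in favour of
  low-variance architectures on near-linear problems.
* **Warm start.** The initial swarm seeds its first two particles at
  reference designs — a minimal linear network (1 purelin neuron, BFGS) and
  the fixed 18/6 tansig judge. They are evaluated like any other particle
  and survive only if nothing random beats them. This is the usual
  default-configuration warm start of architecture search and makes small
  search budgets reproducible rather than luck-dominated.

## PLSR baseline

Univariate-response NIPALS with X-only deflation: w ∝ E'f (unit norm),
t = Ew, p = E't/t't, q = f·t/t't, E ← E − tp'. X columns are mean-centred
but not variance-scaled (spectral channels share units); y is mean-centred.
The regression vector b = W(P'W)⁻¹q reproduces the score-space predictions
to 1e−8 and matches scikit-learn's PLS coefficients to 1e−6 on random data.
Component count is chosen per replication as the validation-MSE argmin
(ties to fewer components), capped at 10.

## Evaluation protocol

Each replication r draws a 60/10/30 split with seed base+r
(n_train = round(0.6n), n_val = round(0.1n), test = remainder; 90/15/45 at
n = 150), trains the model spec (ANN retrained from a fresh seed; PLSR with
n_comp re-selected), and computes R (Pearson), R² (defined as the square of
R — the convention consistent with the published metric pairs, which differs
from 1 − SS_res/SS_tot for biased predictors), MSE, RMSE = √MSE and MAE on
the test split only. Replications are summarised by mean ± sample sd and by
the minimum-RMSE "best state". Per-sample mean predictions are aggregated
over test memberships only, and every sample must be tested at least once.
The default replication count is 300; the test suite and acceptance script
use 20, which is enough to estimate means to the precision their assertions
need while keeping runtimes in minutes.

## Stage statistics

Classical one-way ANOVA from definitional sums of squares, with the linear
polynomial contrast (coefficients −1, 0, 1; defined for exactly three
equally spaced stages, more raise NotImplementedError) and its deviation
term. Post-hoc: Tukey HSD via the studentized-range distribution with the
Tukey–Kramer statistic, and LSD via the t distribution, both with
SE = √(MS_w(1/nᵢ + 1/nⱼ)). Levene's test is the mean-centred variant (ANOVA
on |x − group mean|), matching the statistics-package default the published
tables evidently used. Two-sample t supports pooled (df = n1+n2−2) and
Welch–Satterthwaite forms, with 95% CIs. All tail probabilities come from
scipy's F, t and studentized-range distributions (vendor accuracy well below
the 1e−6 contract).

`groups_from_summary` reconstructs deterministic group vectors with exactly
a given set of means and within-group sum of squares (alternating ±
patterns, scaled), so published ANOVA/post-hoc tables can be re-derived
through the same code paths that handle raw data. Values that depend only on
the summaries (df, MS_w, standard errors, Tukey/LSD p of the printed mean
differences) are reproduced to print precision; values that depend on the
unrounded raw means (F to its third decimal) agree to the rounding of the
published means.

## Synthetic data generator

The generator emulates the study design, not apple physics. Chemistry:
TA ~ N(stage mean, 0.134) truncated above 0.05, taste index ~ N(stage mean,
7.52) truncated above 1, TSS := taste_index × TA so the ratio identity holds
by construction. Stage means (0.5557/0.5649/0.5808; 22.12/22.62/21.24) and
within-stage sds (√0.018, √56.49) reproduce the published chemistry table
and its non-significant stage effect.

Spectra: absorbance = smooth fixed background (pigment and water features) +
Gaussian bands whose amplitudes are linear in standardised latent variables:
the two chemistry latents and six nuisance factors u1–u6. Each property has
one signal band contaminated by dedicated nuisance factors, each of which
also drives its own clean band; predicting the property therefore requires
exactly the planted channel set (signal band + its interferents), which is
what makes recovery tests sharp. Reflectance R = 10^−A is corrupted by
per-sample log-normal multiplicative scatter (σ = 0.05), optional per-sample
baseline slope (off by default), and additive Gaussian noise (σ = 0.002,
giving band SNR well above 20).

Band centres sit exactly on the 1.2 nm grid near the third-overtone region
(864.8/872.0/890.0 nm for TA; 941.6/958.4/966.8/974.0/981.2 nm for taste)
and widths are 1.5 nm. These choices are deliberate idealisations: off-grid
centres make "the" key channel ambiguous between two neighbours, and wider
bands combined with window-5 median smoothing smear 7-nm-spaced bands into
each other, moving the statistically optimal read-out channels ±2 indices
off the centres. Real NIR bands are far broader and overlapping — which is
precisely why real key-wavelength sets are reported as regions, and why
passing recovery tests here demonstrates algorithm correctness, not
instrument-level validity.

The `tiny` fixture (3×6 samples, 10 channels at 5 nm) exists for
enumeration-scale oracle tests (C(10,2) = 45 subsets). It is evaluated on
plain absorbance: on a 10-channel grid the SNV statistics are dominated by
the planted bands themselves (per-spectrum mean/sd become informative,
making off-band channels spuriously optimal) and a window-5 median spans
half the grid. The full chain is exercised on the 751-channel fixtures.

What the generator does *not* model: instrument line shape, temperature
effects, wavelength-dependent noise, band overlap, non-linear detector
response, biological covariance between TA and TSS beyond the constructed
ratio. Passing tests on this generator shows the algorithms recover known
structure under scatter and noise; it says nothing about prediction accuracy
on real fruit.

## Degenerate inputs and tie-breaks

Constant spectra are rejected by SNV (zero variance); constant y is rejected
by PLSR and by the metric computation (Pearson undefined); a constant
*predictor* is assigned R = 0 rather than NaN. Duplicate indices after a
firefly move are repaired to the nearest free index, scanning outward
alternately below/above. PLSR stops extracting components when residual
covariance falls below 1e−12 and treats the remaining components as dead
(zero loadings). `select_ncomp` and the selection parsimony rule both break
ties toward the simpler model.

## Known limitations

* The 19-name trainer vocabulary is implemented as 5 algorithms; the rest
  raise a registry error.
* `trainbr` selects its penalty from a small fixed grid rather than by
  evidence maximisation.
* The firefly recovery guarantees hold for the generator's default band
  layout; substantially overlapping bands make exact channel identity
  ill-posed for any selector.
* Replicated evaluation retrains from scratch per replication; there is no
  cross-replication ensembling except the mean-prediction aggregation.
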