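# Methods

`nirstack` implements a two-stage chemometric framework for Vis-NIR
reflectance spectra of organic fertilizer: wavelength selection by binary
particle-swarm optimization (BPSO) whose objective is the cross-validated
accuracy of a stacked *classifier* on the nine fertilizer varieties, followed
by a stacked *regressor* that predicts nitrogen (N) and organic matter (OM)
jointly from the selected channels. Because the original 810-spectrum dataset
is not publicly deposited, the package includes a synthetic generator that
reproduces the study design with known ground truth; every quantitative claim
in the test-suite is made on that generator.

## Data model and preprocessing

A `SpectraDataset` holds an `n x d` reflectance matrix on a strictly
increasing wavelength grid (canonical: the 2151 integer-nm channels
350–2500 of the resampled ASD output) with per-spectrum metadata: variety
(1–9), sample id, replicate id (1–3), and the two reference concentrations.
Replicates of one sample must agree on variety and concentrations; this is
validated at construction.

Preprocessing follows standard calibration practice:

* **Savitzky–Golay smoothing** (default window 11 channels, polynomial
  order 2) on each spectrum. The filter reproduces polynomials up to the
  chosen order exactly and is linear; both properties are tested. Smoothing
  is appropriate only on densely sampled grids: on the 64-channel benchmark
  grid (~34 nm spacing) a moving polynomial window smears narrow absorption
  bands into neighboring channels, so the benchmark pipelines skip it.
* **Standardization** to zero mean and unit sample SD (ddof = 1) per
  channel, fit on the calibration set only and applied to the prediction
  set — scaling never sees held-out rows. Channels with zero variance raise
  an error naming the wavelength.
* **Splitting**: the prediction set holds `ceil(fraction * n)` spectra,
  stratified by variety through largest-remainder apportionment; at
  fraction 0.25 the 810-spectrum design yields exactly 607 calibration and
  203 prediction spectra. Replicates are independent rows by default (the
  810-spectrum accounting); `group_by_sample=True` allocates whole samples
  to prevent replicate leakage across the split.
* **Channel binning** (block averaging, default width 10) is available to
  make wrapper selection tractable on the full grid; masks found on the
  binned grid expand blockwise back to full resolution.

## The two stacked generalizations

Both stacks are Wolpert stacking: each base learner produces out-of-fold
predictions via an internal (stratified, for classification) k-fold on the
training rows; the meta learner trains on those out-of-fold predictions;
base learners are then refit on all rows. Test rows never enter base or
meta training — verified by a permutation test (stack CV accuracy on
shuffled labels stays at chance).

* **FSGC** (classification): base learners SVM (RBF, C = 1, gamma = 0.01),
  1-nearest-neighbor, logistic regression (C = 100, newton-cg), and a ridge
  classifier (penalized least squares on one-hot labels, strength 0.1) —
  the four screening survivors; meta learner logistic regression
  (C = 1, newton-cg; lbfgs needs hundreds of iterations on the
  ill-conditioned probability meta-features and was ~3x slower for the same
  predictions). Meta-features are per-class probabilities where a family
  provides them and decision scores otherwise.
* **SSGR** (regression): base learners SVR, KNN, MLP (tanh, alpha = 1e-4,
  one hidden layer of 100 units, adam, max 2000 iterations) and ridge
  (strength 0.1); ridge meta learner. Base members are fit per target; the
  meta ridge sees all base predictions for both targets jointly, so N and
  OM are predicted simultaneously.

Base hyperparameters default to grid-search optima reported for the original
data and are exposed through `ModelSpec`; `grid_search_cv` re-tunes any
family with stratified/plain 5-fold CV and deterministic first-in-grid tie
breaking. A single stacking layer is used; the stack builders accept
arbitrary member lists for nesting or ablation. The screening step
(`benchmark_candidates` → `select_stack_members`) ranks families by
(accuracy desc, time asc), which drops MLP when accuracies tie — the same
logic that produced the four FSGC members.

## Wavelength selection

Particles carry a bit per channel. Per iteration and particle:

    v_ij <- w v_ij + c1 q (x^pb_ij - x_ij)/dt + c2 r (x^sb_ij - x_ij)/dt
    x_ij <- 1  iff  r_ij <= S(v_ij),   S(v) = 1/(1 + e^{-v})

with q, r ~ U[0,1] drawn once per particle per iteration (a
`per_coordinate_qr` flag enables per-dimension draws; both variants behave
similarly on the benchmarks here). Personal and swarm bests update under
*strict* improvement, so the best-so-far fitness history is monotone and
ties keep the incumbent. Velocities are clamped to ±v_max (default 6);
positions that come out all-zero are redrawn once and then repaired by
forcing the most probable bit on. When velocities saturate while position
diversity (normalized mean pairwise Hamming distance) has collapsed below
0.01, the swarm is reset: velocities redrawn uniformly, each position bit
resampled from {personal best, swarm best, fresh coin} with probabilities
(0.25, 0.25, 0.5); bests survive the reset. One increasing-logistic
convention is used throughout; a `paper_literal_sigmoid` flag restores the
decreasing form some formulations print.

The default fitness is `J(mask) = alpha P + (1 - alpha)(1 - N_f/N_t)` with
alpha = 0.5, where P is the k-fold CV accuracy of the FSGC restricted to the
masked channels (the PSO-SVM baseline swaps in a single SVM). J is
deterministic given its seed, so fitness values are memoized per bit
pattern. Swarm defaults follow the tuned study settings — 50 particles,
10 iterations, alpha 0.5 — with standard BPSO dynamics elsewhere (w = 0.9,
c1 = c2 = 2, dt = 1). The pipeline evaluates the fitness with 3 CV folds
(the stand-alone `PSOConfig` default is 5): fold count is not a reported
setting, and 3 folds keep a full 50 x 10 run on one CPU near the timescale
of the original experiment without changing which subsets win.

`exhaustive_best_subset` enumerates all non-empty masks for d ≤ 16 channels
and is the oracle the swarm (and the GA baseline) is scored against: on the
8-channel benchmark the swarm attains the exhaustive optimum in ≥ 18/20
seeds.

**Known limitation — subset compactness at the study's budget.** 500
fitness evaluations are enough for the swarm to find the accuracy-relevant
channels (it typically captures 7 of the 8 truly informative channels of
the 64-channel benchmark) but not to exploit the weak per-bit size pressure
(1 - alpha)/N_t ≈ 0.008: masks stabilize with 13–18 redundant channels
still selected. Jaccard overlap with the ground-truth informative set
therefore plateaus near 0.3 under the default budget; recovering a compact
subset on D ≳ 64 requires either more iterations or a stronger compactness
weight than the tuned alpha = 0.5.

## Regression evaluation

`evaluate_model` reports, per property, R²c/RMSEC on the calibration set
and R²p/RMSEP on the prediction set, plus a **pseudounivariate limit of
detection** LOD = 3.3 s_res/|b1|, where b1 and s_res are the slope and
residual SD of the least-squares line of predicted on true concentration
(the 3.3 multiplier is conventional and configurable; no single LOD
definition is standard in multivariate calibration, so these LODs are
internal figures of merit, not comparable to other instruments' values).

The selector comparison harness scores each selector (wrapper PSO with
stack or single-SVM fitness, generational GA, lasso, and a no-selection
baseline) through one shared multi-output ridge (strength 0.1). Selection
sees calibration rows only. Because N and OM live on different scales, the
single R²/RMSE per row standardizes each target to unit SD on the
calibration truth and pools the standardized residuals. GA defaults mirror
the swarm budget (population 50, 10 generations, crossover 0.9, mutation
1/D, tournament 3, elitism 1).

PLS (`fit_pls`) standardizes features, centers/scales targets internally
and back-transforms predictions; calibration R² is non-decreasing in the
number of latent variables (tested). Lasso selection standardizes features
and targets and keeps channels with nonzero coefficients for either target,
choosing the penalty by 5-fold CV over a log grid when not given.

## Synthetic data generator

The generator emulates the study design: 9 varieties x 30 samples x
3 replicates (810 spectra) on the canonical grid. Concentrations are drawn
Normal(mean, SD) per variety from the published summary table. The min/max
rows of that table are internally inconsistent with any bounded
distribution for several varieties (e.g. variety 1 OM: SD 0.083 exceeds
half the printed range, 0.075), so no truncation is applied and min/max are
kept as metadata; variety 8's wide rows (N SD 1.117, OM SD 6.348) are
generated as printed.

Spectra follow a Beer–Lambert-style model:

    reflectance = baseline(λ) + shift + Σ_k (depth_k + a_k N + b_k OM) G_k(λ) + ε

with Gaussian bands G_k, per-spectrum baseline shift ~ N(0, 0.01)
(loading-density/particle-size scatter), and channel noise
ε ~ N(0, 0.005). Couplings are **universal** across varieties — the same
absorber has the same sensitivity everywhere, so one global calibration
exists — with small variety-specific "matrix effect" depth offsets
(±0.002–0.003). All varieties share two N-coupled bands at 1930 and
2100 nm (the 1887–2200 nm absorption every variety shows) and an OM-coupled
band at 1520 nm; odd varieties add a visible-range N band at 500 nm and an
uncoupled water band at 970 nm; varieties 1, 3, 8, 9 add a signature peak
in 1462–1535 nm that carries a weak OM coupling (these peaks are organic
absorption features); variety 9 adds its three uncoupled signature bands at
844, 1733 and 2310 nm. Band σ are sized so that every coupled band's
1%-of-peak support lies inside the nominal informative windows (400–600,
1400–1600, 1800–2300 nm). Coupling magnitudes (a ≈ −0.015…−0.04 per N unit,
b ≈ −0.002…−0.004 per OM unit) put the between-variety band-depth spread at
roughly 20x the channel noise: stacked models reach R²p ≳ 0.995 as in the
original study while selectors still face 2000+ uninformative channels.

Class information deliberately lives in the same channels as the
concentration signal (band depths differ across varieties through their
concentration means and signature peaks; baselines are common), so a
classification-driven wavelength selector is steered toward the channels a
regression needs — the premise of the two-stage framework.

`ground_truth_mask` marks channels where any coupled band's Gaussian weight
exceeds 1% of its peak; `generate_dataset` returns it next to the data for
selector-recovery scoring. Presets: `paper` (810 x 2151), `reduced`
(90 x 64, with exactly 8 informative channels, structured channels placed
on band supports and filler channels kept clear of them) and `tiny`
(90 x 8, for exhaustive-search oracles). What the generator does **not**
emulate: scattering and particle-size physics beyond the additive shift,
instrument drift, water-vapor artifacts, wavelength-dependent noise, and
any nonlinear detector response — so passing tests show the pipeline
recovers the model's own signal structure, not that it would meet the same
numbers on field spectra.

## Problem sizes used in the test-suite

The default suite runs the full pipeline once on the paper preset with the
spectra binned 2151 → 216 channels for the selection stage (fitness CV with
3 folds), the selector-recovery check on the reduced preset, and the
exhaustive-oracle comparisons on the tiny preset with a 2-member stack
fitness shared through one memoized cache. These sizes are the package's
benchmark configuration; all thresholds are stated in the tests themselves.

## Numerical choices

* Sample SD (ddof = 1) throughout standardization; population formulas only
  inside third-party fits.
* Logistic/MLP iteration caps (500 / 2000) are convergence safeguards; MLP
  and forests are seeded from the stack seed plus the member index, so a
  fitted stack is a pure function of (spec, X, y, seed).
* Grid-search and stack CV use shuffled (Stratified)KFold seeded from the
  caller; `fit_stack` caps internal folds at the smallest class count so
  every class appears in every training fold.
* The sigmoid is evaluated branch-wise to avoid overflow beyond |v| ≈ 700.
* Reflectance is clipped to (0.001, 1.2) at generation; the defaults keep
  spectra far from both bounds.
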