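# Methods

This note documents the models, parameters and design choices behind
`drsmargin`, in the order data flows through the pipeline.

## Forward model of the synthetic spectra

Each probed location has a tissue composition
f = (f_fat, f_water, f_collagen, f_blood), a convex vector (closure is
asserted on every draw), plus a blood oxygen saturation S. Reflectance is
a semi-empirical modified Beer–Lambert law on each spectrometer grid
(visible 200–1160 nm, NIR 900–1750 nm, both sampled at 2 nm):

    R(λ) = g · exp(−ℓ · μa(λ)),
    μa(λ) = Σ_i f_i · μa,i(λ),   blood split S : (1−S) into HbO₂ / Hb.

The effective path length ℓ is wavelength-independent (default 1, gain
g = 1). This is intentionally not diffusion theory or Monte-Carlo photon
transport: the analysis downstream needs class-structured band shapes,
not radiometric accuracy.

Chromophore absorption curves are sums of Gaussian bands with documented
centers (fat 930/1210/1720 nm; water 970/1190/1450 nm; collagen
1030/1200/1500 nm; hemoglobin Soret and Q-bands plus the 760 nm deoxy
band). Only the band *locations* matter to the shape features; amplitudes
were set once to give visually plausible reflectance levels.

### Composition priors

Per-class Dirichlet priors over f (concentration 60): healthy mean
(0.60, 0.20, 0.13, 0.07), tumor mean (0.25, 0.42, 0.25, 0.08) — healthy
breast tissue is fat-dominated, tumor water/collagen-dominated. In vivo
locations draw S ~ U(0.70, 0.95), ex vivo S ~ U(0.10, 0.40) (perfusion
stops after excision). These priors are stand-ins chosen for realism,
**not** estimates of any clinical cohort: the default overlap was
calibrated once so that cross-validated MCC on the default cohort lands
in the 0.5–0.8 range that published DRS margin classifiers report,
rather than in a saturated regime where every classifier is perfect.
An optional second malignant mode (`tumor_mean_dcis`, off by default)
can emulate intraductal disease with a composition between the invasive
and healthy means.

### Cohort structure and noise

Defaults: 100 patients × 6 locations, 10% of locations malignant, 50/50
in vivo / ex vivo. All locations of a patient share a multiplicative
log-normal composition perturbation (σ = 0.15) — the random effect that
makes patient-grouped CV the correct design. Each fiber perturbs the
composition again (σ = 0.05, five fibers probe overlapping volumes);
each of the three replicates differs only by log-normal gain jitter
(σ = 0.01) and additive Gaussian noise (SD 0.006), with the additive SD
multiplied by 12 inside 350–400 and 1600–1700 nm. That inflation is what
makes the extremity trim meaningful.

For malignant locations a central margin distance d ~ U(0, 2) mm is
drawn and the tumor area percentage follows
p = clip(100·(1 − d/2) + ε, 0.5, 100), ε ~ N(0, 8). The lower clip is
0.5 rather than 0 because the label contract is *malignant ⇔ p > 0*; a
draw clipped to zero would silently flip the label. Min/max distances
are the central distance ± U(0, 0.3) mm (clipped to the band), and the
mean distance is exactly (min + central + max)/3. The measured
composition mixes tumor into healthy tissue with weight
w = 0.3 + 0.7·p/100 (`tumor_signal_floor = 0.3`), so deep, low-percentage
tumors produce genuinely weaker spectral contrast — the mechanism behind
the negative distance-vs-percentage misclassification trend.

The documented low-overlap configuration (`well_separated_config`)
widens the prior gap (healthy (0.65, 0.18, 0.12, 0.05) vs tumor
(0.15, 0.45, 0.32, 0.08), concentration 120), reduces all noise terms,
and raises the signal floor to 0.4. It is a positive control for
pipeline wiring, not a clinical claim.

All randomness flows from a single cohort seed through one
`numpy.random.Generator`; CV planning, undersampling and model seeds are
derived sub-streams, so identical configurations are bit-identical end
to end.

### What the simulator does not emulate

Instrument spectral response, spectralon calibration, probe-pressure
effects, spatial heterogeneity within a probed volume beyond the
per-fiber jitter, and real H&E appearance. Passing tests therefore
demonstrate that the *pipeline* is correct and leakage-free and that its
statistics behave as designed — not that the reported performance
transfers to clinical spectra.

## Preprocessing

Order is fixed: average → stitch → trim → MSC.

- Replicate averaging is the pointwise mean of the three acquisitions.
- Stitching resamples both ranges to a uniform 1 nm grid (200–1750 nm)
  by linear interpolation and crossfades linearly across the 900–1160 nm
  overlap (vis weight 1 → 0). Hard `vis-priority` / `nir-priority`
  handovers are available by configuration; the crossfade default avoids
  step artifacts at the handover.
- Trimming keeps the half-open window [400, 1600) nm: samples at
  400…1599 nm, exactly 1200 wavelengths. The half-open convention is
  what realizes that count on a 1 nm grid.
- MSC fits x ≈ a + b·m by OLS over all 1200 wavelengths against the
  reference m (no sub-window) and returns (x − a)/b; slopes below 1e-8
  in magnitude raise a degenerate-spectrum error instead of dividing.
  The reference is the mean of the *training-fold* spectra only and is
  frozen into the model artifact — a full-dataset mean would leak test
  information under cross-validation.

## Shape features

For each of the 16 NIR wavelength ranges (1213–1248, 931–1195,
1224–1331, 1142–1225, 1021–1102, 999–1034, 1395–1430, 1404–1437,
1467–1502, 1121–1401, 932–967, 1112–1147, 1201–1236, 1382–1574,
883–1149, 926–1149 nm; a configuration, not a constant) and each fiber:

1. chord slope between the intensity argmaxes of the first and last 25%
   of the range (quartiles by wavelength span; argmax ties take the
   smaller wavelength);
2. maximum of chord(λ) − spectrum(λ) between the chord endpoints — the
   ranges bracket absorption dips, which sit *below* their chord, hence
   the deficit orientation (absolute-difference mode is available);
3. the wavelength of that maximum (first occurrence on ties);
4./5. inflection wavelengths left/right of it: zero crossings of the
   Savitzky–Golay second derivative (window 11 samples, order 2, both
   configurable), located by linear interpolation, clamped to the range
   edge (with a flag) when no crossing exists.

16 ranges × 5 operators = 80 features per fiber; five fibers contribute
independent blocks, 400 features per location. Adding a constant to a
spectrum changes nothing; scaling by k > 0 scales slope and deficit by k
and leaves all wavelength features unchanged.

## MRMR selection

Features are discretized by equal-frequency binning (10 bins; massive
ties collapse bins). Mutual information is the plug-in estimate on the
empirical joint distribution, in bits — which makes the
feature-equals-balanced-label case exactly 1 bit. Greedy forward
selection uses the difference (MID) score
MI(f; y) − mean_{s∈S} MI(f; s); the quotient scheme (MIQ) is a switch.
The score recorded at selection time is thresholded at ≥ 0.015
(inclusive). Selection runs inside each training fold; the reported
"optimum" list is the modal selection (features chosen in ≥ half the
folds, ordered by frequency then mean rank).

## Models and cross-validation

Patient-grouped repeated 5-fold CV, 20 iterations by default: per
iteration, patients are dealt round-robin into folds after shuffling
within malignant/healthy strata (a patient is malignant if any of their
locations is), so folds are balanced, non-empty, and each holds
malignant patients whenever at least five exist. The test set of a fold
is the in vivo locations of its patients; the training set is the
regime-filtered locations of all other patients. Train/test patient
disjointness is asserted on every fold.

Hyperparameters (configuration, defaults following common practice):
linear SVM C = 1 on standardized features; quadratic SVM = polynomial
kernel degree 2, coef0 = 1; weighted k-NN k = 10 with inverse-distance
weights; RUSBoost 100 rounds, learning rate 0.1, tree depth ≤ 5, 1:1
resampling target. SVM scores are Platt-calibrated (logistic fit on
training decision values) so thresholds are comparable across model
families; k-NN and RUSBoost scores are native probabilities / vote
shares. Per-iteration MCC is computed from predicted labels at the 0.5
score threshold, each family's canonical decision rule.

RUSBoost per round: keep every minority example, sample majority
examples without replacement with probability proportional to current
boosting weight until 1:1, fit a depth-limited tree with the drawn
weights, measure the weighted error ε on the *full* training set,
discard and resample rounds with ε ≥ 0.5 (up to 10 retries, then stop
boosting), update weights AdaBoost-style with α = lr·ln((1−ε)/ε) (ε
clipped to [1e-10, 1−1e-10]). The score is the α-weighted vote share,
so 0.5 is the classical weighted-majority decision. A degenerate input
with no class information yields a constant score whose value depends
on the surviving rounds rather than a calibrated 0.5 — hard votes carry
no confidence.

## Evaluation

MCC follows the confusion-matrix formula with the conventional value 0
when a marginal total vanishes. ROC curves sweep unique scores (ties
grouped into one step) with trapezoidal AUC. Two thresholds are
reported, because both are legitimate operating rules and they need not
coincide: the minimum expected-cost ROC point
(cost_fp·FPR·(1−π) + cost_fn·FNR·π, default unit costs, π = empirical
test prevalence, ties toward higher sensitivity) and the MCC-maximizing
threshold. Headline sensitivity/specificity uses the cost-optimal point;
their 95% CIs are 2.5–97.5 percentiles of the iteration-level values —
the only resampling structure the repeated-CV design provides (a
bootstrap over locations is available by configuration). The
misclassification analysis classifies each malignant in vivo location by
its mean cross-validated score at the operating threshold and reports
(mean margin distance, tumor percentage, correct?) triples plus their
Pearson correlation (absent with fewer than two malignant locations).

## Histology quantification

Synthetic sections are rendered at 20 µm/pixel with a straight ink line
and tissue below: the tumor occupies the deepest p% of the 2-mm band as
a full-width strip (top edge at depth 2·(1−p/100) mm, consistent with
the generator's distance-percentage relation), and the healthy remainder
splits into fat/connective columns. The palette gives fat the highest
green channel and tumor the lowest.

Quantification mirrors the rendering assumptions without reading them:
the band is the set of pixels within 2 mm of the rasterized polyline on
the tissue side (the half-plane, relative to the first-to-last chord,
holding most non-background pixels); tumor percentage comes from the
annotation mask; remaining tissue pixels split at green > 200/255
(calibrated once against the palette, configurable); distances are read
off a Euclidean distance transform of the tumor mask at polyline samples
— min/max over samples (max capped at the band depth), central at the
arc-length midpoint, mean = (min + central + max)/3. Everything is 2-D
area arithmetic; no volumetric correction is attempted. Round-trip
accuracy is within ±2 percentage points of the generating truth with
exact labels; distance oracles hold to one pixel.

## Problem sizes and known limitations

The test suite and the acceptance script run reduced protocols chosen as
the package's own defaults for fast iteration: the recovery check uses
the low-overlap cohort with 5 CV iterations; the model-family comparison
uses 3 iterations per seed over five seeds. Full 20-iteration runs are a
single argument away (`fit(n_iterations=20)`).

Known limitations:

- On the default simulated cohort the four model families perform within
  a few MCC points of each other, and the margin-based SVMs are usually
  on top; the pronounced RUSBoost advantage reported on clinical DRS
  data does not reproduce here. The simulated classes differ by a smooth
  shift in a low-dimensional composition space, so the Bayes boundary is
  nearly linear in the selected features and the 10:1 imbalance costs
  convex margin classifiers only a moderate sensitivity penalty —
  whereas boosted trees pay for their extra sensitivity with false
  positives that MCC, at ~9% prevalence, punishes heavily. Reproducing
  the clinical ordering would require distributional structure the
  source data alone defines.
- Percentile CIs over 20 iterations are CIs of the iteration-level
  metric distribution, not of the patient population.
- The stage-wise CLI subcommands (`preprocess`, `features`, `select`)
  operate dataset-wide with a full-dataset MSC reference and are meant
  for exploration; the leakage-safe per-fold versions of those stages
  run inside `run-all` and `fit()`.
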