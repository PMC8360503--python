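# Methods

`cpdecode` implements a time-resolved sensor-space decoding analysis of a
10-step /ba/–/da/ speech continuum measured (or here: simulated) with
306-channel MEG under two listening tasks — passive exposure with a visual
cover task, and active labeling of each token as *ba* or *da*. This note
documents the models and procedures, the synthetic data the pipeline is
exercised on, the numerical choices, and what passing tests do and do not
establish.

## Decoding model

All decoding is binary linear classification per time point. For a pair of
conditions (two continuum steps, or the two percept labels):

1. **Stratified folds.** Trials of each condition are assigned at random to
   k = 5 folds (sizes within a condition differ by at most one). One fold is
   held out; the other four train the classifier. All five rotations are
   scored per repetition, and the whole procedure is repeated `n_reps` times
   (default 100) with fresh fold assignments; accuracies are averaged.
   A config flag (`full_rotation=False`) restores a literal single
   train/test split per repetition.
2. **Multivariate noise normalization** ("epoch" method). Residuals are
   trial minus condition mean at each time point; per-time-point residual
   covariances are averaged over time points and conditions, estimated from
   the *training* folds only. The estimate is regularized by shrinkage
   toward a scaled identity, `(1−λ)S + λ·tr(S)/C·I`, with λ the analytic
   Ledoit–Wolf optimum computed from the pooled residuals (or a fixed value
   from config). Training and test data are both multiplied by the
   symmetric inverse square root `S^{-1/2}` of the training covariance;
   the symmetric root is orientation-free, matching the normalization
   framing (a Cholesky factor would impose a channel ordering).
3. **Summary trials.** Same-condition trials within each fold are averaged
   into one summary trial per condition per fold (8 real trials each for
   stimulus decoding; ~class-count/5 for percept decoding). Because
   whitening is linear, summaries are averaged first and whitened after —
   the results are identical and an order of magnitude cheaper.
4. **Classification.** A linear maximum-margin classifier (C-SVM, C = 1) is
   trained per time point on the whitened training summaries and scored on
   the held-out summaries. The dual problems (one per time point, ~8
   training points each) are solved by a batched SMO with most-violating-
   pair selection, vectorized across time points; tests verify exact
   agreement with libsvm (sklearn `SVC`) decision values on random
   problems. A test decision value of exactly 0 contributes 0.5 — unbiased
   at chance.

Pairwise decoding of all C(10,2) = 45 step pairs yields a 10 × 10
dissimilarity (RDM) time series per subject, task, and sensor subset
(all 306 channels, or the 144-channel left/right hemisphere groups; the 18
midline channels belong to no hemisphere subset). In `decode_all_pairs`
the fold assignment, noise covariance (averaged over all ten conditions'
residuals, as the epoch method prescribes) and summary trials are shared
across pairs within a repetition/rotation; each pair's classifier sees only
its own two conditions. Percept decoding (*ba*- vs. *da*-labeled trials)
uses the identical machinery with percept labels and no class equalization.

**Activation patterns.** Classifier weights are backward-model extraction
filters; for topographic interpretation they are transformed to
forward-model activation patterns as `A = Σ_x · W · Σ_s^{-1}` (data
covariance times weights times inverse latent covariance). For display the
per-window average is divided by its standard deviation (arbitrary units).

## Preprocessing

Epochs (−200…1000 ms) are baseline-corrected per trial and channel over the
prestimulus window, low-pass filtered at 15 Hz, and z-normalized per sensor
with baseline statistics. The filter is a linear-phase Hamming-window FIR
(transition band 10 Hz, ~53 dB single-pass stopband attenuation) applied
forward–backward (zero phase, attenuation doubled) with even-reflect
padding; the implementation is a single FFT convolution with the taps'
autocorrelation, verified against `scipy.signal.filtfilt` to machine
precision. Z-normalization pools baseline mean and SD across trials and
baseline samples per channel (stabler for 306 channels); a `per_trial`
switch computes them per trial instead. Normalization makes the pipeline
invariant to per-channel rescaling, which is what lets magnetometers and
planar gradiometers (units apart by orders of magnitude) share one pattern
vector.

## Group statistics

Above-chance and paired contrasts use one-sided sign-flip permutation tests
with cluster-size inference over the full epoch. Subject curves are flipped
around the null value (50% for accuracy, 0 for paired differences) at
random (5,000 permutations by default); per-time-point p-values are
`(1 + #{perm ≥ obs})/(1 + n_perm)` so p is never zero. Contiguous time
points with p ≤ 0.05 form clusters; each observed cluster's length is
referred to the permutation distribution of the **maximum** cluster length
per permutation map, which controls familywise error (the pooled-cluster
null is available via config). The direction of every test is an explicit
argument. One property worth knowing: for very strong, temporally uniform
effects the sign-flipped maps reproduce the effect in the ~5% of
permutations with predominantly positive signs, so cluster p-values
saturate near the cluster-defining alpha instead of reaching the 1/(n+1)
floor; this is inherent to the procedure, not an implementation artifact.

## Representational similarity analysis

Two behavioral model RDMs are built from the identification data averaged
across subjects, both on a 0–100 scale:

* **Perceptual**: `|%ba(i) − %ba(j)|` — distance in labeling.
* **Ambiguity**: `|consistency(i) − consistency(j)|`, where consistency
  maps the labeling proportion to 100 (same label on every trial) through
  0 (labeled *ba* on exactly half of trials). Only those two anchors are
  fixed by the definition; the map between them is linear here,
  `200·|prop_ba − 0.5|`, and pluggable via `consistency_fn`.

Neural–model correspondence is the partial Spearman correlation of the
45-pair vectors (mid-ranks for ties), each model partialling out the other,
computed per time point on the subject-averaged neural RDM and then
averaged within windows (partial-then-average, not average-then-partial).
Window-level inference bootstraps subjects with replacement (5,000 samples
by default): per sample the neural RDMs are re-averaged per task and both
models are rebuilt from the resampled behavior; task (mean over models of
active − passive), model (mean over tasks of perceptual − ambiguity, sign
convention explicit) and interaction statistics are formed per window, and
two-sided p-values are twice the smaller zero-crossing fraction, assessed
against the Bonferroni-corrected α = 0.017 for three windows. Windows
default to the significant percept-decoding clusters of the same run.

## Representational geometry

Group-average RDM series are averaged within 80-ms windows stepped by
20 ms. Each windowed RDM is embedded in two dimensions by nonmetric MDS
(SMACOF with monotone regression, best of 10 random initializations);
goodness of fit is Kruskal stress-1 computed from the isotonic regression
of embedding distances on the input dissimilarity order. k-means (squared
Euclidean, 50 restarts) partitions the 2-D embedding — clustering operates
on the embedding, as a config-flagged alternative to direct-RDM clustering
— and the mean silhouette value on the embedding validates each k. For
display, cluster identities are aligned so that the cluster containing
stimulus 1 is always cluster 0.

## Synthetic data generator

No recorded MEG accompanies this analysis, so the generator defines the
study conditions end to end. It emulates:

* **Design**: 102 helmet locations × (1 magnetometer + 2 planar
  gradiometers) = 306 channels, with 144/144/18 left/right/midline
  channels; passive runs of 43 tokens per step with 3 visual-target tokens
  per step discarded (400 analysis trials, 40/step), active runs of
  40 tokens per step; epochs −200…1000 ms.
* **Behavior**: per-trial *ba*/*da* draws from a logistic identification
  function with boundary 5.5 and slope 0.5 continuum steps — a sharp
  category boundary between steps 5 and 6 with substantial ambiguity at
  those two steps. The same draws label the simulated active epochs, so
  behavior and percept labels agree trial for trial.
* **Evoked structure**: each trial is a condition template plus noise. The
  template lives in a 12-dimensional orthonormal spatial basis (10
  stimulus-unique patterns, a phonemic-category axis weighted by
  `prop_ba − 0.5`, an ambiguity axis weighted by consistency/100). Time
  courses: a gamma-shaped onset response rising at 60 ms and peaking at
  130 ms that is sustained and then decays (raised-cosine, 120 ms) at the
  maintenance offset; the category component is transient (decays by
  500 ms); the ambiguity component ramps up from 350 ms and persists to the
  maintenance offset. The two presets differ **only** in maintenance
  offset: ~450 ms ("passive-like") vs. ~900 ms ("active-like"), producing
  the longer active information maintenance the analysis is designed to
  detect.
* **Noise**: zero-mean Gaussian with a full random SPD spatial covariance
  (condition number 100, fixed per subject), which makes the noise
  normalization stage consequential. `snr` is the ratio of the mean evoked
  template norm at the response peak to the per-channel noise SD; it is
  referenced to the peak so both presets share the same early SNR. The
  default snr = 0.15 with unit identity/category gains and ambiguity gain
  2 was chosen once to give peak overall pairwise decoding in the low-60%
  range with late-window decoding a few points above chance — magnitudes
  typical of sensor-space MEG decoding — and is not adjusted per test.
* **Subject variability**: each subject's 12-dimensional pattern basis is
  rotated by a small random rotation (Cayley map, scale 0.1) that is a pure
  function of the subject id, so a subject's spatial geometry is identical
  across tasks.

What the generator does **not** emulate: temporally correlated (1/f)
sensor noise, eye-blink/cardiac artifacts, head movement, between-subject
latency differences, or any nonlinear mixing. Passing tests therefore show
that the pipeline recovers structure planted under these idealizations —
they do not certify performance on recorded MEG, where preprocessing
quality and artifact structure dominate.

## Numerical and design choices

* Seeds: every stochastic stage takes an explicit seed; pipeline stage
  seeds are derived from the global seed by hashing the stage name, so
  results are bit-reproducible for a given config and independent of stage
  order or thread count.
* SMO tolerance 1e-4 (KKT violation), max 2,000 iterations; problems that
  cannot move along their most-violating pair are deactivated. The
  intercept is the mean of `y − f` over free support vectors, or the
  midpoint of the KKT bounds when none are free.
* Ledoit–Wolf intensity is computed on at most ~4,000 pooled residual rows
  (strided subsample); the intensity estimate is stable well below that.
* Degenerate inputs: z-normalization refuses zero-variance channels by
  name; whitening refuses non-PD covariances; `partial_spearman` refuses
  constant vectors, while the time-resolved RSA maps isolated constant
  time points (possible in heavily quantized scaled-down runs) to NaN and
  excludes them from window means.
* Scaled-down problem sizes used by the test suite and the worked example
  (200 Hz simulation, 40-ms decoding grid, 8 subjects, 10 repetitions, 500
  permutations/bootstraps) are the package's own choice of desk-scale
  defaults for synthetic verification; full-scale constants (1 kHz, 100
  repetitions, 5,000 permutations/bootstraps, 24 subjects) remain the
  config defaults.

## Known limitations

* The generator's representational geometry is a stand-in: the real
  data-generating process of evoked fields is unknown in this detail, so
  all geometry parameters are configurable rather than asserted.
* Percept decodability in the simulation derives from the category axis
  and per-trial label draws; it does not model trial-by-trial neural
  variability *causing* the percept, only correlating with it.
* The sign-flip cluster test assumes exchangeable, symmetric subject
  deviations under the null; heavy-tailed between-subject effects can
  distort its calibration.
* Nonmetric MDS with 10 points in 2-D is underdetermined up to similarity
  transforms; only similarity-invariant quantities (stress, cluster
  memberships, silhouettes) are interpreted.
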