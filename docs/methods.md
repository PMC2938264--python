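# Methods

## Generative model

The simulator emulates a Geniom-style miRNA biochip: 904 probes (miRNA
and miRNA-star sequences), each printed in 7 replicate spots per array,
one array per blood sample.  All signal structure lives on the glog
(arsinh) scale, where the downstream variance-stabilised analysis
operates:

* per-probe baselines `baseline[p] ~ Normal(mu, tau)` (hyperprior, drawn
  once per probe set);
* per-sample abundance `g[p,s] = baseline[p] + effect[p]·1{case} +
  bio[p,s] + array[s]`, with biological noise `bio ~ N(0, bio_noise_sd²)`
  and a per-array offset `array ~ N(0, array_scale_sd²)` (a multiplicative
  array effect on the raw scale);
* per-spot values `g + spot_noise`, `spot_noise ~ N(0, spot_noise_sd²)`;
* raw intensity `sinh(g_spot) + background`, with the background drawn
  per spot from `N(background_mean, background_sd)` clipped at zero and
  recorded as the spot's background estimate.

Planting an effect of *e* glog units therefore reappears, after the full
preprocessing chain, as a shift of approximately *e* in the feature space
seen by the t-tests and the classifier — which makes planted effect sizes
directly interpretable and parameter recovery testable.

A *biological replicate pair* is two samples sharing the probe baselines
and differing in biological noise, array effect, spot noise and
background.  The model deliberately equates subject-to-subject and
replicate-to-replicate biological variability (one `bio_noise_sd`); no
separate subject level is published to calibrate against.

Case samples carry a histological subtype drawn with probabilities
21/24, 2/24, 1/24 (serous / endometrioid / solid, the composition of the
emulated 24-patient cohort); controls are always `none`.  Subtypes carry
no distributional difference by default; `GeneratorConfig` is the hook
for heterogeneity experiments.

## Calibration of the noise defaults

Two published replicate statistics pin the defaults: biological-replicate
profiles should show Pearson correlation ≈ 0.85 and between-replicate
variance ≈ 0.005 after preprocessing.  (Whether those statistics were
originally computed before or after normalisation is not stated; we
calibrate after the full chain and note the alternative.)  Under the
model, a replicate pair's preprocessed profiles are

    x[p] = baseline[p] + bio_x[p] + med_x[p],
    y[p] = baseline[p] + bio_y[p] + med_y[p],

with `med` the median of the 7 spot-noise draws, whose variance is
`c · spot_noise_sd²` with `c ≈ 0.210` (variance factor of the median of 7
standard normals, Monte-Carlo).  Writing `v = bio_noise_sd² +
c·spot_noise_sd²`:

* mean per-probe between-replicate variance `E[(x−y)²/2] = v`;
* across-probe correlation `rho = tau² / (tau² + v)`.

Both printed statistics constrain the two noise sds only through the
single combination `v`; the correlation additionally fixes the baseline
spread `tau = sqrt(v·rho/(1−rho)) ≈ 0.168`.  Consequently
`calibrate_noise` (a) fixes the bio/spot split of `v` at 50/50 — a neutral
choice, since no printed quantity distinguishes them — and iterates a
common multiplier on both sds against Monte-Carlo measurements through
the full chain until the variance target is met, and (b) verifies the
correlation, which is owned by `baseline_glog_sd`, erroring with
diagnostics when the configured baseline spread is inconsistent with the
targets.  The shipped defaults are the calibrated solution
(`bio_noise_sd = 0.05`, `spot_noise_sd = 0.1089`, `baseline_glog_sd =
0.1683`); the acceptance checks re-measure them over 1000 fresh pairs.

A consequence worth stating plainly: the two published statistics jointly
imply an across-probe signal spread of only ≈ 0.17 glog units, i.e. a
low-dynamic-range array.  Real miRNA arrays span several glog units of
dynamic range; the defaults reproduce the printed replicate quality, not
the dynamic range of real data.

## Preprocessing

**Background correction** subtracts the recorded per-spot background and
floors the result at a small positive constant so the later glog stays
finite.  The floor is data-driven — the 1st percentile of positive
corrected intensities — but clamped to `[0.5, 0.05 × median positive]`.
The cap matters: when an array's signals all sit far above background
(as the generator's do), a raw 1st percentile would land mid-signal and
censor genuinely low probes; a floor is meant to guard against −∞, not to
truncate biology.  Correcting twice raises, never silently re-subtracts.

**Summarisation** is the median over the 7 replicate spots, robust to a
single aberrant spot by construction.

**Normalisation** keeps VSN's two essential properties — between-array
affine calibration and variance stabilisation — in a compact fit.  The
reference profile is the probe-wise median across arrays (robust,
deterministic, order-independent), glog-transformed.  Each array is
calibrated by `h(y) = arsinh((s·y + o)/cofactor)` with `(o, s)` minimising
the transform-both-sides profile likelihood

    n · log( trimmed mean of (h(y) − ref)² ) − 2 Σ log h'(y),

by Nelder–Mead (trim fraction 0.25, so up to a quarter of outlying probes
cannot drive calibration).  The Jacobian term is not decoration: the
arsinh family has a nearly flat (s↓, o↑) valley along which the glog
scale is compressed, which shrinks residual noise and would bias
replicate variances low by ~15% if the fit minimised squared residuals
alone.  The log-derivative term makes pure rescaling exactly neutral, the
same device the original VSN maximum-likelihood fit relies on.  The glog
cofactor defaults to 1.0 (unidentifiable from the published analysis) and
is configurable.

Normalisation is fitted on summarised (not spot-level) values; the
published order of operations is ambiguous on this point and the medians
are the quantities the downstream statistics consume.  Applying a model
to arrays seen at fit time reuses their stored parameters (and reproduces
the stored training output exactly); unseen arrays are calibrated against
the frozen reference.  Re-normalising normalised output is rejected.

## Differential expression

Welch's unequal-variance t-test is the default (the safer choice when
group variances differ; the published analysis says only "unpaired
two-tailed parametric t-test"), with the pooled-variance Student form
selectable.  Positive t means the case mean exceeds the control mean;
`direction` follows that sign, and effect sizes are differences of glog
means, not raw-scale ratios.  Zero-variance/equal-mean probes get t = 0,
p = 1 by convention and are flagged.  Benjamini–Hochberg adjustment is
the standard step-up (delegated to statsmodels; the test suite holds it
against an independent brute-force construction).  Tables rank by
ascending p with ties broken by larger |t| then probe id, so output is
deterministic.  Shapiro–Wilk normality screening (per probe, per group,
both groups must pass) is advisory: it is reported, never gates the
t-tests, since the published analysis "verified" normality without
describing exclusions.

## ROC

One curve point per distinct threshold; AUC by trapezoid; tied scores
grouped.  `auc_rank_oracle` computes the exact pairwise Mann–Whitney
statistic (ties worth one half) and is the independent cross-check: the
two must agree to 1e−12 on any input.  Orientation is explicit and never
auto-flipped — an AUC below 0.5 is information about direction, not an
error.

## Classification engine

Stratified folds are the default (with 15 controls in 10 folds,
unstratified assignment can produce control-free folds); fold assignment
is seed-derived and deterministic, with bounded re-draws if an
unstratified training fold degenerates to a single class.  Inside every
fold, features are ranked by t-test p on the training columns only —
the ranking function's contract forbids access to held-out samples, and a
dedicated `leakage_probe` runs the deliberately wrong variant (rank once
on all samples) alongside the correct one to demonstrate the selection
bias on effect-free data.  Features are standardised with training-fold
statistics (mirroring e1071's default scaling without leakage); the
kernel machine itself is scikit-learn's SVC behind a narrow surface —
the package's own contribution is the resampling/filter/permutation
machinery around it.

Held-out predictions are pooled per pass, so `accuracy = (sens·n_case +
spec·n_control)/n` holds exactly; per-repeat pooled metrics are averaged
over repeats (the alternative — averaging per fold — is not used).  The
best grid cell maximises mean accuracy, with ties broken by smaller
subset, configured kernel order, then smaller cost.  The full published
grid (4 kernels × costs {0.01, 0.1, 1, 10} × subset sizes {10, 20, 40,
60, 100, 200} × 100 repeats) is the `CVConfig` default; test and demo
configurations are scaled down (typically 20 repeats, radial kernel,
subsets {10, 60}) as the package's working problem size.

**Permutation nulls** draw one fresh label permutation per run
(class sizes preserved — a permutation by construction) and re-execute
the entire pipeline, including per-fold re-ranking, under the permuted
labels; anything less does not produce a valid null for a
filter-inside-fold procedure.  Exceedance uses the add-one estimator
`(#{permuted ≥ observed}+1)/(runs+1)`.  Fold assignments are re-drawn per
run rather than reused (the published procedure does not say; re-drawing
is the more conservative null).

**Null behaviour, stated honestly:** on effect-free data this procedure
is chance-level *or slightly below* the majority-class proportion — the
well-documented anti-learning of feature selection under the null, which
the emulated study also exhibits (its permuted accuracy was far below the
majority proportion).  The engine's self-tests therefore check the
absence of *optimistic* bias (null accuracy at or below majority + noise,
leaky variant clearly above) rather than asserting a symmetric band.

## Screening arithmetic

Bayes' rule in closed form; an annual incidence quoted per 10^5 persons
is treated as the prevalence of a single annual screen — the only reading
consistent with the quoted sub-percent general-population PPV.
`prevalence_for_ppv` is the exact algebraic inverse (round-trip to
1e−12).  Values carry full precision; percent rounding to one decimal
happens only in the reporting layer.

## What the synthetic data does and does not show

The generator reproduces: the array geometry (904 probes × 7 spots), the
printed replicate correlation and variance, additive background,
array-level scale effects, planted two-directional group differences, and
cohort compositions (24/15 and 20/39).  It does not attempt: real miRBase
identifiers, scanner/chemistry effects, raw-scale heteroskedasticity
beyond the sinh-back-transform, batch or labeling-protocol effects,
subtype-specific expression (off by default), within-group biological
heterogeneity beyond a single noise scale, or the dynamic range of real
arrays (see the calibration note above).  Tests passing on this generator
therefore validate the *machinery* — normalisation behaviour, error
control, leakage-freedom, permutation calibration, parameter recovery —
not the clinical performance figures of any real cohort, which are not
reproducible without the original raw data.

## Numerical choices

* One master seed per object (`GeneratorConfig.seed`, `CVConfig.seed`);
  sub-streams derive via `numpy` `SeedSequence`; repeated runs are
  bit-identical.  No stage reads ambient entropy.
* Nelder–Mead for the 2-parameter calibration fit (`xatol 1e−8`,
  `fatol 1e−10`), initialised at the median intensity ratio; a 1e−30
  epsilon keeps the log-likelihood finite for exact-fit arrays.
* Median-of-n variance factor estimated once by Monte Carlo (4×10^5
  draws, fixed internal seed) and cached.
* Standardisation guards zero-variance features (sd < 1e−12 → 1).
* Degenerate t-tests (zero variance, equal means) → t = 0, p = 1,
  flagged; BH inputs validated to [0, 1].
* Acceptance-scale problem sizes: 1000 replicate pairs for the
  calibration checks; 10–20 seeded cohorts for the null/recovery suites;
  100 permutation runs against a 20-repeat observed run.

## Known limitations

* The affine-plus-arsinh calibration is not the published VSN likelihood;
  it preserves the calibration and variance-flattening behaviour the
  downstream statistics need, not VSN's exact output values.
* With only two arrays, the normalisation reference (their median) is
  correlated with each array; the Jacobian term removes the first-order
  shrinkage but replicate-pair preprocessing remains the hardest case.
* The classification engine supports exactly two classes and no nested
  hyper-parameter selection beyond the reported grid.
* Real-cohort headline figures (accuracy/sensitivity/specificity,
  significant-probe counts, single-marker AUCs) depend on unavailable raw
  data and are treated as qualitative context only.
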