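# Methods

This note records the models, the numerical choices, and the reasoning
behind the design decisions that were genuinely open.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

A cine sequence is a 2D+t stack `(t, row, col)` with positive in-plane
spacing (mm) and frame interval (ms); intensities are arbitrary
non-negative units.  On disk it is a 3D NIfTI whose slice axis is time and
whose `pixdim` carries (row mm, col mm, frame ms).  Survival tables are
CSV with `subject_id`, `time` (years, > 0), `event_code`
(0 censored / 1 primary event / 2 competing death) and arbitrary numeric
covariate columns.  For the primary outcome, code-2 rows are treated as
censoring; for all-cause death, codes 1 and 2 both count as events.

Preprocessing crops every frame to an isotropic square grid (production
default 128 px at 2.2 mm; tests use 32–64 px at a spacing that preserves
the ~280 mm field of view) by bilinear interpolation, 0-based pixel-centre
coordinates, zero fill outside the source extent, then min–max normalises
the whole sequence to [0, 1] (a constant sequence maps to zeros — a
division-by-zero guard).  The heart centre is an explicit input; the
fallback localizer is the intensity centroid of above-median pixels of
frame 0.  Normalisation before encoding is the package's choice: training
is not stable without a common intensity scale.

## Cine fingerprint extractor

A variational autoencoder with hand-written backprop (no autodiff
framework is a dependency of this package).  Architecture:

- **PCA front end.** Training frames number far fewer than pixels, so all
  frames lie in a low-dimensional linear subspace.  An exact truncated PCA
  basis (default 64 components, capped at n_frames − 1) is computed from
  the *training* frames of each fold; the orthonormal projection preserves
  the L2 objective up to the constant out-of-basis residual, which is
  added back into the reported reconstruction loss.  Training the dense
  network on PC scores instead of raw pixels is ~100× faster and
  numerically better conditioned; it is mathematically a frozen linear
  first layer.
- **Frame-shared encoder–decoder.** Each frame is a training sample of the
  same network (64→128 tanh→ 2×8 linear; decoder mirrored).  The sequence
  fingerprint is the concatenation of per-frame posterior means (and log
  variances), default 8 latents × 8 frames = 64 entries.  Weight sharing
  multiplies the unsupervised sample count by the frame count — at
  200-subject folds this is the difference between an encoder that
  generalises and one that memorises — and places frame-to-frame contrast
  (the contraction pattern, hence ejection fraction) on coordinates that a
  linear risk head can reach.
- **Objective.** `l2 + kl_weight · kl` with `l2` the per-pixel mean squared
  error and `kl = Σ_d ½(μ_d² + σ_d² − 1 − log σ_d²)`.  Because `l2` is a
  per-pixel *mean* while the KL is *summed* over latent dimensions, the
  classical evidence-lower-bound balance corresponds to `kl_weight ≈ 1/D`;
  the default is 1e-4.  Weights of order 1 collapse the posterior onto the
  prior and empty the fingerprint.  Log variances are clipped to ±10.
- **Determinism.** One seed drives initialisation, shuffling and the
  reparameterisation noise; inference never samples, so extraction is
  deterministic.  Adam (lr 2e-3), minibatch 64, 400 epochs by default.

## Risk predictor

A feed-forward network on fingerprint means whose training loss is the
negated Cox partial log-likelihood averaged over events, with Breslow
handling of ties (risk sets computed over the full training batch, which
is the whole training fold — cohorts are small, so risk sets are exact).
The gradient of the loss w.r.t. η is analytic; training is full-batch Adam.

Numerical/design choices:

- **Default head is linear** (`hidden_dim = 0`, a single affine layer);
  `hidden_dim > 0` gives a tanh MLP, and an optional auxiliary
  fingerprint-reconstruction head (weight default 0) covers the
  autoencoder reading of the predictor.  With only tens of events per
  training fold, an unpenalised nonlinear head reaches near-perfect
  in-sample concordance and fails out-of-fold; the linear member of the
  family with a ridge penalty (`weight_decay`, default 0.1, applied to
  weights not biases) is the shrinkage-friendly default.
- **Score anchoring.** The partial likelihood identifies η only up to an
  additive constant, so each trained predictor maps η to mean 0 / sd 1 on
  its *own training subjects* before prediction.  Without this, pooled
  out-of-fold scores from different folds are mutually incomparable and
  the pooled C-index collapses toward 0.5.  The cine risk score is
  logistic(η) — a 0-to-1 display scale; concordance, median splits and HR
  signs are invariant to the choice.
- **Ensembling.** The pipeline trains `ensemble_size` (default 3)
  extractor + head pairs per fold, differing only in derived seeds, and
  averages the anchored linear predictors; member errors are weakly
  correlated, so a small ensemble reduces the variance of the fold's
  direction estimate.

## No-leak sixfold protocol

One stratified fold assignment per run (events per fold differ by ≤ 1,
fold sizes differ by ≤ 1; unstratified behind a flag), shared across
outcomes.  For fold f: train the extractor on folds ≠ f, fingerprint
everyone with it, train the risk head (per outcome) on folds ≠ f, score
fold f.  `combine_fold_predictions` enforces exactly-once coverage
structurally.  One run seed fans out to per-stage seeds through a
documented counter scheme (`stage_seed`), so stages are independently
reproducible.

## Survival statistics

- **Harrell's C**: ordered pair (i, j) is comparable when `t_i < t_j` and
  i had an event, or times tie and exactly i had an event; tied scores
  count ½.  O(n²) vectorised; exhaustive enumeration is the test oracle.
- **Bootstrap**: subjects resampled with replacement, percentile 2.5/97.5
  interval, point estimate on the full sample; failed resamples are
  redrawn (≤ 10 retries).
- **Cox fit**: own Newton–Raphson maximiser (gradient max-norm < 1e-8 or
  100 iterations, step halving), Efron ties by default, Breslow for parity
  with the training loss.  Wald CIs and p-values from the inverse observed
  information.  Monotone likelihood is reported as an explicit error: under
  separation the gradient vanishes at an arbitrarily large coefficient, so
  a coefficient with |β| > 10 and SE > |β| is flagged rather than returned.
  The in-house fitter exists because the Fine–Gray estimator below needs
  the same engine with pair-dependent weights; lifelines is the
  independent cross-check in the tests, never the implementation.
- **Fine–Gray**: subdistribution-hazard fit via the IPCW-weighted partial
  likelihood — subjects with a competing event stay in later risk sets
  weighted by G(t−)/G(s−), with G the left-continuous Kaplan–Meier of the
  censoring distribution on the pooled sample.  Coefficients agree with
  the R `cmprsk` reference implementation; the reported Wald variance is
  the naive inverse information, not the Fine–Gray sandwich, so its CIs
  are approximate (a documented limitation; coefficient tests in the suite
  compare point estimates only).  With no competing events it reduces
  exactly to the Breslow Cox fit.  Note the subdistribution semantics: a
  covariate that raises only the *competing* hazard has subHR < 1 for the
  primary event — fewer subjects remain reachable — which the tests assert.
- **Kaplan–Meier / log-rank** delegate to lifelines (exponential-Greenwood
  log(−log) 95% band; k-sample log-rank with k−1 df).
- **Continuous NRI**: category-free
  `[P(up|event) − P(down|event)] + [P(down|non-event) − P(up|non-event)]`.
- **Incidence rates**: 100·events/person-years with exact Poisson
  (chi-square quantile) bounds.
- **Sample size**: classical pooled two-sided two-proportion formula,
  `n/group = (z_{1−α/2}√(2p̄q̄) + z_{1−β}√(p₁q₁+p₂q₂))²/(p₁−p₂)²`,
  ceiling per group.  (statsmodels' proportion power uses a different
  parameterisation, hence the hand-coded form; R's `power.prop.test` is
  the cross-check.)
- **Quantile splits**: linear-interpolation quantile, ties to the low
  group (score ≤ cutoff → low).
- **Baseline comparisons**: Pearson χ² (no continuity correction),
  Student's t, or two-sided Mann–Whitney U via scipy.

## LGE quantification

`max_si` is the maximum SI in the hyper-enhanced region; `normal_peak_si`
the maximum over the remaining myocardium.  Core = hyper-enhanced pixels
with SI > 0.5·max_si; gray = myocardial pixels with
normal_peak_si < SI < 0.5·max_si (search domain defaults to the full
myocardium because the rule's lower bound references normal myocardium; a
toggle restricts it to the enhanced region).  Both inequalities are
strict, so pixels exactly at the half-maximal SI are counted in neither
class; they are reported separately (`unclassified_px`).  Mass =
count × voxel volume × density / 1000 with myocardial density
1.05 g/mL by default.  Stacks are quantified per slice and summed.

## Synthetic cohort generator

The phantom renders LV, RV, LA, RA as axis-aligned ellipses (bright blood
pools, mid-gray walls, dark background, 3× supersampled partial-volume
edges) on a field of view of `size_px × spacing_mm`.  Ventricular areas
follow a raised-cosine curve from end-diastole to end-systole; atria run
in anti-phase (reservoir pattern).  A single 2D view has no volume, so
volume ejection fraction is mapped to an area fraction through the
isotropic-scaling proxy `V ∝ A^1.5`, i.e. `ef_area = 1 − (1 − EF)^(2/3)`;
the tests confirm the rendered masks return the requested EF to ±0.03 for
EF ∈ {0.15, 0.25, 0.4, 0.6}.  Gaussian pixel noise (sd 0.02 by default) is
added and clipped at zero.  Frame k sits at phase k/n_frames, so the cycle
closes exactly one frame past the stack.

Populations are truncated normals per parameter; the defaults centre on a
dilated-cardiomyopathy ICD-candidate profile (LVEF 0.26 ± 0.08 bounded to
(0.05, 0.6), LA emptying 0.38 ± 0.12, LV end-diastolic 4ch area
3800 ± 700 mm²).  Event times are exponential with rate
`λ₀ · exp(Σ β_k z_k)` over cohort-standardized parameters; an independent
exponential competing death and administrative censoring (default 10
years) truncate them.  λ₀ = 0.0235/year was solved analytically so that a
unit slope on −LVEF yields ≈27% primary events at the 10-year horizon —
the censoring regime the pipeline is designed for.  The exponential (not
Weibull) baseline keeps closed-form checks available.

What the phantom does **not** emulate: myocardial texture, through-plane
motion, arrhythmic dyssynchrony, acquisition artifacts, scanner
heterogeneity, or any nonlinear hazard structure.  Passing the recovery
experiment therefore shows the pipeline can extract chamber
structure/function from moving images and rank censored risk without
leakage — not that it would achieve comparable discrimination on clinical
data.

## Scaled recovery experiment

`cinerisk.benchmark.run_recovery_benchmark` draws 240 subjects at
64×64×8 (4.4 mm spacing → the standard 280 mm field of view), hazard slope
1.0 on standardized −LVEF, and runs the sixfold pipeline with the default
small networks.  The problem sizes are the package's benchmark conditions;
the run takes a few minutes on one CPU.  Under these conditions the true
−LVEF itself attains a C-index of about 0.73 (the information ceiling of
the simulation), and the pipeline's pooled out-of-fold score is expected
in the 0.60–0.72 range depending on the cohort draw; the fixed-seed
acceptance run must clear 0.65 with a median-split log-rank p < 0.01.

## Known limitations

- Fine–Gray variance is the naive inverse information (see above).
- The extractor's PCA front end assumes a common frame geometry across
  subjects; multi-resolution cohorts must be resampled first.
- The risk head's ridge strength is a fixed default, not tuned per fold by
  inner cross-validation; with very different event counts it may need
  adjustment.
- Single-slice (2D+t) sequences only; no multi-slice 3D cine, DICOM
  ingestion, or time-dependent covariates.
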