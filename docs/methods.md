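# Methods

`restconn` implements a seed-based resting-state functional-connectivity
analysis chain for a two-group (lean / obese), two-session (T0, before a
bariatric weight-loss intervention; T8, about eight months after) study
design, together with a synthetic-cohort generator that plants known
effect structure so every stage can be validated against ground truth.

## 1. Synthetic cohort and BOLD runs

### Phenotypes

`CohortSpec` defaults describe the emulated study conditions: 30 lean
and 14 obese female participants; obese mean weight 119 kg at T0
falling to roughly 85 kg at T8; body fat 62 → 42 kg; fasting serum
leptin 70 → 25 ng/ml; lean leptin ~9 ng/ml sampled at T0 only (the
study's follow-up blood sampling and body-composition scans covered
only the surgical group, so lean records carry no T8 hormones and no
fat mass).  Each obese participant receives a planted seed-to-ventral-
striatum Fisher-z increase `dz ~ N(0.36, 0.15²)` between sessions
(baseline couplings r = 0.20 obese vs 0.50 lean; the 0.36 mean z-change
is consistent with reported coupling shifts from ≈ −0.05 to ≈ +0.11
plus the baseline group gap).  Weight change is

    Δw = offset + β·dz + ε,   offset = −25 kg, β = −25 kg per z, ε ~ N(0, 4²),

so the group mean loss is ≈ 34 kg and the connectivity change carries
genuine predictive information.  A second target region ("dlpfc",
hyper-connected in the obese group at baseline, r = 0.35 vs 0.15) does
not change over time and is unrelated to weight — a planted null
feature mirroring the study's negative control.

Leptin is tied to fat mass with per-session slopes (1.1 ng/ml/kg at T0,
0.6 at T8, matching the group-mean ratios), and the leptin lost per kg
of fat is additionally coupled to `dz` (4 ng/ml/kg per z-unit), so the
hormone-connectivity correlation has a planted positive sign of
realistic size (population ρ ≈ 0.7 at n = 14).  These generator values
are the study conditions of the test suite; they were chosen once from
the magnitudes above and are not tuning knobs.

### BOLD runs

Runs are 20×20×20 voxel grids (3 mm isotropic affine) × 299 volumes at
TR = 2 s (304 acquired, first five discarded) — desk-scale stand-ins,
not MNI-resolution brains.  Masks are disjoint cubes: seed (27 voxels),
vstr (64), dlpfc (27), white matter and CSF (125 each), placed at fixed
fractional positions so any grid ≥ 8³ works.

Seed voxels share a latent course that is *band-limited to the
0.01–0.1 Hz analysis band*, plus small band-limited voxel noise; each
target-ROI voxel is `a·latent + √(1−a²)·noise` with `a` calibrated so
the expected Pearson correlation between the voxel and the seed-mean
course equals the planted coupling (the calibration accounts for the
seed-mean's noise inflation).  Keeping all coupled signal inside the
pass band means denoising does not destroy planted correlations.
Background voxels carry broadband white noise, a per-voxel linear
drift, and a shared global fluctuation whose tails are clipped at 2.5
SD so that an artefact-free run stays below the global-signal censoring
threshold by construction; WM/CSF voxels share slow tissue courses.
The global fluctuation is omitted from seed/ROI voxels so the coupling
calibration stays exact — a deliberate simplification.

Motion traces are translation/rotation random walks (≈0.05 mm
framewise).  Spontaneous spikes (rate 0.005 per volume; the study did
not quantify motion distributions) are out-and-back pulses of
0.6–1.2 mm built from two opposite step injections, so displacement
never accumulates toward the participant-level exclusion threshold.
The public `inject_motion_spike` uses step semantics: one framewise-
displacement excursion per call, plus a proportional intensity
disturbance at the spiked volume.  `n_high_motion` participants receive
a slow 4 mm excursion that triggers participant exclusion (≥3.5 mm)
without tripping the per-volume censor.

What the generator does *not* emulate: anatomy, k-space/slice-timing
physics, spatial autocorrelation of noise, physiological rhythms,
motion-correlated signal dropout, and session-to-session registration
error.  Passing tests therefore validate the statistical machinery, not
robustness to those real-data complications.

## 2. Denoising

* **Framewise displacement** is the sum of absolute backward
  differences of the three translations plus 50 mm × the absolute
  rotation differences (rotations converted to arc length on a 50 mm
  sphere — the dominant scrubbing convention; first element 0).
* **Outlier volumes**: |z| > 3 of the linearly detrended volume-mean
  intensity series, or FD ≥ 0.5 mm.
* **Confound design**: 6 motion parameters + first and second backward
  differences (18 columns, first rows zero-padded), eroded-WM and
  eroded-CSF mean courses (default one 6-connected erosion), linear and
  quadratic trends, and one indicator per censored volume
  (K = 22 + outliers).
* **Simultaneous regression + band-pass**: one least-squares fit per
  voxel, restricted to retained volumes, of the confound design
  augmented with an intercept and a DCT-II basis of all frequencies
  outside 0.01–0.1 Hz (band-stop by regression).  Censored-volume
  indicators are constant on the retained rows and are dropped with a
  warning, as is any other zero-variance column (tie-break by column
  order).  Residuals are exactly orthogonal to the fitted columns over
  retained volumes; censored volumes are zeroed and flagged.

Two numerical properties worth knowing:

* The fit refuses to run with fewer than K + 10 retained volumes.
* Because the broadband confounds and the complete stop-band basis
  jointly span some in-band directions, in-band signal that *shares
  waveform content with the confounds' in-band component* is removed —
  that is nuisance removal working as intended.  Signal orthogonal to
  the fitted subspace passes through exactly; since every voxel is
  filtered by the same projection, between-voxel correlations of
  band-limited signals are preserved (verified by the planted-coupling
  recovery tests).

Gaussian smoothing (`smooth_volume`, FWHM in mm via the affine's voxel
spacing) is provided and off by default in the synthetic pipeline: an
8 mm kernel is comparable to the planted ROI size on a 20³ desk-scale
grid and would mostly mix ROI and background rather than emulate the
real-data step it corresponds to.

## 3. Connectivity

Seed-mean course (unweighted, retained volumes only) correlated with
every voxel; Pearson r clipped at |r| ≤ 1−10⁻⁶ and Fisher-transformed
(z = atanh r).  Seed-internal voxels are reported, not masked.
Zero-variance voxels get z = 0 with a warning.  ROI features are
unweighted means of z over ROI voxels, following the convention of
averaging voxel-wise z rather than transforming the ROI-mean
correlation.

## 4. Group maps and cluster inference

The 2×2 group-by-time factorial is realized as the planned contrasts
the analysis interprets: pooled-variance two-sample t maps for obese vs
lean at each session, and an unpaired contrast on per-participant
change maps (T8−T0) for the interaction.  Clusters are face-connected
(6-connectivity; 18/26 configurable) components above the one-sided
t threshold at voxel p = 0.001.

Cluster inference is nonparametric: group labels are permuted (default
1000 times), the maximum supra-threshold cluster extent over both
one-sided directions is recorded per permutation (a family null valid
for the directional contrast pair), and each observed cluster gets
p = (1 + #{null maxima ≥ extent}) / (B + 1), followed by
Benjamini–Hochberg FDR across clusters at q = 0.05.  This replaces
parametric random-field cluster inference: at desk scale the
permutation null is exact, assumption-free, and testable (the suite
verifies ≲5% of null datasets produce any significant cluster).

ROI selection for the prediction analysis uses the *baseline* contrast
only (no information from T8 or weight change can leak into ROI
definition).  The hormone analysis ROI comes from the interaction map
at p < 0.001 uncorrected with a 50-voxel extent gate, falling back to
the baseline hypo-connectivity ROI when no interaction cluster reaches
the gate.

## 5. Out-of-sample prediction of weight change

For each participant i, ordinary least squares of weight change on the
ROI feature over the other n−1 participants, then prediction of the
held-out participant: ŷᵢ = β₀⁽⁻ⁱ⁾ + β⁽⁻ⁱ⁾·zᵢ.  The trained intercept
is applied by default (standard OLS prediction); `intercept=False`
reproduces the literal slope-only prediction form.  The feature is the
session change z_T8 − z_T0 by default, with the T0 level as a
configurable alternative (both readings of the published model are
supported; neither is asserted as the original choice).  All
participants, lean included, enter the folds.

Agreement between predicted and observed weight change is Pearson r
with two inferential companions:

* parametric two-tailed p from t = r√(n−2)/√(1−r²) on n−2 df;
* a permutation chance interval: the 5th/95th percentiles of r over
  10 000 random shuffles of the observed vector against the *fixed*
  predictions (LOOCV is not re-run inside the permutation loop).  The
  5th/95th pair is the default because it matches the ±1.65/√(n−1)
  scale of published chance bounds (≈±0.25 at n = 44, ≈±0.46 at
  n = 14); other percentile pairs are configurable.

**The LOOCV null is negatively biased.**  When the training slope is
near zero, every fold's prediction collapses toward the left-out
training mean ȳ⁽⁻ⁱ⁾ = ȳ − (yᵢ−ȳ)/(n−1), which correlates −1 with the
observations; simulation at n = 44 with an uninformative feature gives
mean r ≈ −0.33 (intercept applied), with a third of null replicates
below −0.25.  A negative predicted-observed correlation is evidence of
*no* predictive skill, not of skill.  `PredictionResult.detected`
therefore compares r to the upper chance bound only (one-sided), which
is also how a chance interval is used in practice when the question is
"does the model predict?".  The suite contains a test documenting the
negative bias itself.

## 6. Hormone linkage

For the obese group, x = (leptin_T0 − leptin_T8)/(fat_T0 − fat_T8) in
ng/ml per kg (participants with |Δfat| < 0.01 kg are excluded with a
warning rather than producing unstable ratios), y = z_T8 − z_T0 on the
interaction-derived ROI, and Pearson ρ(x, y) with the same parametric
and permutation inference as above.  Because this is a plain
correlation (no cross-validation), the two-sided chance interval is the
natural reference.  `change_tests` reports the paired obese T0-vs-T8
t tests (weight, BMI, body-fat % and kg, leptin, insulin; df = n−1) and
two-sample obese-vs-lean baseline tests; an all-zero change vector is
reported as t = 0, p = 1 rather than 0/0.  Insulin and glycaemia-style
measures flow through the same machinery with no asserted direction.

## 7. Pipeline, determinism and problem sizes

`run_full_pipeline` chains: cohort generation → per-run censoring,
confound regression and band-stop → seed-to-voxel z maps → baseline
contrast + permutation cluster FDR → ROI features → LOOCV prediction →
interaction ROI → hormone correlation → TSV/NIfTI/JSON outputs plus a
manifest (config hash, exclusion cascade, censored-volume counts).
Every random draw derives from the single `rng_seed` through
`SeedSequence` spawn keys (cohort, per-participant-and-session runs,
cluster permutations, inference permutations are independent streams),
so re-running a config reproduces outputs byte-for-byte.

Default problem sizes (44 participants × 2 sessions on 20³×299 grids,
1000 cluster permutations, 10 000 inference permutations) run in about
half a minute on one core.  The test suite uses smaller grids and runs
(12³ or 10³, 155–299 volumes) chosen so every planted effect remains
comfortably detectable at the stated replicate counts.

## 8. Known limitations

* The permutation family for cluster FDR covers the two directional
  baseline contrasts; it is not a global correction across all maps a
  study might screen.
* The factorial engine implements planned two-sample contrasts, not a
  full mixed-effects ANOVA; paired structure enters only through change
  maps.
* The synthetic generator's voxel noise is spatially independent, so
  cluster extents under the null are smaller than in smoothed real
  data; extent thresholds tuned here do not transfer to real grids.
* The ratio statistic x is sensitive to small fat changes despite the
  epsilon guard; with real data a regression-based adjustment would be
  more robust.
* No atlas labelling, random-field theory, slice-timing, realignment or
  spatial normalization: volumetric inputs are assumed already aligned
  on a common grid.
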