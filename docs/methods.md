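# Methods

`pupilseed` implements a pupillometry-seeded resting-state functional
connectivity analysis. Spontaneous pupil constriction/dilation is used
as a non-invasive surrogate for activity of the locus coeruleus (LC),
the brainstem noradrenergic nucleus that is too small (~2 mm in the
axial plane) to seed reliably from fMRI voxels or atlas masks. Two seed
regressors are derived from the pupil trace: the HRF-convolved pupil
diameter (tonic arousal) and its first temporal derivative (phasic
arousal events). Each is correlated with every brain voxel, and group
statistics, cluster-extent inference and covariate associations follow.

## Seed construction (module `pupil`)

Input is the per-frame output of a video pupil segmenter: time,
diameter (arbitrary units) and a segmentation confidence in [0, 1],
with failed frames flagged missing. The chain, in order:

1. **QC gate.** A subject is analysed only if strictly less than 20% of
   frames are unsuccessful and at least 75% have confidence above 0.9.
   Both boundaries are implemented literally (20.0% unsuccessful fails;
   exactly 75% high-confidence passes).
2. **Confidence masking.** Frames with confidence < 0.9 become missing.
3. **Sliding-window smoothing**, 57-frame centred window. The window
   statistic is an unweighted mean of the non-missing frames (a median
   is available by flag); the window is truncated at the trace edges.
   A frame whose entire window is missing stays missing.
4. **Canonical HRF convolution.** The kernel is the standard
   double-gamma difference (response peak 6 s, undershoot 16 s, unit
   dispersions, undershoot ratio 1/6, 32 s support), peak-normalised.
   Remaining gaps are linearly bridged first, because discrete
   convolution needs a complete uniform series. The chain uses a
   steady-state boundary (the signal is assumed to have sat at its
   initial value before recording), which removes the 32 s onset
   transient; the raw `convolve_hrf` default is the pure zero-padded
   convolution identity, selectable via `pad=`.
5. **Interpolation to volume times.** Linear interpolation at the
   acquisition time of each fMRI volume; the default temporal reference
   is TR/2 after scan start (configurable — the original acquisition's
   reference point is not knowable from the data we model).
6. **Differentiation.** Second-order central differences (one-sided,
   second-order at the ends) of the interpolated, convolved series.
   Differentiating after convolution and interpolation rather than
   before differs only by discretisation error, by linearity of all
   three operators.

## BOLD denoising (module `boldprep`)

Operates on registered 4D data (slice timing, realignment and spatial
normalisation are upstream tools' jobs; the synthetic data is generated
on a common grid). Defaults mirror standard practice for this analysis:

- **Framewise displacement**: sum of absolute frame-to-frame changes of
  the three translations plus 50 mm times the absolute rotation
  changes (rotations as arc length on a 50 mm sphere).
- **Outlier volumes**: FD > 0.9 mm, or global-signal frame-to-frame
  change beyond 5 SD of its own distribution.
- **Spatial smoothing**: separable Gaussian, 8 mm FWHM, nearest-edge
  boundary (so constant volumes stay constant at the borders).
- **Confound regression**: per-voxel OLS on an intercept, the six
  motion parameters, a session-onset block (first 10 volumes) plus a
  linear trend standing in for the "effect of rest", externally
  supplied tissue (white matter / CSF) signals, and one indicator per
  flagged volume — which forces the residual at scrubbed volumes to
  exactly zero. The global signal is never regressed.
- **Bandpass 0.008–0.09 Hz**: a hard zero-phase mask on real-FFT bins.
  A hard mask is deterministic and analytically testable (a bin is
  either kept or zeroed), at the price of spectral leakage for
  off-bin components; the in-band retention tests bound that leakage
  at 2%.

Order: smooth → scrub/regress → bandpass. The composition is linear per
voxel (asserted on random instances), so the order of regression and
filtering interacts only through the scrubbed indicators.

## Connectivity (module `connectivity`)

Seed-to-voxel maps are Pearson correlations between the seed and each
in-mask voxel series over unflagged volumes, Fisher z-transformed
(`atanh`, with |r| clipped at 1 − 1e−7 to keep z finite). Local
correlation — a regional-homogeneity measure used as the negative
control for seed-mediated effects — is the Gaussian-weighted average
correlation of each voxel with its in-mask neighbours (10 mm FWHM
weight kernel by default, self excluded, weights from inter-voxel mm
distance, kernel truncated at 3 sigma per axis). It is computed via the
standardised-series identity (spatially convolving the z-scored data
and taking the temporal inner product), which tests verify equals the
direct O(V²) weighted sum to 1e−8.

## Group inference (module `inference`)

`ClusterInferenceModel.fit()` runs, on a stack of subject z-maps:

1. the voxel statistic — one-sample t across subjects, or the group
   contrast from a per-voxel OLS of z on [intercept, group, centred
   covariates] (sex is the standard covariate; centring keeps the
   group contrast interpretable);
2. cluster forming at two-sided voxel p < 0.001 (both positively and
   negatively coupled clusters are of interest), with 6-face
   connectivity (18/26 selectable; 6 is the most conservative standard
   choice) and sign-consistent components;
3. a permutation null of the **maximum** cluster extent: random sign
   flips of subject maps for the one-sample design (assumes a
   symmetric subject-level null — stated test assumption), or group
   label permutation with covariates kept attached for the group
   design. When all 2^n sign patterns number no more than `n_perm`,
   they are enumerated exhaustively. Cluster
   p = (1 + #{null ≥ extent}) / (n_perm + 1);
4. Benjamini–Hochberg FDR across the observed clusters; significance
   at corrected p < 0.05.

Referring every cluster to the max-extent null is conservative
(FWER-style null) before the BH step; the empirical type-I acceptance
test shows the family rate stays at or below nominal.

Cluster naming follows an integer label volume: the peak voxel's
label; if the peak is unlabeled, the majority label among its 26
neighbours with `*` appended; otherwise `unlabeled*`.

## Associations (module `association`)

Per-subject cluster connectivity is the mean Fisher z over the
cluster's voxels (median by flag; the summary statistic is a
documented choice, not derivable from the analysis description).
`ClusterAssociationModel.fit()` computes, for every cluster × measure
pair, the partial Pearson correlation given age and sex (education
optionally added), with p from t = r·sqrt((n − k − 2)/(1 − r²)), and
BH-FDR over the whole battery (one family per analysis table).
Subjects with a missing measure or covariate are listwise-deleted per
measure, with counts logged in the output. The identical code path
accepts local-correlation maps, reproducing the negative-control
logic: if associations survive on seed-connectivity summaries but not
on local-correlation summaries, they are not explained by local
coherence. Cohort-level summary comparisons use the pooled-variance
two-sample t computed directly from printed group means/SDs.

## Synthetic cohorts (module `synth`)

The generator defines the study conditions under which everything is
tested:

- **Latent arousal** is an exact-discretisation Ornstein–Uhlenbeck
  process (mean 4.0 a.u., SD 0.4 a.u., tau 10 s). An OU process is the
  simplest stationary process with a matched autocorrelation time;
  tau = 10 s concentrates its power inside the 0.008–0.09 Hz analysis
  band.
- **Pupil traces** sample the latent process at 60 Hz (camera rate is
  not a property of the modelled study; it is explicit, configurable
  generator config) with 0.05 a.u. measurement noise and blink-like
  missing runs (geometric run length, mean 10 frames; iid mode
  available) totalling 5% of frames by default. Missing frames get
  confidence below 0.9, others at or above.
- **BOLD** datasets are 320 volumes at TR 1.89 s on 1.5 mm isotropic
  grids (24×24×12 default; 8×8×4 for desk-scale tests). Planted voxel
  sets carry beta × (standardised HRF-convolved latent, or its
  derivative) plus unit-SD Gaussian noise; all other voxels are pure
  noise, so the generative voxel-level coupling is
  r = beta/sqrt(beta² + sigma²) (0.447 for the default beta = 0.5).
  Motion is six small Gaussian random walks (0.02 mm / 0.0005 rad per
  volume — realistic FD mostly below, occasionally above, 0.9 mm);
  white-matter and CSF nuisance columns are slow autocorrelated
  signals.
- **Cohorts** default to 37 younger + 39 older subjects; ages are
  truncated normals on either side of the 57-year group boundary, and
  sex/education/score/CSF columns follow the modelled cohort's group
  summaries. Older subjects' derivative-coupled betas are multiplied
  by the plant's attenuation factor. Each subject's coupling is
  beta × (1 + 0.3 u) with u ~ N(0, 1) (`coupling_sd` = 0.3). This
  between-subject spread exists so that covariates can be planted with
  a specified correlation to coupling strength (drawn bivariate
  normally against u), and its size is an identifiability requirement:
  the spread of true per-subject coupling must dominate the
  per-subject measurement noise of the cluster-mean z (seed-estimation
  and filtering noise common to all cluster voxels, roughly 0.05 in z
  at 320 volumes), or a covariate–coupling association is
  unrecoverable from the maps no matter how it is analysed. A 30%
  relative spread — comparable to commonly seen between-subject
  variability in seed connectivity — puts the measured cluster summary
  at correlation ≈ 0.8 with the true coupling factor. Ground truth
  (plant voxels, per-subject betas, the coupling factor) is recorded
  for recovery tests.

What the generator does **not** emulate: anatomy and tissue contrast,
spatial autocorrelation of noise, physiological (cardiac/respiratory)
signal structure, distance-dependent motion artefacts, susceptibility
dropout, or any nonlinearity of neurovascular coupling. Passing the
recovery tests therefore demonstrates that the pipeline's estimators
and inference are correct under the stated generative model, not that
the pipeline is robust to every artefact of real data.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng`; cohorts
  spawn per-subject child seeds from one `SeedSequence`, so any
  subject regenerates bit-identically in isolation.
- Correlations are clipped at 1 − 1e−7 before `atanh`; constant voxel
  series get r = 0 and are counted in map metadata; zero
  between-subject variance yields a signed infinite t sentinel, also
  counted.
- The seed regressor is not bandpass-filtered (only the BOLD data is),
  so out-of-band latent power attenuates measured planted correlations
  relative to the generative coupling; detection margins in the
  acceptance tests absorb this.
- Replicate-level acceptance tests run on 8×8×4 grids with denoising
  but without the 8 mm smoothing step, which on so small a grid would
  smear a 30-voxel plant across most of the volume and make
  voxel-overlap scoring meaningless; the demo-scale run in
  `scripts/acceptance.py` keeps the full 8 mm smoothing.
- Problem sizes used by `scripts/acceptance.py`: one 76-subject demo
  cohort on 24×24×12; 100 null cohorts (n = 20, 8×8×4, 500
  permutations); 20 replicates each for cluster recovery (n = 39),
  group attenuation (n = 76) and covariate recovery (n = 76). The test
  suite's versions of the same checks use 200 null cohorts and 50
  replicates.

## Known limitations

- Permutation inference is implemented only for the one-sample and
  two-group designs; no Gaussian-random-field or TFCE alternatives.
- The "effect of rest" regressor (onset block + trend) is a documented
  surrogate for an unspecified toolbox construction, not a claim of
  equivalence.
- Cluster p-values from the max-extent null are conservative for
  non-maximal clusters.
- No imputation: subjects missing a measure are dropped from that
  measure's tests only.
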