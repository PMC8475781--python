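# Methods

`demandmri` reimplements, end to end and against simulated ground truth, an
fMRI analysis that contrasts *linguistic* demand (a semantic word-matching
task made harder) with *non-linguistic* demand (a perceptual symbol-matching
task made harder) while behavioral difficulty is matched across domains.
Because the original scans are not available, a synthetic-data generator
takes the place of the cohort: every stage of the analysis can then be
checked by parameter recovery, by null calibration, and against brute-force
oracles.

## Experimental design

A run is 30 contiguous 16-s blocks — six each of Semantic Easy, Semantic
Difficult, Perceptual Easy, Perceptual Difficult, and Rest — in a uniformly
random order per seed (480 s; 240 volumes at TR = 2 s, with four discarded
initial volumes emulated). Active blocks hold eight go/no-go matching trials
at a 2-s SOA; each block's number of match trials is drawn uniformly from
2–6 of 8, bounding the match proportion to 25–75%. Responses are recorded
300–1,900 ms after onset.

The Semantic Difficult condition is adaptive: items come in three difficulty
sub-levels, and the sub-level tracks the participant's running accuracies on
the two difficult conditions. If semantic accuracy exceeds perceptual
accuracy by more than 5%, the hardest sub-level is presented; if it trails
by more than 5%, the easiest; otherwise the middle one. Exactly 5% falls in
the middle branch. Running accuracy is cumulative within session; before any
difficult trial is scored the rule cold-starts at the middle sub-level
(mirroring the "otherwise" branch). Whether the update applies per block
(default) or per trial is configurable, as the original cadence is not
specified.

## Synthetic data

**Phantom.** The default grid is 24×24×18 voxels at 3-mm isotropic spacing
(tests use 16×16×12; the geometry is configurable). Twenty-four disjoint
spherical truth regions sit on a fixed per-hemisphere lattice: twelve
multiple-demand-like (MD) regions, ten language-like regions, and two
default-mode-like regions. Sustained-response amplitudes per condition (in
signal units on a baseline of 100):

| family   | SE  | SD   | PE  | PD   | profile |
|----------|-----|------|-----|------|---------|
| md       | 0.5 | 1.0  | 0.5 | 1.6  | both demands positive, non-linguistic larger (interaction −0.6) |
| language | 1.0 | 1.8  | 0.1 | 0.0  | linguistic demand only (interaction +0.9) |
| dmn      | 0.0 | −0.8 | 0.0 | −1.2 | deactivated by difficulty in both domains |

**BOLD model.** A voxel's series is baseline + Σ amplitude × (block boxcar ⊛
HRF) + quadratic drift (Legendre P1/P2 coefficients 1.0/−0.5 signal units) +
a small coupling to simulated global WM/CSF series + stationary AR(1)
Gaussian noise. The marginal noise SD defaults to 0.75 signal units, chosen
so single-run contrast *t* values in truth regions fall roughly in the 3–7
range; the AR(1) coefficient defaults to 0.3 and is exposed as a free
parameter (the original model's autocorrelation treatment is not
documented). Each participant's amplitudes are scaled by N(1, 0.15) to give
between-subject variability. 244 volumes are generated and the first 4
discarded.

**Behavior.** Responses are Bernoulli with per-condition hit and false-alarm
probabilities; RTs are lognormal. Defaults place accuracy near 97.5% in the
easy conditions and near 82% / 81% in the two difficult conditions, with the
same RT distributions across domains — a difficulty effect with no domain
effect and no interaction in expectation. Conditional on trial type, the
difficult-condition defaults (hit 0.712 / FA 0.072 semantic; hit 0.93 / FA
0.304 perceptual, with matches at 50% on average) make semantic-difficult
errors mostly misses (≈14.4% of trials) and perceptual-difficult errors
mostly false alarms (≈15.2%), reproducing the qualitative error asymmetry
the analysis must be robust to. Participant-level random offsets act on the
logit (SD 0.35) and log-RT (SD 0.08) scales; harder semantic sub-levels
shift the logit by −0.25 per step, which gives the adaptive rule something
real to track.

What the generator does **not** emulate: physiological/vascular noise
structure, motion-correlated signal, spatial autocorrelation of noise,
susceptibility artifacts, or anatomical variability. Passing tests therefore
demonstrate the correctness and calibration of the *analysis machinery*
under the stated noise model, not robustness to all properties of real data.

## First-level GLM

The HRF is a difference of two gamma densities with time-to-peak 5.4 s /
FWHM 5.2 s (first component) and 15 s / 10 s (second), the second weighted
0.09. Each gamma's shape and scale are solved numerically from (mode, FWHM):
the ratio FWHM/mode pins the shape by bisection (the FWHM of a unit-scale
gamma scales linearly in the scale parameter), and the scale follows from
mode = (shape−1)·scale. The kernel is sampled at 0.1 s on [0, 32 s] and
normalized to unit integral, so a sustained block's fitted coefficient reads
directly in signal units of sustained response. Condition regressors are
unit boxcars convolved on that grid and sampled at volume times.

The design has 16 columns: 4 condition regressors (rest is the implicit
baseline), 6 motion parameters, WM and CSF series, 3 cubic-spline temporal
trends, and an intercept. The trend columns are a natural cubic spline with
knots at the run start, 1/3, 2/3, and end — chosen so the trend space has
exactly three functions beyond the constant. Nuisance and trend columns are
centered, so the intercept estimates the rest baseline. Estimation is OLS
per voxel (df = 240 − 16); optional one-iteration AR(1) prewhitening
estimates the lag-1 coefficient per voxel from OLS residuals and refits on
quasi-differenced data (off by default). A `legendre_degree` option appends
Legendre trend columns (residualized against the design and dropped when
already spanned) to emulate polynomial detrending as a consistent
preprocessing step; the pipeline uses degree 2, matching the quadratic drift
family, and the residual df shrinks accordingly.

Named contrasts over (SE, SD, PE, PD): linguistic demand (−1,+1,0,0);
non-linguistic demand (0,0,−1,+1); language (+1,+1,−1,−1); interaction
(−1,+1,+1,−1); plus each condition versus rest. Participant-level maps are
the unweighted mean of the two run effects with propagated variance (the
combination rule is this package's choice; on noiseless data it equals a
stacked two-run fit with per-run intercepts).

## Group inference

Second-level inference is a per-voxel one-sample *t* over participants
(df = n−1; zero-variance voxels get a signed-infinity sentinel and a
warning). Clusters form above the one-sided p < 0.005 threshold per
direction, under 26-connectivity by default (6/18 configurable); extent is
voxel count × voxel volume and the center of mass is the unweighted mean of
member mm coordinates, reported rounded to integers. Family-wise error is
controlled by sign-flip permutation of the maximum cluster extent: each
permutation re-signs each participant's map (identity always included),
recomputes the t map, and records the largest suprathreshold component per
direction; a cluster's corrected p is the fraction of the null set with max
extent at least as large, bounded below by 1/(number of assignments). All
2^n assignments are enumerated when n ≤ 12 and the request covers them.
Positive and negative directions are corrected separately. Sign flips leave
voxel sums of squares unchanged, so all permuted t maps come from one
matrix product, and permutations are labeled in one pass by stacking them
along a fourth axis with no connectivity across it.

A practical note on calibration: with spatially white maps the max-extent
null is concentrated on very small extents and the attained FWER is
conservative; after Gaussian smoothing at the pipeline's 6-mm FWHM (the
voxelwise GLM is linear, so smoothing effect maps equals fitting smoothed
data) the attained rate is close to nominal, which is how the calibration
suite exercises it.

## Functional ROIs and ROI statistics

Spheres of radius 8 mm are placed around network peaks — twelve MD spheres
and ten language spheres by default, at the phantom's truth-region centers
(in a real study the MD centers come from an external group image and the
language centers from the group language contrast smoothed by a further
8-mm FWHM before peak finding, which `smooth_for_peaks` implements). For
each sphere and each run, the individual fROI is the top 10% of sphere
voxels with the highest localizer *t* in the *other* run (k = round(0.10 ×
sphere size), taken from the eligible set and capped by it; ties break by
voxel index), excluding voxels modulated by the orthogonal contrast at
two-sided uncorrected p < 0.1. MD fROIs localize on non-linguistic demand
and exclude on language; language fROIs localize on the language contrast
and exclude on non-linguistic demand. Condition effects are extracted
cross-run — voxels chosen from run A are measured in run B and vice versa,
then averaged — as percent signal change relative to the voxel's baseline
(intercept), with a raw-effect mode available. An ROI with an empty
selection is dropped from statistics with a warning.

Per-ROI inference uses sign-flip permutation of the per-participant contrast
values: the observed statistic is the mean, two-sided p = (1 + #{|null| ≥
|observed|})/(1 + draws) with exact enumeration for n ≤ 12, and the effect
size is Cohen's d_z = mean / sample SD (n−1). Correction across each ROI
family uses the single-step max-statistic rule with |mean/SE| as the
family statistic (scale-free across ROIs). Between-region differences use a
permutation null that independently permutes each participant's vector of
region values; the omnibus statistic is the one-way repeated-measures F.
The parametric omnibus ANOVA applies the Greenhouse–Geisser correction, with
epsilon computed from the double-centered sample covariance and floored at
1/(k−1); Huynh–Feldt would be a slightly less conservative alternative.

## Numerical and design choices

- RT clipping winsorizes at mean ± 2.5 sample SD of the raw
  participant-condition cell (a discard mode exists); because the bounds
  derive from the raw cell, clipping is a projection onto a fixed interval
  and is idempotent. RTs from hits and false alarms pool into the clipped
  mean. Out-of-window responses count as absent.
- The 2×2 repeated-measures ANOVA is computed as the squared one-sample t
  of per-participant contrast scores (exact for two-level factors; no
  sphericity correction is needed), with contrast scores grouped as paired
  differences so identical cells cancel exactly in floating point.
- Smoothing uses reflective boundaries, under which a normalized Gaussian
  kernel preserves the image mean to machine precision.
- Seeds derive from a single master seed through `SeedSequence` spawning;
  identical configuration and seed reproduce every output bit-identically.
- Scaled problem sizes used by the test suite, chosen to keep the default
  run fast while preserving the statistical content: 16³ or 16×16×12 grids,
  200 replicates × 20 participants × 1,000 permutations for FWER
  calibration (one short 160-s run per participant), 200 participants for
  noisy recovery, and 50 cohorts of 10 participants (exact 2^10 sign-flip
  enumeration) for the qualitative ROI-pattern suite.

## Known limitations

- The noisy-recovery acceptance check compares 96 region × condition means
  with truth at ±2 SE each; with unbiased estimation the expected number of
  chance exceedances is ≈4, so that check is stricter than its nominal
  level and can fail on individual bins without any systematic error (see
  the recovery diagnostics: mean z ≈ 0 across seeds).
- Cluster centers of mass are unweighted; t-weighted centroids would differ
  for asymmetric clusters.
- The AR(1) prewhitening is a single iteration with binned coefficients and
  reports the modal bin's covariance factor for contrast SEs.
- External datasets can be analyzed if they follow the simulated layout,
  but fROI spheres must then be supplied explicitly; without them the fROI
  stage is skipped.
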