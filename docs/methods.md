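# Methods

This note documents the models and numerical conventions implemented in
`pcfdc`: what the synthetic cohort generator simulates and deliberately
omits, the seed-refinement and mapping procedures, the statistics layer,
the prediction framework, and the design choices made where more than one
reading was defensible. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Synthetic normative cohorts

Every downstream module is exercised on cohorts drawn from an explicit
generative model (`pcfdc.synthetic`):

* **Networks.** A small set of pairwise-disjoint planted networks; each
  network q has a latent white Gaussian time-course `s_q(t)` with standard
  deviation `timecourse_sd` (default 1.0), drawn independently per subject.
* **Tissue compartments.** Member voxels in grey matter receive the latent
  at amplitude 1; member voxels in white matter at amplitude
  `wm_signal_scale` (default 0.35 — WM BOLD runs at roughly a quarter to a
  half of GM amplitude). Each compartment adds independent voxel noise
  with its own SD (`gm_noise_sd`, `wm_noise_sd`, both default 1.0).
* **Shared WM fluctuation.** Every white-matter voxel additionally carries
  one fluctuation common to the whole compartment, with SD `wm_common_sd`
  (default 0.3). This term stands in for the broad, low-amplitude
  coherence of WM BOLD (vascular/physiological signal, crossing fibre
  systems). It is essential for realism of the *baseline*: a whole-lesion
  seed owes its diffuse positive connectivity background to weak coherence
  among WM voxels. With mutually independent WM noise the refined seed
  would dominate the baseline at every threshold and the characteristic
  strength crossover (below) could not occur at all.

Because latents are white and Gaussian, expected correlations are closed
form: two GM members of the same network with latent SD `s` and noise SD
`σ` correlate at `s²/(s²+σ²)` (0.5 at the defaults); two non-member WM
voxels at `c²/(c²+σ²)` ≈ 0.08 with `c = 0.3`. The generator is
deterministic given its seed.

The standard study layout (`default_study`) is a 16³ voxel grid at 2 mm
with a grey slab over a white slab, three networks of 48 GM + 12 WM voxels
each, 150 timepoints, and **60 normative subjects**. The subject count is
the condition that matters most: the refinement rests on the first
principal component of an n-voxel × m-subject matrix, and PC1 is only
stable when m is comfortably larger than n (real applications use
normative samples of ~170 subjects against lesions resampled to a few
hundred voxels). With m near n the component mixes and tissue selectivity
degrades; 60 subjects against 20-voxel lesions preserves the m ≫ n regime
at desk scale.

Synthetic lesions take `n_gm_voxels` from the target network's GM core
(the coherent compartment) and `n_wm_voxels` from the *whole* WM mask, so
a lesion cuts through white matter unrelated to the cortical area it hits,
as infarcts do. Behavioural scores are a noisy linear functional of
subject maps: `score_i = Σ_v w(v)·map_i(v) + N(0, noise_sd)`.

What the generator does **not** emulate: haemodynamic autocorrelation,
motion and physiological noise spectra, scanner drift, spatial smoothness
of noise, overlapping or hierarchical networks, and inter-subject
anatomical variability. Passing tests therefore demonstrate that the
algorithms do what they claim under a known correlation structure — not
that the refinement is advantageous on any particular real dataset.

## Seed refinement (PC-FDC) and the FDC baseline

For one subject, the within-lesion strength vector averages each row of
the Fisher-z-transformed n × n correlation matrix, **excluding the
diagonal** (a voxel's unit self-correlation would otherwise make every
average infinite). |r| is clipped at `1 − 1e-7` before `atanh`, with a
warning, so duplicate series cannot poison the matrix. Voxels outside a
run's brain mask or with zero temporal variance are dropped and reported;
validity is harmonized across subjects by intersection (a voxel invalid
for any subject is dropped for all), keeping the strength matrix
rectangular under one row-major voxel ordering.

Subjects whose global |strength| (column mean of absolute values) deviates
more than 3 sample SDs from the sample mean are excluded before PCA; with
zero SD nothing is excluded, and exclusion never reduces the sample below
three subjects.

The PCA treats subjects as observations and voxels as variables, centres
variables across subjects, and does **not** scale them (covariance PCA):
amplitude information is what separates coherent grey-matter voxels from
the rest, so correlation-PCA would discard part of the signal of interest.
The component sign is fixed so coefficients correlate non-negatively with
the subject-mean strength vector — thresholding uses |coefficients|, so
results are sign-invariant, but reproducibility wants a convention. The
implementation is an SVD of the centred matrix; a brute-force
eigendecomposition of the voxel covariance serves as an independent test
oracle (agreement < 1e-8).

Seed thresholding computes the given percentile (default 20, linear
interpolation between order statistics) of the |coefficient| distribution
and keeps voxels **strictly** above it; the sensitivity sweep values 5, 10,
20, 50 and 80 are plain parameters. If every coefficient ties at the
cutoff the seed would be empty and an error is raised. The FDC baseline
seed is the unmodified lesion. Component index is exposed as a parameter
for second-component analyses; no PC2-specific logic exists.

## Network maps and permutation inference

Single-subject maps are the Fisher-z of the Pearson correlation between
the seed's mean time-course and every brain voxel; voxels outside the
brain mask are 0, zero-variance voxels get z = 0 with a warning. The
r-map is the voxel-wise mean over subjects. The one-sample t-map uses
sign-flipping of whole subject maps with the maximum-|t| null across
voxels for family-wise error control; the identity permutation is always
a member of the null set, so p ≥ 1/n_perm. Voxels with zero
between-subject variance receive t = 0 when their mean is 0 and a signed
sentinel (excluded from the max-statistic null) otherwise. Max-statistic
FWE replaces cluster-enhancement (TFCE) inference deliberately: it is
exact for the same null and needs no cluster-forming machinery.

The paired voxel-wise test runs both one-sided contrasts at α = 0.025
each (two-tailed 0.05 overall); the two-sample test permutes group labels
and uses max |t| at α = 0.05; the behaviour-correlation test regresses
map values on the score with an intercept and lesion volume as nuisance,
and permutes the reduced-model residuals of the data (Freedman–Lane, the
default scheme of the standard permutation tools for covariate designs)
at α = 0.01. All permutation procedures are reproducible from their seed.

## Map statistics

* CDF cutoffs are taken over strictly positive voxel values only
  (percentiles 10/20/50/80/90/95/99 by default), optionally within a
  GM/WM/whole-brain domain mask.
* Thresholded map means use strict inequality (`value > z_threshold`,
  default thresholds 0 and 0.2) and population SD; an empty selection
  returns (NaN, NaN, 0) rather than raising.
* NCI divides the winning template's spatial correlation by the mean of
  the losing templates' correlations, negatives included as-is; when that
  mean is non-positive the index is undefined (NaN, flagged) but the
  winner is still reported. Exact ties go to the first template in atlas
  order. NCI is invariant to positive rescaling of the map. The domain
  defaults to whatever mask the caller supplies (whole-brain recommended).
* A lesion is classified "pure WM" iff its WM/size ratio is strictly
  greater than 0.9.
* The Wilcoxon signed-rank test drops zero differences, mid-ranks ties,
  enumerates all 2ⁿ sign assignments exactly for n ≤ 12, and uses the
  tie-corrected normal approximation above; the Friedman statistic is
  `12/(nk(k+1))·ΣR_j² − 3n(k+1)` with mid-ranks, all-tied data giving 0.

## Behaviour prediction

Subject r-maps are reduced by PCA (subjects × voxels, centred); the
smallest leading component set reaching 95% cumulative variance is kept,
never fewer than two components, and loadings are retained for
back-projection. The score matrix is z-normalized with **one global
mean/SD pair** — not per column — preserving the components' variance
ordering; the outcome is z-normalized likewise, which is why the ridge
model carries no intercept.

λ is tuned inside each outer leave-one-out fold by an inner leave-one-out
search over 100 log-spaced values in [1e-5, 1e5] (ties to the smallest λ),
so outer predictions are honest. The inner search uses the exact
linear-smoother identity `e_i = (y_i − ŷ_i)/(1 − H_ii)`, requiring one SVD
per fold instead of refitting every (fold, left-out point, λ) triple; a
brute-force reimplementation that does refit everything is the test oracle
(agreement < 1e-8).

The reported R² is `1 − Σ(Y−Y′)²/Σ(Y−Y″)²` with Y″ the **mean of the
predictions**. This is implemented literally because it is the accuracy
definition the prediction framework is specified with; it differs from the
conventional coefficient of determination (reference: mean of Y) whenever
predictions are biased, and can be negative. The conventional form is
available via `conventional=True`. The permutation p-value is
`count(null R² > observed)/n_perm` exactly — no +1 correction — with a
corrected variant behind a flag; a consequence of the uncorrected form is
that p = 0 is attainable. Null models' across-fold mean weights are
harvested from the same permutation runs and serve as the null
distribution for the per-component reliability t-tests
(Benjamini–Hochberg at q = 0.05); surviving averaged weights are mapped to
voxel space through the transposed loadings.

## Problem sizes in the validation battery

The replicate experiments (`pcfdc.experiments`, used by both
`tests/test_acceptance.py` and `scripts/acceptance.py`) run at sizes
chosen so the whole battery completes in a few minutes on one CPU: 50
random matrices up to 20 × 10 for the PCA oracle; n = 20, p = 5 for the
ridge oracle; 50 lesion replicates for tissue selectivity; 20 for the
strength crossover; 30 for network assignment; 20 replicates × 500
permutations at n = 60 subjects (SNR 2) for prediction power; 50
replicates × 200 permutations for null-p uniformity; 100 null simulations
× 200 permutations for the family-wise error rate. Prediction-experiment
maps are drawn directly from a low-rank pattern-plus-noise model rather
than through the full seed pipeline; the linear-readout behaviour model is
identical either way and the map route is exercised separately.

## Known limitations

* The generator's closed forms rely on white latents; autocorrelated BOLD
  would widen the sampling variance of correlations and lower effective
  degrees of freedom, which none of the permutation procedures here need
  to model but any application to real runs should remember.
* The NCI denominator can legitimately be near zero for maps orthogonal to
  every template; consumers must handle the `undefined` flag.
* With the uncorrected permutation counting rule, reported p-values of 0
  should be read as p < 1/n_perm.
* Nearest-neighbour resampling is provided for binary masks only;
  continuous images must arrive on the template grid.
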