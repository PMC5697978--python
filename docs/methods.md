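# Methods

This note documents the models, numerical choices and limitations of the
package in the order the pipeline runs. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic cohort generator

The generator emulates a normative-comparison study: a healthy-control
cohort (default 20, sex-balanced) and a small patient group (default 10,
9:1 female:male), each subject with a label map, a BOLD run with
physiological recordings, and a skeletonized FA map. Defaults are the
emulated study's conditions: 150 volumes at TR = 2 s, in-plane BOLD voxels
3.4375 × 3.4375 × 3.5 mm.

**Latent-signal model.** Region mean signals are drawn from a stationary
zero-mean multivariate Gaussian whose correlation matrix carries the
planted link structure (all within-network links at r = 0.45 by default;
per-patient weakened links — 3 per network by default — overridden to
r = 0). There is no hemodynamic convolution: the analysis consumes only
second-order structure, and a Gaussian with the target correlation
exercises every downstream stage exactly. Voxels of a region share the
region's latent signal plus independent N(0, 1) noise on a baseline of
100. Averaging ~50–100 voxels per region shrinks the noise contribution to
a few percent of the latent variance, so extracted correlations converge
to the planted targets (verified in the suite at 200 subjects × 150
timepoints within 0.05).

**Covariance repair.** Arbitrary user link sets can imply an indefinite
correlation matrix. Negative eigenvalues are clipped at zero and the
matrix renormalized to unit diagonal. This slightly perturbs planted
values when the input was indefinite; planted-recovery guarantees apply to
the repaired targets.

**Confounds.** Cardiac and respiratory confounds are pure sinusoids with a
random phase per subject, added coherently to all brain voxels; the exact
regressor time courses are returned as the physiological trace, sampled at
frame times. This matches the linear-regression removal model exactly, so
the residual-orthogonality test is sharp. The cardiac fundamental is
1.1 Hz rather than a round 1 Hz: sampled at TR = 2 s, 1 Hz aliases to an
exactly constant column (a degenerate design), while 1.1 Hz aliases to
0.1 Hz — above the 0.08 Hz passband, as a real aliased cardiac series
would be. Respiration is 0.3 Hz (aliases to 0.2 Hz).

**Label maps.** Regions occupy contiguous runs of the flattened grid
(6 000 labeled voxels on a 22 × 22 × 18 grid by default) — geometry is
irrelevant to every consumer except voxel counting. Tissue-group voxel
fractions are drawn per subject around planted group means (controls
GM 0.453 ± 0.011, WM 0.281 ± 0.0168; patients GM 0.435 ± 0.021,
WM 0.297 ± 0.048; CSF is the remainder), and the left/right split of the
thalamus realizes a planted asymmetry index (drawn per subject:
controls 0.089 ± 0.057, patients 0.188 ± 0.172, folded to be
non-negative) up to one-voxel quantization. V_R = round(S(2 − AI)/4),
V_L = S − V_R for a combined count S, inverting
AI = (V_L − V_R)/((V_L + V_R)/2).

**FA skeletons.** A fixed synthetic "skeleton" (two coronal + two axial
sheets, ~1 700 voxels at the default grid) carries values
N(0.5, 0.03) truncated to [0.2, 1]; patients get a spherical lesion patch
(radius 3 voxels intersected with the skeleton) reduced by 0.15. Lesion
geometry is a generator convenience, not a claim about MS lesion shape.

**Randomness.** Every draw comes from a stream keyed by
(master seed, stream id, subject kind, subject index), so identical
(seed, config) pairs are bit-reproducible and extending a cohort never
perturbs earlier subjects.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: hemodynamics, head motion, scanner drift, EPI
distortion, slice timing, registration error, anatomically shaped regions,
spatially structured noise, and non-Gaussian link distributions. Passing
tests establish that the *statistics* are implemented and calibrated
correctly, not that the pipeline is robust to real-world artifacts (the
stages that handle those — skull stripping, segmentation, realignment,
registration, skeletonization — are deliberately out of scope; inputs are
assumed aligned).

## Preprocessing

**Physio regression.** Each voxel series is replaced by its least-squares
residual against [intercept, linear trend, cardiac, respiratory], the
traces linearly interpolated to frame times (no cardiac/respiratory phase
expansion — the minimal reading of a "linear regression" cleanup).
Residuals are exactly orthogonal to every retained column; numerically
constant columns are dropped with a warning instead of producing a
rank-deficient design. Regression runs before filtering, and filtering is
voxelwise before extraction; by linearity the region-mean signal is
identical either way.

**Low-pass filter.** 4th-order Butterworth applied forward–backward
(zero phase, no temporal shift of correlations). Because two passes square
the magnitude response, the design frequency is scaled by
(√2 − 1)^(−1/8) ≈ 1.1165 so the *combined* −3 dB point sits at the nominal
cutoff (0.08 Hz default). This keeps the passband contract — combined gain
0.935 at 0.8× cutoff, ≥ 0.999 at 0.03 Hz — and the stopband one (0.0094 at
2× cutoff); an uncorrected 4th-order two-pass design would fall to 0.856
at 0.8× cutoff. Any filter meeting these gain bounds is a conforming
realization. The cutoff (after correction) must stay below Nyquist =
1/(2·TR).

## Networks

Region-name → label mapping ships as an editable JSON dictionary with a
synthetic default; real studies substitute their own label scheme. The
default-mode network is encoded with 4 bilateral regions (medial
prefrontal cortex, cingulate cortex merged, precuneus, lateral parietal
cortex): the merged-cingulate reading is the only one consistent with its
published 28-link count. **Known discrepancy:** the attention network's
6-region listing gives 12 nodes and 66 links, yet its published link count
is 45 (which would require 10 nodes). The package ships the listing as
printed and documents, rather than resolves, the inconsistency; no
headline quantity is taken from the attention link count. The fornix is
kept in the visuospatial working-memory network as listed although it is a
white-matter structure. Regions shared between networks (e.g.
supramarginal gyrus) are independent entries per network.

## Connectivity

"Cross-correlation" is computed as the zero-lag Pearson coefficient — one
scalar per link, the only reading consistent with one number per matrix
element. No Fisher z-transform is applied before thresholding (an arctanh
option exists, off by default). Zero-variance or missing-label nodes
propagate NaN to their links and are excluded from counts downstream.
Input BOLD and label volumes must share grid and affine (1e−4 tolerance);
there is no implicit resampling.

## Normative model and group statistics

Per-link mean and sample SD (denominator n − 1) across controls; with sex
labels present, stratification is on by default and each patient is
compared against same-sex controls. Links with fewer than two usable
controls are unmodelable and yield `undefined` statuses.

The ± 2 SD rule is two-sided, but the headline count is *reduced* links
only (both counts are emitted, and the link-frequency map is written in
both variants). Finite-cohort calibration: with 20 controls the per-link
null flag rate is E[2·P(|t₁₉| > 2/√(1 + 1/20))] ≈ 6.6 %, above the
asymptotic 4.55 %; the acceptance band [0.03, 0.09] asserts exactly this
inflation. With 10 controls per sex stratum the inflation is larger —
which is why demo-cohort mean reduced counts exceed the 3 planted links
per network.

The one-sample deficit t-test defaults to null mean 0; a calibrated
alternative (expected false-flag count Φ(−2)·L per patient) is available,
since the emulated study does not state its null. No multiple-testing
correction is applied across links or networks, matching the emulated
analysis. Network-by-network Pearson correlations of per-patient counts
require at least 3 patients and identical patient sets.

Volumetry uses Welch's unequal-variance t-test (group sizes are unequal by
design, 10 vs 20). The asymmetry index is reported as a magnitude by
default: across patients in which either hemisphere may be atrophic, only
|AI| has a coherent group mean; the signed variant is behind a flag.
Total brain volume includes CSF spaces, so GM + WM + CSF fractions sum to
one identically.

## FA single-case comparison

Default statistic is Crawford–Howell: t = (x − mean_c)/(sd_c √(1 + 1/n_c))
with n_c − 1 df. Note the pooled 1-vs-n two-sample t is *algebraically
identical* to this form (the single patient contributes no variance and
no df), so the anti-conservative alternative offered behind the
`zscore` flag is the naive z form t = (x − mean_c)/sd_c with a normal
p-value — the form casual single-case analyses actually use. Voxels with
control-mean FA < 0.2 (non-white-matter) are excluded; zero-SD voxels
yield NaN and are counted in the output. No cluster-level or TFCE
correction is applied. The overlay writer is purely presentational.

## Pipeline and problem sizes

Stages communicate via files (uncompressed `.nii`, float32 for images;
TSV tables; JSON summaries with sorted keys), so any stage is re-runnable
and the full bundle is byte-reproducible from (config, seed). The shipped
demo cohort — 20 controls, 10 patients, 150 timepoints, 22 × 22 × 18 grid,
6 000 labeled voxels — was chosen so a complete run plus its statistical
calibration experiments (1 000 null patients for the band calibration,
100 patients and 50–100 replicates for sensitivity/power, 3 null FA
replicates over ~1 700 skeleton voxels) completes in well under a minute
on a single CPU while keeping Monte-Carlo error a small fraction of each
acceptance band.

## Known limitations

* Single-session, motion-free, pre-aligned inputs only; no registration.
* The Gaussian latent model cannot probe robustness to autocorrelated or
  heavy-tailed BOLD noise; low-pass filtering does reduce the effective
  temporal degrees of freedom, widening link sampling error, and the
  normative band absorbs this only empirically.
* Label-map "regions" are contiguous index runs, not anatomical shapes;
  partial-volume effects are absent.
* The per-link normative model ignores correlations *between* links; the
  per-patient count distribution is therefore not binomial, and the
  deficit t-test treats it only through its empirical mean and SD.
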