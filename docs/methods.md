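# Methods

## Pharmacokinetic model

The enhancement model is the Brix-type constant-infusion two-compartment
exchange model: contrast is infused at a constant rate for a bolus
duration τ (default 7 s), exchanges between plasma and the
extravascular–extracellular space with back-transfer rate constant
`k_ep`, and is eliminated from plasma with rate constant `k_el` (both in
1/min).  The relative enhancement is

    E(t) = (A/τ′)·k_ep·[h(k_el,t) − h(k_ep,t)]/(k_ep − k_el),
    h(k,t) = ((e^{k·min(t,τ′)} − 1)/k)·e^{−kt},

with τ′ the bolus duration converted to minutes.  `h` is the convolution
of the unit boxcar infusion with an exponential washout, so E is
continuous everywhere; the limits k → 0 (h → min(t, τ′)) and
k_ep → k_el (−∂h/∂k) are substituted analytically when |k_ep − k_el| <
1e−6/min.  The transfer constants `k_pe` and `k_in` complete the
compartment diagram but are neither fitted nor mapped; the analysis
rests on the spatial statistics of A, k_ep and k_el only.  No arterial
input function, T1 mapping, or concentration conversion is attempted:
the pipeline operates on signal enhancement.

**Identifiability.** The model curve is exactly invariant under
swapping (k_ep, k_el) with the amplitude rescaled to preserve A·k_ep.
Fits are therefore canonicalized to the physiological branch
k_ep ≥ k_el.  This matters: without the convention, "recovered
parameters" are defined only up to a mirror.

**Fitting.** Voxel curves are converted to relative enhancement
(S(t) − S(0))/S(0); a non-positive baseline marks the voxel unfittable.
Bounded least squares runs over A ∈ [0, 50], k_ep ∈ [0, 10]/min,
k_el ∈ [0, 2]/min, multi-started from the 3 × 3 rate grid
{0.1, 0.5, 2.0} × {0.01, 0.1, 0.5} (1/min).  The model is linear in A,
so the amplitude is profiled analytically at each grid candidate before
gradient refinement — the per-curve path (`fit_voxel_curve`) refines
the two best candidates with scipy's bounded trust-region solver, while
`fit_volume` refines every masked voxel in lockstep with a batched,
damped Gauss–Newton (Levenberg–Marquardt) iteration minimizing the
identical objective.  The two paths agree to ~1e−8 on test curves; the
batched path keeps a 256 × 256 × 64 study at desk scale.  The A
pseudoimage stores the fitted curve's peak on a 1 s grid (A_peak) — a
model-derived, noise-robust version of "peak enhancement reached" —
rather than the raw data maximum.

**Precision at the default acquisition.** With six samples 120 s apart,
noiseless curves are recovered to machine precision, and Monte-Carlo
recovery at noise sd = 1% of the curve peak gives median relative
errors of roughly 1.6% (A), 4% (k_ep) and 5% (k_el).  The k_el figure
is not an optimizer deficiency: a Cramér–Rao analysis of this design
puts the efficient estimator's median |error| for k_el at ≈5%, so k_el
sits at its statistical identifiability limit — five post-contrast
points simply carry little washout information at k_el ≈ 0.05/min.

## Body mask

Tissue is separated from air by an Otsu threshold on the baseline
volume followed by one 6-connected morphological closing.  A constant
baseline yields an all-false mask with a warning.

## Texture stage

Continuous parameter volumes are quantized to G = 16 levels, linearly
between the 1st and 99th percentile of in-mask values (clipped
outside, so a handful of extreme fit outliers cannot swallow the
dynamic range); out-of-mask voxels get level 1.  Sixteen levels keep
the ≤ 80-voxel windows from producing overly sparse matrices.

A 5 × 5 × 2 scanning volume of interest (short axis through-plane) is
raster-scanned over each volume.  Per window and direction
((1,0,0), (0,1,0), (0,0,1); distance 1, chessboard), ordered gray-level
pairs are tallied in both orders (symmetric construction — all ten
statistics used are invariant to symmetrization) and normalized to sum
1.  The ten statistics use base-2 logarithms (entropies in bits), sum
variance is computed about the sum average (the accepted correction of
the classical typo), and the correlation of a constant window (zero
marginal variance) is defined as 0.  Difference entropy, the two
information measures of correlation and the maximal correlation
coefficient are excluded by design.  Statistics are assigned to the
window-local centroid (2, 2, 0) — the lower slice of the even z-axis —
and windows must fit entirely: border voxels are zero with
`validity_mask` false, so padding never contaminates textures.
Internally the scan is vectorized (pair-code fields, sliding-window
histograms, batched statistic evaluation); unit tests pin it to a
literal nested-loop reference on random windows to 1e−10.

## Classifier

Balanced voxel sets: half of the lesion-marked voxels are sampled as
positives, the same number of negatives from body tissue inside the
texture validity region; when a benign-lesion mask is supplied, half of
the benign voxels (capped at the positive count) are placed among the
negatives with target 0 — benign tissue is a *negative* class by
default.  The pooled sample is split in half, stratified by label, into
disjoint training and verification sets whose sizes differ by at most
one voxel.  All sampling is reproducible from a single seed.

The network has 90 inputs (z-scored with training-set statistics;
zero-variance features dropped and recorded), one hidden layer of 15
tanh units and one linear output unit.  A purely linear hidden layer
would collapse to linear regression, so the conventional
tanh-hidden/linear-output reading is used.  Full-batch gradient descent
with momentum (learning rate 0.05, momentum 0.9, ≤1500 epochs)
minimizes the MSE against 0/1 labels; training early-stops when the
verification MSE has not improved for 100 epochs and the
best-verification weights are restored.  The linear output is clipped
to [0, 1] before thresholding at the default sweep
{0.39, 0.49, 0.59, 0.69, 0.78, 0.88, 0.98}; masks are nested by
construction, so TPF and FPF are non-increasing in the threshold.

## Evaluation

Voxelwise confusion counts are taken over an evaluation universe —
body ∧ texture-validity by default (configurable to the whole volume);
counting air as true negatives would shrink FPF artifactually — minus
an exclusion mask holding every voxel sampled for training *or*
verification (verification voxels steered early stopping, so they are
biased too).  TPF = TP/(TP+FN), FPF = FP/(FP+TN); an empty-truth TPF is
reported as missing, never as 0.  "Overall" fractions pool the raw
counts across subjects; per-subject fractions feed the reader
comparison.  The paired test is a one-sample two-sided t-test of the
per-subject difference vector (classifier minus second reader) against
mean 0: t = d̄/(s_d/√n), df = n − 1, α = 0.05, reported as (t, df, p,
reject) without further interpretation.  A zero-variance difference
vector is flagged degenerate (reject with p ≈ 0 if the mean is
non-zero, fail to reject otherwise).

## Phantom

The generator emulates the target acquisition: 6 time points (baseline
+ 5 post-contrast, 120 s apart), τ = 7 s, a 64 × 64 × 16 volume with an
ellipsoidal body (radii 45% of each extent) of baseline intensity 100
in zero air.  Tissue classes follow the model with
(A, k_ep, k_el) = (2.0, 1.2, 0.05) malignant, (1.0, 0.4, 0.02) benign,
(0.2, 0.2, 0.01) normal — malignant k_ep ≫ normal k_ep, mirroring the
radiological heuristic that malignant microvasculature is denser and
leakier.  Default lesions: two malignant ellipsoids (radii (5,5,3) and
(4,4,2)) and one benign ((4,4,2)).  Additive Gaussian noise with sd =
1% of baseline (Rician available as an option) and optional rigid
in-plane shifts of random time frames (motion artifacts) complete the
simulation.  A "second reader" is simulated by eroding or dilating each
truth lesion component at random (radius 1 by default) and missing
components with a stated probability.

What the phantom does *not* emulate: realistic breast anatomy, coil
inhomogeneity, partial-volume mixtures, k-space/reconstruction
artifacts, or inter-voxel noise correlation.  Passing tests on the
phantom therefore demonstrate the pipeline's internal correctness and
end-to-end behaviour under known kinetics, not clinical performance;
the near-perfect phantom operating points (TPF ≈ 0.99 at FPF ≤ 0.01)
reflect the phantom's clean class structure and should not be read as
expected patient-data performance.

## Problem sizes and numerical choices

The bundled study conditions are one 64 × 64 × 16 × 6 phantom subject
for the operating-point run and four 48 × 48 × 12 × 6 subjects (training
on two) for the reader-comparison t-test — large enough to exercise
every stage at realistic local statistics while keeping a full run in
the low minutes on a single CPU.  Tolerances: k_ep ≈ k_el degeneracy at
1e−6/min; co-occurrence normalization asserted to 1e−12; 0·log 0 ≡ 0
throughout; texture/statistic agreement with the brute-force reference
at 1e−10; t-test agreement with an independent implementation at
1e−10.  Voxel indices are 0-based, axis order (x, y, z, t); volumes
travel as NIfTI with affines preserved, masks as uint8, acquisition
timing in a JSON sidecar.

## Known limitations

- k_el at normal-tissue magnitudes is at its identifiability limit for
  the 6-point acquisition (see above); its pseudoimage is accordingly
  the noisiest of the three.
- The quantization (G = 16, 1–99 percentile, linear) is a design choice
  exposed in `TextureConfig`; texture values are only comparable across
  volumes quantized the same way.
- The pipeline assumes a single coherent enhancement model per voxel;
  partial-volume voxels at lesion rims are systematically intermediate,
  which is where classification errors concentrate.
- Training pools at most a few thousand voxels; the network is small by
  design and no cross-validation is performed beyond the
  verification-set early stopping.
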