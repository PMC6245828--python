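# Methods

`retinotort` measures retinal vascular tortuosity from fundus-style images
and provides the statistical workbench used to validate such measurements
against a panel of human graders.  This note records the models, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Tortuosity metrics

All metrics operate on an ordered sub-pixel vessel centerline with arc
length L_c and chord length L_x (x right, y down, pixel units).

* **Hart** — `tau = L_c / L_x − 1`.  Dimensionless, zero iff the samples are
  collinear in order, invariant to rigid motion and uniform scaling.
* **Grisan** — the vessel is partitioned into `n` maximal runs of
  constant-sign curvature with per-run arc/chord lengths L_csi, L_xsi, and
  `tau = (n − 1) / L_c · Σ_i (L_csi / L_xsi − 1)`.  Units 1/px (a tortuosity
  density).  A historical variant with the `(n − 1)/n` prefactor is
  available behind `normalize_by_n`; the plain `n − 1` form is the default.
* **Trucco** — `tau = (Σ_j |k(j)|^p)^(1/p)` over interior centerline points,
  with `k` the signed curvature `k = (x′y″ − x″y′)/(x′² + y′²)^{3/2}` and
  `p` a strictly positive integer (default 1).
* **Onkaew** — `tau = (n − 1)/n · 1/L_c · Σ_i |K(p_i, k)|` where `K` is a
  chain-code style curvature and `n` the number of constant-sign runs of
  that profile.  Zero whenever the turning never changes sign.

Per-vessel values combine into a whole-retina score by arc-length-weighted
averaging, `tau_total = Σ L_ci·tau_ci / Σ L_ci`, so the total always lies
within the range of its constituents.

### Curvature estimation

The derivative curvature resamples the centerline to uniform arc-length
steps (`spacing`, default 1 px), smooths the coordinates with a Gaussian of
scale `sigma` (arc-length px) and applies central differences.  The sample
grid is `linspace(0, L, m)`, which makes resampling commute with reversing
the point order; all four metrics are reversal-invariant and rigid-motion
invariant to floating-point precision.  The first and last two points carry
curvature 0 and drop out of the Trucco/Onkaew sums.

`sigma` defaults to 4 px.  The derivative scale must exceed the correlation
length of residual centerline jitter, which for traced-and-refined skeleton
paths is set by the detection scales (2–4 px); a smaller default (e.g. 2 px)
lets pixel jitter masquerade as curvature and, on near-straight vessels,
inverts the ranking produced by the inflection-count metrics.  For analytic
curves at unit scale the parameters must be scaled with the geometry
(`spacing`, `sigma` and `zero_tol` all carry length units); the 1/s scaling
law of the density metrics holds exactly under that covariance.

The chain-code curvature labels each step of the (optionally 1-px-resampled)
polyline by its direction relative to the previous point; on an 8-connected
pixel chain those directions are exactly the eight Freeman code angles.
`K(p_i, k)` is the mean signed turning angle over a window of half-width `k`
points (radians per point).  Computing turning from the raw step directions
rather than from re-quantized codes keeps the measure exact on pixel chains
while extending it continuously to sub-pixel polylines, where hard
quantization would either zero the profile (dense sampling) or break
rotation invariance.  The default window `k = 5` averages grid-quantization
wobble to near zero while preserving genuine turning.

### Constant-sign partitioning

Points with `|k| < zero_tol` inherit the sign of the surrounding run; an
all-zero profile is one subsegment.  Runs shorter than `min_run` points
(default 5) merge into the longer neighbour, suppressing noise-driven
micro-inflections.  `zero_tol` defaults to 1e-3 /px: a curvature radius of
1000 px is treated as straight, which is far gentler than any clinically
tortuous vessel at typical fundus resolution yet above the jitter floor of
extracted centerlines.  The Onkaew sum uses |K| magnitudes; a literal signed
sum would telescope to ~0 on S-shaped vessels and destroy the property that
inflection-rich vessels score higher, which is the stated point of the
segment-count metrics.

## Vessel extraction

1. **Ridge detection.**  A multiscale creaseness operator: at each scale the
   image gradient (of the inverted image, so vessels are bright ridges) is
   orientation-regularized by the structure tensor; the response is the
   negative divergence of the dominant-eigenvector field sign-aligned with
   the gradient, weighted by the tensor energy `sqrt(lambda_1)`.  The energy
   weighting matters: the orientation field is unit length, so the raw
   divergence is contrast-blind and responds to faint noise creases as
   strongly as to vessels.  Scales default to {2, 3, 4} px, matched to
   vessel half-widths; the per-pixel response is the maximum over scales.
2. **Binarization and thinning.**  Otsu's threshold on the strictly positive
   responses (configurable), removal of components smaller than 10 px, then
   topology-preserving thinning to a width-1 skeleton (no 2×2 block).
3. **Tracing.**  Skeleton pixels with ≥ 3 neighbours are junctions; the
   remaining pixels form 8-connected paths traced from the endpoint with the
   smallest (y, x), making the decomposition deterministic.
4. **Sub-pixel refinement and smoothing.**  Each traced path is resampled to
   1 px, moved to the ridge-strength centroid along the local normal
   (half-width 2.5 px), Gaussian-smoothed (σ 1.5 px) and boxcar-smoothed
   (window 3, endpoints preserved).  Refinement roughly halves the residual
   grid jitter (mean deviation from phantom ground truth ≈ 0.2–0.4 px).

Segments shorter than 10 points are dropped from tree totals and logged.
RGB input reduces to the green channel (highest vessel contrast).

## Synthetic data

* **Vessels** — lines, circular arcs (`hart = θ/(2 sin(θ/2)) − 1`), and
  sinusoids with a configurable half-wave count (arc length by quadrature;
  a sinusoid with h half-waves has h − 1 interior inflections).
* **Phantoms** — dark tubes (distance-transform thresholding at width/2,
  default width 5 px) on a bright background, optional 0.5 px optical blur
  and seeded Gaussian noise; layouts are banded and the generator rejects
  frames where vessels come closer than twice the width unless crossings
  are requested.  Bit-identical per seed.
* **Rating panels** — a latent four-grade severity per image drawn from a
  prior (uniform by default, mirroring a balanced-severity study design);
  each rater reports through a row-stochastic confusion matrix,
  independently per round.  The closed-form expected Cohen kappa for two
  raters (`p_o = Σ_g π_g Σ_c A_gc B_gc`, `p_e` from the induced marginals)
  serves as the analytic oracle for recovery tests.

What the phantoms do **not** emulate: optic disc and lesions, illumination
gradients, vessel-width variation, branching trees, artery/vein contrast
differences.  Passing the recovery benchmarks therefore demonstrates the
correctness of the geometry/extraction machinery, not clinical-grade
performance on fundus photographs.

The extraction-recovery benchmark uses clearly tortuous vessels
(arc/chord excess ≈ 0.05–0.2).  Pixel-grid extraction has an absolute noise
floor of roughly 1e-3 on the arc/chord excess, so a relative error bound is
ill-conditioned for near-straight vessels; the benchmark measures relative
recovery where it is well defined and the noise floor is reported here as a
known limitation.  The same floor limits the Grisan/Onkaew discrimination of
*near-straight* vessels in the synthetic end-to-end study.

## Rater agreement and validation

Cohen's kappa is `(p_o − p_e)/(1 − p_e)` with `p_e` from marginal products;
the degenerate case (both raters constant and identical, `p_e = 1`) is
reported as NaN, never coerced to 0 or 1.  Interpretation bands are the
half-open intervals [0, 0.20] slight, (0.20, 0.40] fair, (0.40, 0.60]
moderate, (0.60, 0.80] substantial, (0.80, 1] almost perfect; negative
values are "less than chance".

Majority voting pools all votes of the given rounds (an expert rating in
two rounds contributes two votes); exact ties go to the higher —
clinically conservative, more symptomatic — grade and are flagged.
Consensus summaries report the fraction of images whose modal label reaches
R, R−1 and R−2 of R raters.

ROC curves use the decision rule score ≥ t → positive, with the symptomatic
class positive (higher tortuosity score → symptomatic).  Equal scores are
grouped at one threshold and the AUC is computed by the trapezoid rule on
integer confusion counts, which makes it *exactly* equal to the
Mann–Whitney pairwise probability with ties counted ½ — the two routes are
kept as independent implementations and cross-checked bit for bit.
Categorical expert predictions yield single (sensitivity, specificity)
points.

The packaged CSV fixtures are published *marginal* rating counts of a
five-expert, 60-image study (four-grade first round, binary second round,
majority-vote and consensus label sets).  Per-image expert labels were
never published, so pairwise agreement statistics cannot be recomputed from
them; they anchor the grouping arithmetic exactly and size the simulations.

## Study orchestration

`run_study` executes measure → agreement → ROC from a single config.  In
fully synthetic mode each image's latent grade drives both the phantom
(amplitude and inflection count grow with grade) and the simulated panel,
so the whole prognostic analysis runs under known ground truth.  The
consensus reference is an explicit labels file when provided; otherwise the
pooled majority vote is used and flagged in the report provenance.  All
randomness derives from one seed (split per purpose); reports round floats
to 6 significant digits and serialize with sorted keys, so re-running a
study is byte-identical.  Default problem sizes (10–16 images of 256² px,
3 vessels each, five raters, two rounds) keep a full study in the
low seconds while exercising every code path; all sizes are configurable.

## Known limitations

* Near-straight vessels: absolute tortuosity noise floor ≈ 1e-3 (Hart) from
  pixel discretization, even after sub-pixel refinement.
* The creaseness detector weakens at vessel crossings (conflicting
  orientations) and within ~2 scales of the image border.
* Onkaew's printed form leaves the summation index ambiguous; the per-point
  |K| interpretation implemented here is a documented choice.
* Kappa and ROC analyses assume complete rating tables (every rater rates
  every image); missing cells are rejected, not imputed.
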