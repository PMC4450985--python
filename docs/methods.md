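# Methods

This note records the models, defaults, and numerical choices behind
`spotcount`, and what the synthetic benchmarks do and do not establish.

## Pipeline model

The unit of candidacy is a strict 26-connected local intensity maximum in
the 3D stack. Maxima are 3D but Gaussian fits are 2D in the maximum's own
z-plane: a diffraction-limited emitter is approximately an isotropic 2D
Gaussian in its focal plane, and the axial profile is handled separately by
the focal-prominence feature. Plateaus (exact intensity ties with a
neighbor) yield no maximum; on quantized real data this can drop a spot
whose peak straddles two equal voxels, a deliberate trade against duplicate
candidates.

**Ranking and truncation.** Candidates are ranked by background-corrected
intensity: center pixel minus the median of the patch's border ring, a
local statistic robust to smooth background structure. Ranked candidates
are fit sequentially and the scan stops once `persistence_window` (default
30) consecutive fits have mean-squared error below a cutoff; everything
before the first member of that run is retained. The cutoff, when not set
explicitly, is `1.5 ×` the median fit MSE of a seeded sample (120) of the
dimmest decile of candidates. Rationale: the dimmest decile is essentially
never real signal, so its fit MSE estimates the image's noise floor; a run
of fits at the noise floor marks the point where the ranked list has
descended into pure noise. Two guards matter in practice:

- At realistic noise the MSE of a *true* spot is statistically close to the
  noise floor too (both ≈ the noise variance), so a narrow persistence
  window can fire inside the signal region. W = 30 makes that a ≲1e-3
  event while still stopping within a few thousand noise candidates.
- In adaptive mode at least `min_retained` (default 150) candidates are
  always kept. On clean stacks the rule can fire immediately after the last
  true spot, and downstream training/calibration needs a pool of labeled
  noise candidates to learn from. An explicit `mse_cutoff` disables the
  floor.

**Gaussian fitting** is a vectorized batched Levenberg–Marquardt
minimization of `A·exp(−((y−dy)²+(x−dx)²)/2σ²) + c` over the 7×7 patch
(side configurable, odd), with analytic Jacobian, per-patch damping, σ
clamped to [0.05, 4·side], at most 60 iterations, early exit on stall.
Initialization: `A = center−min`, offsets 0, `σ = side/6`, `c = min`.
A failed fit (non-finite or no cost improvement) returns the evaluated
initialization flagged `fit_ok = 0`, which becomes a classifier feature
rather than an exception. Batching matters: stacks at realistic noise have
tens of thousands of maxima, and the batch fitter does ~10k fits in a few
seconds where per-patch generic optimizers take minutes. Border patches use
mirror padding so their statistics stay scale-consistent.

**Features** (13, fixed order, versioned schema): raw center intensity;
background-corrected intensity; fitted A, σ, c; fit MSE; MSE/patch variance
(scale-free fit quality); A/border-ring sd (local SNR); fitted-center
displacement; patch mass above the border median; fraction of pixels above
half-maximum (footprint); center minus the mean of the same (y,x) pixel in
planes z±1 (focal prominence); fit-converged indicator. The set covers the
attribute families a human curator inspects — brightness, shape, fit
quality, 3D focus. Multiplying the stack by k > 0 scales the intensity
features by k, the MSE by k², and leaves the ratio/geometry features
unchanged (property-tested for k ∈ {2, 10}).

**Classifier.** Bagged decision trees (default 500), each grown on a
same-size bootstrap resample, Gini splits over `mtry = ⌈√13⌉ = 4` randomly
chosen features, `min_leaf = 5`. `min_leaf > 1` keeps leaf class
proportions informative as probabilities instead of collapsing to 0/1. The
preliminary probability is the unweighted mean across trees of the reached
leaf's signal proportion — proportion averaging, not majority vote, because
the averaged value is what gets calibrated. Trees are built with
scikit-learn and immediately exported to plain node arrays; prediction,
JSON serialization and reload use only those arrays (no pickles), and a
model refuses to score feature vectors from a different schema version.

**Calibration.** The corpus is the training set's out-of-bag preliminary
probabilities (each example scored only by trees whose bootstrap excluded
it), avoiding resubstitution optimism. Scores are binned at centers
0.0–1.0 step 0.1 (edges at midpoints, ends clipped), empty bins dropped,
and `g(p̂) = 1/(1+exp(a·p̂+b))` is fit by least squares weighted by bin
count (initialization a = −8, b = 4). A fit with a > 0 would be decreasing
and is rejected; the builder then falls back to a monotone nondecreasing
clamp of the raw bin proportions, flagged `monotone_bins` — this typically
happens when the corpus is separated so cleanly that the optimal slope
diverges. The hard call is signal iff `g(p̂) > 0.5`, strictly: 0.5 exactly
is noise.

**Counting.** The count model is a Poisson-binomial sum over the calibrated
probabilities of the *tested* maxima (candidates removed by truncation were
never tested and do not enter n). The default interval is the percentile of
1000 Monte-Carlo replicates; with N sorted samples the bounds are
`sorted[floor(q_lo·N)]` and `sorted[min(ceil(q_hi·N), N−1)]` — a
nearest-rank rule that leans one sample outward and is always
integer-valued. The exact pmf by iterative convolution (O(n²), numerically
exact to ~1e-12) is attached whenever n ≤ 5000 and serves as the oracle for
the Monte-Carlo path. The interval deliberately excludes forest sampling
variance and calibration-curve uncertainty; it quantifies classification
ambiguity only.

## Synthetic data generator

A synthetic stack is
`GaussianBlur(background + PSF ∗ δ(sources), σ_blur) + N(0, σ_noise)`,
clipped at 0; uint16 quantization happens only on file write. Components:

- **PSF**: separable 3D Gaussian, default σ_xy = 1.3 px, σ_z = 1.8 planes —
  the standard approximation for a diffraction-limited widefield spot;
  no Born–Wolf model, no aberrations.
- **Background**: baseline 120 + linear illumination gradient (amplitude
  30, random in-plane direction) + 12 broad Gaussian blobs (amplitude 40,
  σ 24 px, axially squashed) mimicking autofluorescent bodies. This is a
  parameterized stand-in for empty-specimen acquisitions; it reproduces
  smooth structured background but not its real texture statistics.
- **Sources**: uniform random voxel positions under a minimum-separation
  constraint (rejection sampling, default 6 voxels), magnitudes
  Normal(mean, cv·mean) truncated positive, default mean 5000, cv 0.2.
  Sub-voxel positions are not modeled, so ground-truth matching is exact.
- **Post-blur** σ = 0.5 px, **noise** sd 4 counts, additive Gaussian
  (no Poisson shot noise, gain, or blinking/bleaching photophysics).

Defaults were chosen once so that the stack-level signal-intensity metric —
mean emitter-center brightness above the image mean in units of image
standard deviations — lands in the 4–8 band considered realistic for
widefield smFISH at the default 25×256×256 shape: the normalized PSF
spreads an emitter's magnitude so its peak is ≈2% of it, and the structured
background sets the image sd. Note the metric depends on field size (a
fixed blob count thins out in larger fields), so other shapes shift it.

Because the generator's noise is additive and its background smooth, the
synthetic benchmarks demonstrate that the pipeline separates Gaussian peaks
from structured-background maxima and that its intervals are honest *under
the stated model*; they do not establish performance on real textured
backgrounds, shot-noise-limited images, or dense clusters where emitters
are not resolvable (an intensity-regression regime this package does not
attempt).

A note on resolving touching spots: with two equal emitters whose maxima
are 3 voxels apart in-plane, two *discrete* maxima exist only while the
effective in-plane width (PSF ⊕ blur) stays near 1 px; at the default
σ ≈ 1.39 the midpoint voxel is brighter than either emitter voxel and the
pair merges before detection ever sees it. The resolvability test therefore
runs at σ_xy = 1.0, blur 0.3.

## Numerical and degenerate-input choices

- Ranking ties break lexicographically by (z, y, x); determinism everywhere
  is by explicit seeds (numpy `SeedSequence` spawning per-tree seeds).
- Flat patches: zero variance ⇒ ratio features defined as 0; a constant
  stack yields no candidates and a (0, [0, 0]) count report.
- `signal_intensity_metric` is undefined (error) for constant images or
  empty truth; `spot_density_metric` uses an exact Euclidean distance
  transform.
- AUROC is the tie-corrected rank statistic over *retained* candidates
  only: truth sources never proposed as candidates count as false negatives
  in detection matching but do not enter the ROC, which measures
  classification quality separately from detection coverage.
- Detection-to-truth matching is greedy nearest-first within a 2-voxel
  tolerance (≈ one PSF σ_xy), each side used at most once.
- Calibration corpora pool curators by default; `curator_id` is carried on
  every training row so per-curator corpora can be built.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the cross-background
protocol at reduced sizes chosen as the package's own benchmark scale:
25×256×256 stacks with 50 spots (acceptance; the areal spot density of
~200 spots in a 512×512 field) and 15×160×160 with 30–40 spots (test
suite). The degradation sweep uses four magnitude levels spanning
signal intensities ≈ 4.2 down to ≈ 0.7 over three backgrounds. Monotonicity
assertions allow one inversion beyond the statistic's Monte-Carlo
resolution (±1 count for interval widths at 1000 replicates, 0.005 AUROC).

## Known limitations

- The feature schema is a reasoned reconstruction of what a curator
  inspects, not a canonical list; it is versioned so models and extractors
  cannot silently disagree.
- The adaptive MSE cutoff assumes the dimmest decile of candidates is
  noise; on nearly-empty stacks with very few maxima that sample can
  include real spots, in which case setting `mse_cutoff` explicitly (or
  relying on the retention floor) is the remedy.
- Counts are per-stack; no attempt is made to segment cells/embryos or to
  handle transcriptional foci brighter than single molecules.
- The interval covers classification uncertainty, not detection misses:
  emitters that never became candidates (e.g. below the noise floor) are
  invisible to it.
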