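# Methods

## Decay model and forward kernel

A TCSPC acquisition at repetition period T (12.5 ns at 80 MHz) histograms
photon arrival times into `n_channels` uniform bins (default 256). The
emission model per pixel is the two-component exponential

I(t) = α₁·exp(−t/τ₁) + α₂·exp(−t/τ₂) + C,

with normalized fractions α₁ + α₂ = 1 (only α₁ is stored; the amplitude-
weighted mean lifetime τₘ = α₁τ₁ + α₂τ₂ presumes normalized weights). Under
periodic excitation the incomplete decay of earlier pulses wraps around, so
each component contributes exp(−t/τ)/(1 − exp(−T/τ)) on [0, T); for τ₂ ≈ 3 ns
the wrapped tail is ≈1.5% of the peak at the period end and ignoring it biases
fits. The detected expectation is the **circular** convolution of this wrapped
decay (sampled at channel centers, unit-sum) with the unit-sum IRF, scaled by
the expected signal photon count, plus C per channel. The same kernel
(`decay_model.model_curve`) is the simulator's expectation and the fitter's
forward model — a single source of truth, so round-trip tests are exact up to
noise.

The default IRF is a Gaussian of 0.3 ns FWHM centered at 1.0 ns sampled on the
same grid — a reasonable stand-in for a measured second-harmonic-generation
response; both parameters are configurable and measured IRFs can be supplied
as arrays.

## Per-pixel fitting

`fit_pixel` optimizes (α₁, τ₁, τ₂, amplitude, C) with `scipy.optimize.
least_squares` (trust-region reflective) within bounds α₁ ∈ [0, 1],
τ₁ ∈ [0.05, 1.5] ns, τ₂ ∈ [1.0, 8.0] ns, initialized at the free/bound
NAD(P)H anchors (0.7, 0.5 ns, 3.0 ns). Two objectives:

- **Poisson MLE (default):** signed square-root deviance residuals,
  r = sign(y−m)·√(2(m − y + y·ln(y/m))). Minimizing ‖r‖² minimizes the Poisson
  deviance; it is accurate down to low counts (measured: median fitted τₘ
  1.239 ns vs truth 1.25 ns at 5,000 photons over 256 channels).
- **Neyman least squares** (`objective="neyman"`): Σ(y−m)²/max(y,1), common in
  TCSPC software. Its fitted total is biased low by roughly one count per
  channel, which at a few thousand photons shifts τₘ by ~5%; it is retained
  for comparison but is not the default for exactly that reason.

The Neyman reduced chi-square (dof = n_channels − 5) is reported for either
objective as the familiar fit-quality diagnostic. Component ordering τ₁ < τ₂
is enforced by swapping after convergence (with α₁ ← 1−α₁); "free"/"bound"
naming per channel is interpretation, not math. The background C is a free
nonnegative parameter by default; with `fit_background=False` it is fixed to
the mean of the channels before the IRF rise — note those channels contain the
wrapped decay tail, so the pre-rise estimate overstates a true dark offset.
Known identifiability limit: for noise-free data the offset C and the wrapped
long-lifetime plateau are nearly collinear, so C is recovered only to ~10%
while the shape parameters recover to <0.2%.

`fit_image` first sums decays over a square neighborhood of radius
`spatial_bin` (default 1, i.e. 3×3, zero-padded at the border) and skips
pixels whose binned total is below `min_photons` (default 100), marking them
invalid (NaN maps). Identical binned histograms are fitted once and cached —
exact, and a large saving on synthetic fields where all pixels of a cell share
parameters.

## Phasor analysis

`phasor_of_histogram` implements the Riemann (channel-center) discretization
of the defining integrals; uniform channel widths cancel in the ratio. Closed
forms: a mono-exponential maps to g = 1/(1+(ωτ)²), s = ωτ/(1+(ωτ)²) on the
universal semicircle; a biexponential maps to the intensity-weighted convex
combination with fractions F_k = α_kτ_k/(α₁τ₁+α₂τ₂) — a point on the chord
between the component semicircle points. First harmonic only (ω = 2πf).

Calibration multiplies the complex phasor by z_true/z_ref of a reference
measured through the same system; the simulator's exactly-known IRF serves as
a zero-lifetime reference. One numerical subtlety: under the channel-center
Riemann transform, a zero-lifetime decay is a point mass in the first channel
with phasor (cos(ωh/2), sin(ωh/2)), h the channel width — not (1, 0).
Assigning the reference this *discrete* true phasor makes reference and data
share the discretization and cancels the half-channel phase bias to O(h²)
(~1e-4 at 256 channels); assigning (1, 0) instead leaves a rotation of
ωh/2 ≈ 0.012 rad. `zero_lifetime_reference` computes it; a reference
fluorophore of known lifetime can be passed through the same `calibrate`
operation for real data.

`phasor_image` applies the *same* spatial binning and photon threshold as the
fitter, so the two feature routes see identical pixel support — required for a
fair comparison. No background subtraction is applied before the transform by
default.

## Synthetic data generator

`simulate_field` emulates one two-channel (NAD(P)H, FAD) acquisition:
non-overlapping disk cells (rejection-sampled centers, uniform radius in a
configured range, bounded at 10,000 attempts), one (α₁, τ₁, τ₂) draw per cell
per channel from truncated normals, every pixel of a cell sharing that cell's
truth (features are pixel-averaged per cell, so per-pixel jitter would only
add variance the average removes), Poisson noise per pixel and channel, and a
constant dark rate outside cells (default 0.02 counts/channel). Default
brightness is 5,000 expected signal photons per in-cell pixel — a well-exposed
acquisition; real photon budgets vary widely and this is a choice, not a
measured value. Randomness: one master seed; per-field streams are spawned as
`SeedSequence([master, field_index])` so any field is reproducible in
isolation.

What the generator does **not** emulate: optical blur (cells have hard
edges), detector afterpulsing and dead time, spectral bleed-through,
intra-cell lifetime heterogeneity, and realistic cell morphology. Passing
tests therefore demonstrate correctness of the estimators and the comparison
machinery under the stated noise model, not robustness to instrument
artifacts.

Benchmark phenotype constructors:

- `matched_phasor_pair()` exploits the phasor's rank deficiency: given base
  NAD(P)H parameters (0.7, 0.5, 3.0), `solve_matched_decomposition` finds a
  second decomposition (≈0.759, 0.9, 3.74) whose chord passes through the same
  phasor point (root-finding on the chord cross product). The FAD channel is
  identical in both phenotypes. Decay-fit features separate the pair; phasor
  features are blind to it up to cloud-shape effects.
- `large_shift_pair()` moves both channels' decompositions by many per-cell
  standard deviations (per-cell SDs default to 0.02 / 0.03 / 0.06 ns for α₁ /
  τ₁ / τ₂), so both routes classify near-perfectly.
- `macrophage_like_phenotypes()` gives M0/M1/M2 analogs with qualitative
  shifts (lower free-NAD(P)H fraction in M1, shorter bound lifetime in M2,
  FAD shifts in M1) for demos and visualization.

## Cell features

`segment_cells` is a deliberately simple stand-in for a full segmentation
pipeline: Gaussian smoothing, global Otsu (or fixed) threshold, connected
components, area filter. Externally produced label masks (16-bit TIFF) take
precedence when present. `aggregate_features` computes, per cell, the
**unweighted** mean of each of the 12 per-pixel quantities over pixels valid
in the respective map (photon weighting is available but off by default);
per-cell τₘ is the mean of per-pixel τₘ, not τₘ of mean parameters — the two
differ. Cells with fewer than 10 valid pixels (configurable) are dropped to
avoid degenerate single-pixel entries.

## Statistics and classification

- Feature-wise group comparisons: two-sided Welch t-tests per group pair,
  significance at p < 0.05, unadjusted (each contrast reported on its own; a
  Holm adjustment can be applied downstream if desired). Degenerate groups
  (n < 2 or zero variance) raise with the group named.
- Classifiers: random forests (500 trees, √p feature subsampling, unlimited
  depth, seeded) under stratified 5-fold cross-validation — train on 80%,
  test on the held-out 20%; accuracy and ROC AUC per fold, gini importances
  averaged over folds, pooled ROC retained for plotting only. Stratification
  preserves class proportions because real per-group cell counts are
  imbalanced. Cells from one field may straddle folds by default (cell-level
  analysis); `group_by_field` blocks folds by source image for users who want
  conservative estimates, since within-field correlation inflates accuracy.
- Feature-set comparison: the three sets (decay8, phasor4, combined12) share
  one fold assignment per class pair, and are compared by **paired** fold-wise
  two-sided t-tests on accuracy or AUC — better defined than comparing
  unpaired fold means, and the reports refuse comparison when fold
  assignments differ. Identical per-fold values return (t=0, p=1); a constant
  nonzero difference returns p=0.
- UMAP embeddings (z-scored features, seeded) are for visualization only;
  nothing downstream consumes them.

## Problem sizes

Tests and the acceptance script run the full pipeline on 64×64-pixel fields
with 15 cells each, 2–3 fields per phenotype (≈60–90 cells per class), 256
time channels — small enough for a laptop core in minutes while keeping every
stage's statistics meaningful; all sizes scale up through the same interfaces
(256×256 fields are the natural full size).
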