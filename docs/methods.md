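# Methods

This note records the models, conventions and numerical choices behind
`specstack`, and what the synthetic phantom does and does not establish
about measured data.

## Data model

Scanning-probe nano-XANES produces a 4D measurement
(E_incident × Y × X × E_fluorescence). Upstream XRF peak fitting (out of
scope here) reduces it to one **energy stack** per element: a 3D grid
(E × Y × X) of integrated element-line intensities with its incident-energy
axis in keV. `EnergyStack` enforces strictly increasing energies, finite
values, and non-negativity for raw count stacks; edge-step-normalized
stacks (flagged `normalized`) may carry small negatives from baseline
subtraction, floored at −0.5 by default.

Flattening to the matrix V (E × P, P = Y·X) is row-major over (Y, X):
column j is pixel (j // X, j % X). All maps and loadings use this one
convention so factorization results are reproducible.

## XANES normalization

A spectrum is normalized as `(raw − pre_line) / edge_step`:

* **E0**: energy of the maximum of the 3-point-smoothed first derivative,
  overridable by a tabulated value (Fe K: 7.112 keV).
* **Pre-edge**: straight line fitted on [E0 − 1.0, E0 − 0.020] keV
  (intersected with the scan). The conservative −20 eV upper end matters
  for mixed-phase spectra: phase edges spread over several eV, and a
  window ending −8 eV below the steepest edge can swallow the jump of a
  lower-edge phase, producing runaway pre-line slopes.
* **Post-edge**: degree-1 polynomial (degree 0–2 supported) on
  [E0 + 0.015, E0 + 1.0] keV; edge step = post(E0) − pre(E0); a
  non-positive step raises "no edge detected".

Whole stacks are normalized with one shared parameter set fitted on the
stack mean spectrum — per-pixel refitting of noisy spectra is deliberately
avoided.

### Baseline consistency in fitting

Linear-combination fits are only as good as the consistency between the
data's and the references' baseline treatment: the references are mutually
correlated, so a percent-level baseline tilt redistributes coefficients by
several percentage points. `fit_spectrum` therefore re-levels every
reference before fitting: its pre-edge line is refit over the *same
absolute pre-edge window* used for the data and subtracted. Only the line
is removed — each reference keeps its unit edge step, so coefficient
ratios remain spectral fractions. On noiseless phantoms this makes the
mean-spectrum fit exact to better than 0.02 in every fraction.

## Linear-combination fitting (LCF)

`nnls_coeffs` solves min ‖d − Σ cᵢ rᵢ‖₂ s.t. cᵢ ≥ 0 with
`scipy.optimize.nnls` (convex; global optimum; cross-checked in the test
suite against exhaustive grid search). Fit statistics use the XAFS
conventions with unit per-point weights (no per-point uncertainties are
assumed; weights are injectable):

* r-factor = Σ(d−f)² / Σd²
* reduced χ² = Σ(d−f)² / (n_points − n_params)

**Per-pixel chemical maps** (`fit_pixelwise`) fit *raw* pixel spectra
against normalized references: the pixel's overall intensity scale is
absorbed into the coefficients and cancels in the fractions, which is far
more stable than normalizing individual noisy pixel spectra. Pixels whose
summed intensity falls below 2% (configurable) of the maximum pixel sum
are background: excluded from fitting, zero in all maps. Global spectral
fractions are each reference's share of the total fitted coefficient
weight; per-pixel r-factor maps flag locally poor fits.

**Combinatorial screening** (`combinatorial_fit`) fits every subset of the
library with sizes 1–5 by default (an 11-entry library gives
Σ C(11,s) = 1023 subsets) and ranks rows by reduced χ² ascending, ties
broken by fewer components, then by r-factor. Components with fraction
≤ 0.05 (configurable) are flagged "inspect" rather than removed — in
practice near-degenerate references enter top-ranked fits at the
few-percent level, and whether such a minority phase is real requires
looking at its spatial map. The suggested automatic candidate is the
highest-ranked row with no flags. Top-ranked rows routinely differ in
reduced χ² by far less than the noise level; treating the ranking as a
shortlist plus flags, not a verdict, is intentional.

`oxidation_state_fraction` is the two-reference special case (e.g.
Fe(III)/Fe(II) split over a restricted energy window); nearly collinear
references over the window are flagged `degenerate`.

## Decomposition

The stack matrix is modeled as V ≈ W H (W: E × k spectra, H: k × P
loadings). The component count is read off an SVD scree; explained
fractions use squared singular values (σᵢ²/Σσ²). Note that on uncentered
count data the first singular vector is essentially the mean spectrum and
dominates the variance, so the default 0.90 threshold is conservative —
pass an explicit k (as the interactive workflow would after inspecting the
scree) or raise the threshold.

**NMF** is the primary method because nonnegativity makes W columns
directly readable as XANES-like spectra. Plain NMF is rotation-ambiguous:
factorizations with mixed component spectra reconstruct V as well as the
pure ones. The solver is therefore seeded from k-means cluster means over
shape-normalized pixel spectra (a standard device in hyperspectral
unmixing that biases the solution toward spatially segregated components),
with deterministic SVD (`nndsvd`) and seeded-random restarts as
alternatives; a later candidate must reduce the Frobenius residual by more
than 0.1% to displace an earlier one. Coordinate-descent, tol 1e-4, max
2000 iterations; everything is deterministic given the seed. PCA, ICA,
factor analysis, truncated SVD and dictionary learning are available for
comparison; for the mean-centered family the leading component is
conventionally dropped from composites (it is the mean), but all
components are kept in the data structures.

Component spectra are edge-step normalized (components without an edge —
pure noise — are returned raw and flagged) and matched to the reference
library by Pearson correlation, which is invariant to the affine scale
ambiguity of factorization. Zero-variance spectra yield NaN (missing), not
zero correlation.

## Alignment

Frames are registered to a single reference frame (default: last = highest
signal, post-edge) by cross-correlation with subpixel refinement
(`phase_cross_correlation`, `normalization=None`; the spectral-whitening
variant fails on smooth band-limited fluorescence frames). Shifts are
reported as per-frame drifts; frames are resampled by the negative shift
with linear interpolation, out-of-field pixels zero-filled and excluded by
a validity mask so photometry never mixes real and padded counts.

Accuracy: on content-constant frames (the translation oracle) drifts up to
5 px are recovered to better than 1/upsample px. On a full multi-energy
stack, frame *content* changes with energy — each phase brightens across
its own edge — which biases registration by up to ~0.2 px regardless of
upsampling. This is a physical limit of intensity-based registration on
spectrally heterogeneous scenes, not an implementation artifact.

## Energy-point subsetting

`subset_energies` auto mode greedily selects the n energies maximizing the
minimum pairwise Euclidean distance between the library's reference
spectra restricted to the chosen energies — the points where candidate
phases are most distinguishable, emulating multi-energy-point acquisition
(~10 points instead of a full edge scan). Duplicate references are
collapsed before selection (a duplicate pair has zero distance everywhere
and would defeat the max-min criterion). On the standard phantom a
12-point subset reproduces the 73-point chemical fractions to well within
0.05.

## Noise injection

`add_gaussian_noise` adds zero-mean Gaussian noise with σ = scale × σ̂,
where σ̂ is the stack's baseline noise: per pixel, the SD of the residual
after a 3-point moving average along energy; aggregated as the median over
signal-bearing pixels (above 2% of the maximum pixel sum — empty
background pixels would drag the median toward zero). "scale 3×/10×" means
multiples of this estimate. Negatives are clipped for raw stacks;
everything is seeded.

## The phantom generator

The phantom emulates a mixed-mineral nanoparticle aggregate measured
across the Fe K edge:

* **Grid**: 73 energies, 7.08–7.20 keV; 160 × 160 raster by default.
* **Standards**: arctan edge (position jittered ±4 eV around 7.112 keV, a
  proxy for oxidation-state edge shifts) plus 1–2 Gaussian white lines;
  each draw is passed through the package's own normalization so
  references and simulated data share one baseline convention; rejection
  sampling enforces pairwise Pearson r < 0.995.
* **Geometry**: `tiles` (pure rectangles), `blobs` (disjoint ellipses), or
  `aggregate` — elliptical particles grown greedily until the occupied
  area's phase shares match the target fractions within 0.01;
  `mixing_fraction` smooths boundaries into mixed pixels.
* **Forward model**: signal = counts_scale · Σ fraction · μ_phase, clipped
  at zero, plus a 2% mass-proportional energy-independent pedestal
  (scatter/background; it keeps pre-edge frames registrable, as in
  measured stacks, and biases fraction recovery by ≤ 0.006), optional
  per-energy drift (bounded random walk), optional Poisson sampling. Same
  seed ⇒ bit-identical phantom.
* **Model preset**: 4 phases at global spectral fractions
  0.50 / 0.20 / 0.12 / 0.18, counts_scale 1e4 (edge-jump counts per pure
  pixel).

What the phantom does *not* emulate: detector response and pile-up,
self-absorption, energy-dependent backgrounds, non-rigid distortions,
spatially varying noise beyond Poisson, and real mineral spectra
(tabulated standards would add EXAFS-like structure the arctan+Gaussian
family lacks). Passing tests therefore demonstrate the correctness and
stability of the reduction and fitting machinery under controlled
conditions, not end-to-end accuracy on beamline data.

## Problem sizes and determinism

The test suite and the worked example run the standard conditions (73
energies, 4 phases, 1e4 counts, 0.50/0.20/0.12/0.18 fractions) on 48×48
and 64×64 rasters; parameter-recovery statistics aggregate 20 seeded
phantoms. Raster size only multiplies the number of per-pixel fits, so
these sizes exercise the same estimator behavior as the full 160×160
default, which any example can request explicitly. Every stochastic step
(phantom draw, noise, factorization restarts, k-means) takes an explicit
seed; pipeline runs echo their full configuration and a config hash into
the output directory and are numerically identical on rerun.

## Known limitations

* Per-pixel LCF assumes the pixel spectrum is a nonnegative combination of
  the supplied references plus an intensity scale; missing phases
  masquerade as mixtures of present ones.
* The combinatorial ranking is a shortlist: reduced-χ² gaps between top
  rows are typically far below noise, and the flagged-component heuristic
  (≤5%) can retain a borderline decoy at 5–6%.
* Registration accuracy on spectrally heterogeneous scenes is limited to
  ~0.2 px by content change across energies (see Alignment).
* Scree-based component counting on uncentered data underestimates k at
  moderate thresholds (see Decomposition).
* No self-absorption correction; thick-sample stacks will be biased.
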