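# Methods

## Peak-width model

Mass resolving power varies with *m/z*; for FTICR instruments the peak width
grows quadratically (undamped transient: Δm = 7.589 m² / (q B T_FID); damped:
Δm = 2√3 m² / (q B τ); linear TOF: m/Δm = t / (2Δt)). These closed forms are
provided for qualitative comparison only and are deliberately kept out of the
weighting pipeline, because their constants are instrument- and
unit-convention dependent. The operational model is empirical: FWHM values of
isolated peaks (apex SNR ≥ 3, noise level 1.4826 × MAD of the intensity
trace, half-max crossings located by linear interpolation on each flank) are
extracted from one full-profile spectrum and smoothed by LOESS. The LOESS is
a tricube-weighted local polynomial regression, degree 2, span 0.5 (both
configurable); queries outside the trained range clamp to the boundary value
with a warning rather than extrapolating local polynomials. Gaussian peak
shape links width and envelope scale: FWHM = 2√(2 ln 2) σ_G ≈ 2.3548 σ_G.

## Mass-window weighting

For an MOI at m_MOI, every observed peak inside m_MOI ± 3σ_G receives the
weight exp(−(m_j − m_MOI)²/(2σ_G²)) — the envelope scaled to 1 at its centre,
not a unit-area density — and the weighted intensities are summed per pixel.
Uniform weighting (w_j = 1 over the same support) is retained for
comparison. Peak binning uses iterative bisection of the pooled sorted mass
vector at the largest adjacent gap (ties: lowest-mass occurrence, for
determinism) until every bin satisfies |peak − μ_bin|/μ_bin < tolerance; the
conventional tolerance is FWHM at a reference mass divided by that mass
(0.0048 Da at m/z 400 → 12 ppm). Intensities of several member peaks of one
bin within the same pixel are summed, consistent with the weighting step.
The occurrence filter drops peaks present in fewer than 1% of pixels before
binning.

## Spatial point pattern and null model

The tissue window Φ_tissue is the union of all measured unit pixel squares;
its area is the pixel count. Pixels with positive weighted intensity become
marked points at their grid coordinates (0-based, x = column, y = row,
y down). The CSR control places exactly n points uniformly at random in
Φ_tissue (pixel chosen uniformly, then a uniform offset within the square)
and assigns a random permutation of the observed marks. Fixing the count at
n rather than drawing Poisson(ΛA) keeps the mark permutation one-to-one.
The permutation is drawn from a canonically sorted copy of the marks so that
the null realization depends only on the mark multiset and the seed, which
makes ensemble projections invariant to member order.

## Density estimation

The weighted KDE is an isotropic Gaussian ρ(x, y) ∝ Σ_i mark_i K_h / e(x, y)
evaluated at pixel centres inside the tissue, with uniform edge correction
e(x, y) = kernel mass inside Φ_tissue, then sum-normalized to 1. It is
computed by FFT convolution with a kernel spanning the full grid, so for
grid-aligned points it equals the brute-force double sum to ~1e−12.
Off-grid points (CSR realizations, simulations) are spread bilinearly onto
the four surrounding pixel centres before convolution — a sub-pixel
approximation that slightly smooths each point and is negligible at h ≥ 1.
Tiny negative values from FFT round-off are clipped to 0 before
normalization.

Edge correction makes the null mean spatially flat, but the variance of the
corrected field is inherently larger near the window border (fewer points
fall inside a truncated kernel). The pooled normal null below ignores this
heterogeneity; its consequence is quantified under Limitations.

## Hotspot/coldspot inference

μ_CSR and σ_CSR are the mean and sample standard deviation of the CSR
density over tissue pixels, taken from a single CSR realization (its seed is
recorded in the result). Each ρ_MOI pixel receives
P_upr = 1 − Φ((ρ − μ_CSR)/σ_CSR) and P_lwr = Φ(·); Benjamini–Hochberg
correction is applied separately within each tail over tissue pixels only.
Hotspots are {P*_upr ≤ α}, coldspots {P*_lwr ≤ α}, α = 0.05 by default;
boundaries are traced by marching squares at level 0.5 on a zero-padded
copy of each 8-connected mask (holes preserved, contours unsmoothed). The
original marks pass through unmodified; smoothing exists only inside the
inference.

## Bandwidth selection

Moran's I (first-order Queen's-case adjacency, unit weights, 8-neighbour
pairs both inside tissue) is computed on the KDE image for h = 1–10 px in
0.5 steps. The knee of the concave increasing I(h) curve is found by the
Kneedle construction: min-max normalize both axes, form the difference curve
d = y_n − x_n, take the x at its maximum, and require the curve to fall
below the sensitivity-1 threshold afterwards. A curve without curvature
(e.g. linear) yields no knee; the fallback is the largest bandwidth whose
Moran's I increment still exceeds 1% of the curve's range, with a warning.
Moran's I is scale-invariant, so whether the normalized or unnormalized
density is scanned is immaterial.

On the simulated patterns the knee lands at 2.5–3.0 px while the
ground-truth-recovery DSC, as a function of h, peaks at 3.0–4.0 px; the DSC
at the knee stays within ~10% of the curve's maximum. "Knee-optimality" is
therefore asserted as adjacency (median |h_peak − h_knee| ≤ 1 px over
simulations) and near-optimality (DSC(knee) ≥ 0.9 × max), not as exact
coincidence.

## Ensembles and cross-tissue comparison

For a collective projection, members with duplicate observed m/z contribute
once (first in input order), degenerate members (n < 2 or constant marks)
are skipped with a warning, and each retained member is z-standardized
(sample sd). Points are concatenated; co-located points co-exist without
summation (rasterization, where unavoidable, sums co-located marks and says
so). Because standardized marks can be negative and the weighted KDE needs
nonnegative masses, the projected marks are shifted by their global minimum
plus 1e−6 before density estimation; the shift offsets the observed and CSR
densities identically.

Cross-tissue maps combine the spatial MPM of the test tissue with an
intensity test: each test mark x receives eCDF tail p-values against the
reference marks using the add-one estimator p_upr = (1 + #{r ≥ x})/(n_ref+1)
(never exactly 0; reference floor 20 marks), BH-corrected over test points
per tail. Combined hotspots are spatial hotspot pixels whose point is
upper-tail significant; coldspots analogously. Comparability of intensity
scales between tissues is the caller's responsibility (same-slide
acquisition or robust normalization); a warning restates this.

## Synthetic study conditions

Four ground-truth geometries in a 100 × 100-unit window: central circle
(r = 20), five circles (r = 10, centre + 4 on the diagonals at distance 30),
ring (outer/inner radii 30/20), and a dominant circle with four satellites
(r = 20 and 5, area ratio 16). Points follow homogeneous Poisson processes
with densities 0.4 (inside the geometry) and 0.3 (background) points per
unit area. Marks default to lognormals with σ_log = 0.5 and a high/background
mean ratio of 2.3 — a stand-in chosen to preserve the positivity, right skew
and contrast of real per-pixel ion intensities; any sampler can be
substituted. The analytic Poisson means (e.g. 0.4·π(30²−20²) ≈ 628 expected
ring points) are the reference for count assertions.

Noise injectors: (1) additive Gaussian mark noise Normal(μ_MOI, σ_k²) with
σ_k = k·σ_MOI (k ≥ 1) and σ_0 = √μ_MOI (Poisson-like), results clipped at 0
(the clipped fraction grows with k; clipping is documented rather than
resampled); (2) an interference peak column at m_MOI + 2σ_G in every pixel,
intensities Normal(μ_MOI, σ_MOI²) clipped at 0; (3) single-pixel intensity
artifacts, Uniform(max_MOI, 10·max_MOI) added to n distinct random pixels
(pixels without a point gain one). All generators are deterministic given a
seed.

The cross-tissue case simulators share these densities: case 1 has the
central-circle structure with region marks Normal(230, 15²) against
background/reference marks Normal(100, 15²) (the 2.3 contrast of the main
generator); case 2 is structureless with all test marks shifted; case 3 has
structure but reference-identical marks everywhere.

## What the simulations do and do not show

The generator emulates the spatial statistics of an MSI experiment — Poisson
point placement, skewed positive marks, density and intensity contrast in a
known geometry — but not its spectral dimension (one m/z channel; per-pixel
normalization is meaningless here), nor instrument drift, batch effects or
spatially correlated background. Passing tests therefore validate the
statistical machinery (null calibration, bandwidth selection, mask
stability, ensemble and cross-tissue logic), not performance on any
particular instrument or tissue type.

Two robustness analyses deserve explicit caveats:

- **Extreme-outlier artifacts.** Uniform(max, 10·max) artifact marks are
  ~35× the mean mark of this generator. Once permuted into the CSR null they
  dominate σ_CSR, and with the clean map operating at pixel z-scores of only
  ~4–7 the inference collapses (clean-vs-contaminated hotspot DSC ≈ 0.01–0.1
  at 2% artifact pixels; similar at 0.1%). Robustness to such artifacts on
  real tissue data rests on much larger clean effect sizes (dense signals
  over tens of thousands of pixels) and on per-pixel spectrum normalization
  bounding single-peak outliers — neither of which a single-channel
  simulation possesses.
- **Strong Gaussian noise (k = 4).** Mark noise with sd ≈ 2.7× the mean mark
  reduces the clean-vs-noisy hotspot DSC to ~0.3 under the selected
  bandwidth (~0.55 at the best fixed bandwidth). Milder contamination —
  interference at 2σ_G, k = 1 noise — reproduces the expected robustness.

Both are reported honestly by `scripts/acceptance.py`; they reflect the
study conditions, not tunable implementation choices.

## Numerical choices and degenerate inputs

- Gaussian weights use the exact envelope; support cut at exactly ±3σ_G
  (closed interval).
- LOESS guards against rank deficiency at the edges by reducing the local
  degree; fitted FWHM values are floored at a tiny positive value.
- Binning tie-break: first (lowest-mass) occurrence of the maximal gap.
- TIC/RMS normalization leaves all-zero pixel rows unchanged with a warning.
- Empty SPPs are valid outputs of the weighting step (with a warning) but
  invalid inputs to CSR generation and KDE.
- Zero-variance CSR densities, constant Moran's I images, and constant-mark
  standardization all raise rather than return NaNs.
- Dice of two empty masks is defined as 1 (identical emptiness).
- BH families: tissue pixels per tail (maps); test points per tail (CT-MPM).

## Known limitations

- The pooled normal null ignores the border-variance inflation of
  edge-corrected KDE; under a global null, spurious (BH-familywise ~α, but
  border-concentrated) rejections occur in roughly a quarter of
  realizations, typically as a small blob at the window edge. The
  three-case cross-tissue validation is therefore asserted as a majority
  outcome over replicates, not a single run.
- The Moran's I curve saturates quickly because KDE itself induces
  autocorrelation; the knee is consequently insensitive to added pixel
  noise and cannot adapt the bandwidth upward to suppress heavy
  contamination.
- Multiple acquisition regions in one imzML are not separated automatically;
  use a region mask upstream.
- Expression evaluation propagates no uncertainty; division warns.
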