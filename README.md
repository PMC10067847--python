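# spotmap

Probabilistic spatial mapping of metabolites in mass spectrometry imaging
(MSI) data.

MALDI-MSI measures a full mass spectrum at every pixel of a tissue section.
The conventional readout — the ion image of a metabolite of interest (MOI) —
depends on a user-chosen mass window and says nothing about whether an
apparent accumulation is statistically distinguishable from noise. `spotmap`
addresses both problems:

1. **Data-dependent Gaussian mass-window weighting.** The peak width
   (FWHM) of the instrument is measured as a function of *m/z* from a single
   full-profile spectrum and smoothed by LOESS. For an MOI at theoretical
   mass *m*<sub>MOI</sub>, a Gaussian envelope with
   σ<sub>G</sub> = FWHM(*m*<sub>MOI</sub>) / (2√(2 ln 2)) is erected and every
   observed peak within *m*<sub>MOI</sub> ± 3σ<sub>G</sub> contributes
   Σ<sub>j</sub> w<sub>j</sub> i<sub>j</sub>, with w<sub>j</sub> the envelope
   weight. Proximal interferences are down-weighted instead of summed in.

2. **Molecular probabilistic maps (MPM).** The weighted intensities form a
   *marked spatial point pattern* (SPP) inside the tissue window
   Φ<sub>tissue</sub>. The spatial null model is complete spatial randomness
   (CSR): the same number of points placed uniformly at random, carrying a
   random permutation of the observed marks. Intensity-weighted Gaussian
   KDE produces sum-normalized densities ρ<sub>MOI</sub>(x, y) and
   ρ<sub>CSR</sub>(x, y); the CSR pixel-value distribution is approximately
   normal with moments (μ<sub>CSR</sub>, σ<sub>CSR</sub>), against which each
   pixel receives lower/upper-tail p-values. After Benjamini–Hochberg
   correction per tail, pixels with P*<sub>upr</sub> ≤ α form **hotspots**
   (significant relative spatial abundance) and P*<sub>lwr</sub> ≤ α
   **coldspots**, reported as closed contour polygons. The KDE bandwidth is
   chosen at the knee (Kneedle) of the global Moran's I vs bandwidth curve,
   scanned over 1–10 px in 0.5 steps.

On top of the single-MOI map the package provides **collective projections
(CPPM)** — many z-standardized MOIs projected onto one tissue plane and
tested jointly — **cross-tissue maps (CT-MPM)** — the conjunction of the
spatial test in a test tissue with a nonparametric eCDF test of its
intensities against a reference tissue — and **spatial arithmetic** over ion
images (e.g. the adenylate energy charge
(ATP + 0.5·ADP)/(ATP + ADP + AMP) evaluated pixel-by-pixel).

A first-class synthetic-data module generates the ground-truth hotspot
geometries (central circle, five circles, ring, circle-plus-four satellites;
Poisson densities 0.4/0.3 points per unit area; mark contrast ≈ 2.3), the
three contamination types used for robustness analysis (additive Gaussian
noise, single-pixel intensity artifacts, interference peaks at
+2σ<sub>G</sub>), and the Dice similarity coefficient (DSC) for mask
evaluation — so the whole pipeline is testable without any instrument data.

## Worked example

```python
import numpy as np
from spotmap import GroundTruthPattern, simulate_pattern, compute_mpm, dice

truth = GroundTruthPattern("ring")            # annulus, outer/inner radii 30/20
sim = simulate_pattern(truth, seed=7)
spp = sim.spp
print(f"simulated points: n = {spp.n}, density = {spp.lambda_density:.3f} / unit^2")

result = compute_mpm(spp, alpha=0.05, h="auto", seed=7)
print(f"selected bandwidth (Moran's I knee): h = {result.bandwidth} px")
print(f"CSR null moments: mu = {result.pvals.mu_csr:.3e}, sigma = {result.pvals.sigma_csr:.3e}")
print(f"hotspot fraction of tissue: {result.hotspot_fraction():.3f}")
print(f"hotspot DSC vs ground truth: {dice(result.hotspot_mask, truth.truth_mask):.3f}")
```

prints

```
simulated points: n = 3209, density = 0.321 / unit^2
selected bandwidth (Moran's I knee): h = 2.5 px
CSR null moments: mu = 1.000e-04, sigma = 2.436e-05
hotspot fraction of tissue: 0.125
hotspot DSC vs ground truth: 0.816
```

The simulated annulus covers 15.7% of the window; the MPM declares 12.5% of
pixels significantly abundant, and the hotspot mask overlaps the true
annulus with a Dice coefficient of 0.82 — the ring is recovered, not just
the bright pixels.

## Command line

The `spotmap` console script wraps the library:

```sh
spotmap simulate --pattern ring --seed 1 --out sim/          # fixture imzML + truth mask
spotmap fwhm --profile-csv profile.csv --out curve.json      # FWHM(m/z) curve
spotmap mpm --imzml data.imzML --profile-csv profile.csv \
            --mz 544.3009 --normalize TIC --out out/          # single-MOI map
spotmap cppm --imzml data.imzML --profile-csv profile.csv \
             --annotations metaspace.csv --fdr-max 0.2 --out out/
spotmap ctmpm --imzml test.imzML --ref-imzml ref.imzML \
              --profile-csv profile.csv --mz 544.3009 --out out/
spotmap expr --imzml data.imzML --profile-csv profile.csv \
             --expression '(atp + 0.5*adp)/(atp + adp + amp)' \
             --operand atp=505.9885 --operand adp=426.0221 \
             --operand amp=346.0558 --out out/
spotmap evaluate --mask-a a.npy --mask-b b.npy               # Dice coefficient
```

Every run writes a manifest (seed, bandwidth, α, null moments) sufficient to
reproduce it; maps are exported as rasters, GeoJSON contour polygons and a
rendered PNG (hotspots red/white, coldspots blue/white).

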