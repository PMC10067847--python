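"""Occurrence filtering, iterative-bisecting peak binning and normalization.

Centroided peak positions jitter from pixel to pixel; binning groups the
pooled mass vector by recursive bisection at the largest adjacent gap until
every bin satisfies |peak - mean| / mean < tolerance.  The tolerance is a
relative deviation (Delta-m / m), conventionally derived from the measured
FWHM at a reference m/z (0.0048 Da at m/z 400 gives 12 ppm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .io import PeakMatrix

__all__ = [
    "BinMap",
    "NormalizationSpec",
    "filter_rare_peaks",
    "bin_peaks",
    "bin_peak_matrix",
    "normalize",
    "tolerance_from_fwhm",
]


@dataclass
class BinMap:
    """Result of iterative-bisecting peak binning.

    ``assignment[i]`` gives the bin index of the i-th input mass (input
    order); ``bin_centers[j]`` is the mean mass of bin j's members.
    """

    bin_centers: np.ndarray
    assignment: np.ndarray
    tolerance: float

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, float)
        self.assignment = np.asarray(self.assignment, int)

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size

    def member_counts(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_bins)

    def to_csv(self, path) -> None:
        """Two-column audit export: bin_center, member_count."""
        counts = self.member_counts()
        with open(path, "w") as fh:
            fh.write("bin_center,member_count\n")
            for c, n in zip(self.bin_centers, counts):
                fh.write(f"{c!r},{n}\n")


@dataclass
class NormalizationSpec:
    method: str = "none"

    def __post_init__(self):
        if self.method not in ("none", "TIC", "RMS"):
            raise ValueError(f"unknown normalization method '{self.method}'")


def filter_rare_peaks(pm: PeakMatrix, min_pixel_frac: float = 0.01) -> PeakMatrix:
    """Drop m/z columns present in less than ``min_pixel_frac`` of pixels.

    A column is kept when its nonzero fraction is >= the threshold
    (strictly-less-than removal); the default removes peaks occurring in
    less than 1% of pixels.
    """
    if pm.n_pixels == 0 or pm.mz_axis.size == 0:
        return pm
    nnz = np.asarray((pm.values != 0).sum(axis=0)).ravel()
    # all-zero columns are dropped even at threshold 0
    keep = (nnz > 0) & (nnz / pm.n_pixels >= min_pixel_frac)
    return PeakMatrix(
        pm.coords,
        pm.mz_axis[keep],
        pm.values[:, np.flatnonzero(keep)],
        pixel_size_um=pm.pixel_size_um,
        polarity=pm.polarity,
    )


def bin_peaks(masses, tolerance: float) -> BinMap:
    """Group a sorted mass vector by iterative bisection at the largest gap.

    The pooled vector is recursively split at the largest adjacent
    difference (ties broken at the lowest-mass occurrence) until every bin
    satisfies |peak - mu| / mu < tolerance, where mu is the bin's mean mass.
    """
    masses = np.asarray(masses, float)
    if masses.size == 0:
        return BinMap(np.empty(0), np.empty(0, int), tolerance)
    if np.any(np.diff(masses) < 0):
        raise ValueError("masses must be sorted ascending")
    assignment = np.empty(masses.size, int)
    centers = []
    stack = [(0, masses.size)]  # half-open segments
    segments = []
    while stack:
        lo, hi = stack.pop()
        seg = masses[lo:hi]
        mu = seg.mean()
        if hi - lo == 1 or np.all(np.abs(seg - mu) / mu < tolerance):
            segments.append((lo, hi, mu))
            continue
        gaps = np.diff(seg)
        split = int(np.argmax(gaps)) + 1  # first occurrence of the max gap
        stack.append((lo + split, hi))
        stack.append((lo, lo + split))
    segments.sort()
    for j, (lo, hi, mu) in enumerate(segments):
        assignment[lo:hi] = j
        centers.append(mu)
    return BinMap(np.asarray(centers), assignment, tolerance)


def bin_peak_matrix(pm: PeakMatrix, tolerance: float) -> PeakMatrix:
    """Re-bin a peak matrix's m/z axis; member columns are summed per pixel."""
    bm = bin_peaks(pm.mz_axis, tolerance)
    if bm.n_bins == pm.mz_axis.size:
        return pm
    proj = sparse.coo_matrix(
        (np.ones(pm.mz_axis.size), (np.arange(pm.mz_axis.size), bm.assignment)),
        shape=(pm.mz_axis.size, bm.n_bins),
    )
    return PeakMatrix(
        pm.coords,
        bm.bin_centers,
        (pm.values @ proj).tocsr(),
        pixel_size_um=pm.pixel_size_um,
        polarity=pm.polarity,
    )


def normalize(pm: PeakMatrix, spec: NormalizationSpec | str = "none") -> PeakMatrix:
    """Per-pixel intensity normalization: none, TIC or RMS.

    TIC divides each pixel row by its intensity sum; RMS by the root mean
    square of the row's intensities over all m/z bins.  All-zero rows are
    left unchanged (with a warning).
    """
    if isinstance(spec, str):
        spec = NormalizationSpec(spec)
    if spec.method == "none":
        return pm
    rows = pm.values.tocsr().astype(float)
    if spec.method == "TIC":
        denom = np.asarray(rows.sum(axis=1)).ravel()
    else:  # RMS
        sq = rows.copy()
        sq.data = sq.data**2
        denom = np.sqrt(np.asarray(sq.sum(axis=1)).ravel() / max(pm.mz_axis.size, 1))
    zero = denom == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} all-zero pixel rows left unnormalized", stacklevel=2)
        denom = np.where(zero, 1.0, denom)
    scale = sparse.diags(1.0 / denom)
    return PeakMatrix(
        pm.coords,
        pm.mz_axis,
        (scale @ rows).tocsr(),
        pixel_size_um=pm.pixel_size_um,
        polarity=pm.polarity,
    )


def tolerance_from_fwhm(fwhm_at_m: float, m: float) -> float:
    """Relative binning tolerance Delta-m / m from the FWHM at a reference mass."""
    if fwhm_at_m <= 0 or m <= 0:
        raise ValueError("FWHM and m must be positive")
    return fwhm_at_m / m
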