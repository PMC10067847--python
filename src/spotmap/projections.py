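"""Ensemble projections (CPPM) and cross-tissue comparisons (CT-MPM).

A collective-projection probabilistic map treats a whole set of metabolites
as one pattern: each member SPP is z-score standardized (so high- and
low-intensity species contribute on the same scale), duplicated m/z entries
are dropped, and all points are projected onto the same tissue plane.
Co-located points from different members coexist without summation.  The
projected pattern then runs through the ordinary MPM pipeline.

A cross-tissue MPM combines two tests: the spatial CSR test in the test
tissue, and a nonparametric intensity test of every test-tissue mark against
the empirical CDF of the reference tissue's marks.  Only locations rejecting
both nulls are reported as significant cross-tissue abundance/deficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .mpm import MPMResult, compute_mpm
from .spp import SpatialPointPattern

__all__ = [
    "EnsembleProjection",
    "CrossTissueResult",
    "zscore_standardize",
    "collective_project",
    "compute_cppm",
    "ecdf_tail_pvalues",
    "compute_ctmpm",
]


@dataclass
class EnsembleProjection:
    """Z-standardized union of member SPPs on one tissue plane."""

    members: list  # retained (mz, standardized SPP) pairs
    projected: SpatialPointPattern
    dropped_duplicates: int = 0
    skipped: list = field(default_factory=list)
    standardized: bool = True


@dataclass
class CrossTissueResult:
    mpm: MPMResult
    combined_hotspot_mask: np.ndarray
    combined_coldspot_mask: np.ndarray
    point_p_upr_adj: np.ndarray
    point_p_lwr_adj: np.ndarray
    alpha: float

    @property
    def spatial_hotspot_mask(self) -> np.ndarray:
        return self.mpm.hotspot_mask

    @property
    def spatial_coldspot_mask(self) -> np.ndarray:
        return self.mpm.coldspot_mask


def zscore_standardize(spp: SpatialPointPattern) -> SpatialPointPattern:
    """Marks transformed to zero mean and unit sample standard deviation."""
    if spp.n < 2:
        raise ValueError("need at least 2 points to standardize")
    sd = spp.marks.std(ddof=1)
    if sd == 0:
        raise ValueError("zero mark variance; cannot standardize")
    z = (spp.marks - spp.marks.mean()) / sd
    return spp.with_marks(z, check_marks=False)


def collective_project(members) -> EnsembleProjection:
    """Project member SPPs of an ensemble onto one tissue plane.

    ``members`` is a sequence of ``(mz, spp)`` pairs.  Members sharing an
    identical observed m/z contribute once (first in input order kept);
    degenerate members (fewer than 2 points or constant marks) are skipped
    with a warning.  Retained members are z-standardized and their points
    concatenated; co-located points are kept distinct.
    """
    members = list(members)
    if not members:
        raise ValueError("empty ensemble")
    ref_window = members[0][1].window
    seen = set()
    retained, skipped = [], []
    dropped = 0
    for mz, spp in members:
        if spp.window.shape != ref_window.shape or not np.array_equal(spp.window, ref_window):
            raise ValueError("ensemble member windows differ")
        if mz in seen:
            dropped += 1
            continue
        seen.add(mz)
        try:
            retained.append((mz, zscore_standardize(spp)))
        except ValueError as exc:
            skipped.append(mz)
            warnings.warn(f"ensemble member m/z {mz} skipped: {exc}", stacklevel=2)
    if not retained:
        raise ValueError("no usable ensemble members after deduplication/skipping")
    x = np.concatenate([s.x for _, s in retained])
    y = np.concatenate([s.y for _, s in retained])
    marks = np.concatenate([s.marks for _, s in retained])
    projected = SpatialPointPattern(x, y, marks, ref_window, check_marks=False)
    return EnsembleProjection(
        members=retained,
        projected=projected,
        dropped_duplicates=dropped,
        skipped=skipped,
    )


def compute_cppm(
    proj: EnsembleProjection, alpha: float = 0.05, seed=None, h="auto"
) -> MPMResult:
    """MPM of the collective projection.

    Standardized marks can be negative, whereas the weighted KDE needs
    nonnegative masses; marks are therefore shifted by the global minimum
    plus a small epsilon before density estimation (the shift only offsets
    both the observed and CSR densities and is recorded on the result's SPP).
    """
    spp = proj.projected
    if spp.n == 0:
        raise ValueError("empty projection")
    shift = 0.0
    marks = spp.marks
    if marks.min() <= 0:
        shift = -float(marks.min()) + 1e-6
        spp = spp.with_marks(marks + shift, check_marks=True)
    return compute_mpm(spp, alpha=alpha, h=h, seed=seed)


def ecdf_tail_pvalues(test_marks, ref_marks, min_ref: int = 20):
    """Tail p-values of test marks against the reference empirical CDF.

    Uses the add-one estimator so p is never 0:
    p_upr(x) = (1 + #{r >= x}) / (n_ref + 1), and symmetrically for the
    lower tail.  Returns ``(p_lwr, p_upr)`` raw arrays.
    """
    test = np.asarray(test_marks, float)
    ref = np.sort(np.asarray(ref_marks, float))
    if ref.size == 0:
        raise ValueError("empty reference mark set")
    if ref.size < min_ref:
        raise ValueError(f"reference needs at least {min_ref} marks (got {ref.size})")
    n = ref.size
    n_le = np.searchsorted(ref, test, side="right")  # #{r <= x}
    n_ge = n - np.searchsorted(ref, test, side="left")  # #{r >= x}
    p_lwr = (1.0 + n_le) / (n + 1.0)
    p_upr = (1.0 + n_ge) / (n + 1.0)
    return p_lwr, p_upr


def compute_ctmpm(
    test_spp: SpatialPointPattern,
    ref_spp: SpatialPointPattern,
    alpha: float = 0.05,
    seed=None,
    h="auto",
    min_ref: int = 20,
) -> CrossTissueResult:
    """Cross-tissue probabilistic map.

    The spatial hotspot/coldspot masks come from the test tissue's MPM; every
    test point's mark is additionally scored against the reference tissue's
    mark eCDF (BH-corrected over test points, per tail).  Combined hotspots
    are spatial hotspot pixels whose point is intensity-significant in the
    upper tail; coldspots analogously in the lower tail.  Intensities must be
    comparable across the two tissues (same slide / robust normalization).
    """
    warnings.warn(
        "cross-tissue comparison assumes comparable intensity scales between "
        "test and reference tissues (same-slide measurement or robust "
        "normalization)",
        stacklevel=2,
    )
    mpm = compute_mpm(test_spp, alpha=alpha, h=h, seed=seed)
    p_lwr, p_upr = ecdf_tail_pvalues(test_spp.marks, ref_spp.marks, min_ref=min_ref)
    p_lwr_adj = multipletests(p_lwr, method="fdr_bh")[1]
    p_upr_adj = multipletests(p_upr, method="fdr_bh")[1]
    ix = np.rint(test_spp.x).astype(int)
    iy = np.rint(test_spp.y).astype(int)
    sig_up = np.zeros(test_spp.window.shape, bool)
    sig_up[iy[p_upr_adj <= alpha], ix[p_upr_adj <= alpha]] = True
    sig_lo = np.zeros(test_spp.window.shape, bool)
    sig_lo[iy[p_lwr_adj <= alpha], ix[p_lwr_adj <= alpha]] = True
    return CrossTissueResult(
        mpm=mpm,
        combined_hotspot_mask=mpm.hotspot_mask & sig_up,
        combined_coldspot_mask=mpm.coldspot_mask & sig_lo,
        point_p_upr_adj=p_upr_adj,
        point_p_lwr_adj=p_lwr_adj,
        alpha=alpha,
    )
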