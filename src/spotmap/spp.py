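"""Gaussian mass-window weighting and the marked spatial point pattern (SPP).

For a metabolite of interest (MOI) at theoretical m/z ``m_moi``, a Gaussian
envelope is erected whose standard deviation sigma_G follows from the
measured FWHM at that m/z (FWHM = 2 sqrt(2 ln 2) sigma_G).  All observed
peaks within the window m_moi +/- 3 sigma_G are weighted by the envelope
(scaled to 1 at the centre) and summed into one intensity per pixel, which
becomes the mark of a spatial point.  The set of marked points inside the
tissue window is the SPP, the central object of the statistical machinery.

Coordinates are 0-based with x = column and y = row (y grows downward); the
pixel with index (x, y) covers the unit square centred on (x, y).
"""

from __future__ import annotations

import ast as _ast
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fwhm import FWHMCurve, sigma_from_fwhm
from .io import PeakMatrix

__all__ = [
    "GaussianWindow",
    "SpatialPointPattern",
    "RasterImage",
    "SpatialExpression",
    "make_window",
    "weighted_intensity",
    "build_spp",
    "spp_to_raster",
    "raster_to_spp",
    "eval_expression",
]


@dataclass
class GaussianWindow:
    """Data-dependent Gaussian mass window centred on an MOI m/z."""

    m_moi: float
    sigma_g: float

    def __post_init__(self):
        if self.sigma_g <= 0:
            raise ValueError("sigma_g must be positive")

    @property
    def support(self) -> tuple:
        """(lo, hi) of the effective support m_moi +/- 3 sigma_G."""
        return (self.m_moi - 3 * self.sigma_g, self.m_moi + 3 * self.sigma_g)

    def weights(self, mz) -> np.ndarray:
        """Envelope weight in [0, 1] for each m/z; zero outside the support."""
        mz = np.asarray(mz, float)
        w = np.exp(-((mz - self.m_moi) ** 2) / (2 * self.sigma_g**2))
        lo, hi = self.support
        return np.where((mz >= lo) & (mz <= hi), w, 0.0)


@dataclass
class SpatialPointPattern:
    """Marked 2-D point pattern inside a tissue window.

    ``window`` is a boolean (H, W) mask of unit pixel squares; the tissue
    area is the count of True pixels and the overall point density is
    Lambda = n / area.  Marks are the (Gaussian-weighted) intensities.
    """

    x: np.ndarray
    y: np.ndarray
    marks: np.ndarray
    window: np.ndarray
    check_marks: bool = True

    def __post_init__(self):
        self.x = np.asarray(self.x, float).ravel()
        self.y = np.asarray(self.y, float).ravel()
        self.marks = np.asarray(self.marks, float).ravel()
        self.window = np.asarray(self.window, bool)
        if not (self.x.size == self.y.size == self.marks.size):
            raise ValueError("x, y and marks must have equal length")
        if self.window.ndim != 2:
            raise ValueError("window must be a 2-D boolean mask")
        if self.check_marks and np.any(self.marks < 0):
            raise ValueError("marks must be nonnegative")
        if self.x.size:
            ix = np.rint(self.x).astype(int)
            iy = np.rint(self.y).astype(int)
            h, w = self.window.shape
            if ix.min() < 0 or iy.min() < 0 or ix.max() >= w or iy.max() >= h:
                raise ValueError("points outside the window bounding box")
            if not np.all(self.window[iy, ix]):
                raise ValueError("points outside the tissue window")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def area(self) -> float:
        return float(self.window.sum())

    @property
    def lambda_density(self) -> float:
        return self.n / self.area if self.area else 0.0

    @property
    def grid_aligned(self) -> bool:
        return bool(
            np.all(self.x == np.rint(self.x)) and np.all(self.y == np.rint(self.y))
        )

    def with_marks(self, marks, check_marks: bool | None = None) -> "SpatialPointPattern":
        return SpatialPointPattern(
            self.x,
            self.y,
            marks,
            self.window,
            check_marks=self.check_marks if check_marks is None else check_marks,
        )

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("x,y,mark\n")
            for xi, yi, mi in zip(self.x, self.y, self.marks):
                fh.write(f"{xi!r},{yi!r},{mi!r}\n")


@dataclass
class RasterImage:
    """Pixel-based image; NaN marks pixels outside the tissue."""

    values: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def shape(self) -> tuple:
        return self.values.shape


def make_window(m_moi: float, curve: FWHMCurve) -> GaussianWindow:
    """Gaussian window at ``m_moi`` with sigma_G from the fitted FWHM curve."""
    return GaussianWindow(m_moi, sigma_from_fwhm(float(curve.evaluate(m_moi))))


def weighted_intensity(mz, intensity, win: GaussianWindow, mode: str = "gaussian") -> float:
    """Summed (weighted) intensity of the peaks inside the mass window.

    ``gaussian`` weights each peak by the envelope (1 at the centre, e^{-9/2}
    at the support edge); ``uniform`` sums the same peaks with weight 1.
    """
    mz = np.asarray(mz, float)
    intensity = np.asarray(intensity, float)
    if mz.size == 0:
        return 0.0
    lo, hi = win.support
    inside = (mz >= lo) & (mz <= hi)
    if mode == "gaussian":
        return float(np.sum(win.weights(mz[inside]) * intensity[inside]))
    if mode == "uniform":
        return float(np.sum(intensity[inside]))
    raise ValueError(f"unknown weighting mode '{mode}'")


def build_spp(pm: PeakMatrix, win: GaussianWindow, mode: str = "gaussian") -> SpatialPointPattern:
    """Weight a peak matrix through the mass window into an SPP.

    Every measured pixel (including zero-intensity ones) contributes to the
    tissue window; pixels with positive weighted intensity become marked
    points at their grid coordinates.
    """
    if pm.n_pixels == 0:
        raise ValueError("empty peak matrix")
    lo, hi = win.support
    cols = np.flatnonzero((pm.mz_axis >= lo) & (pm.mz_axis <= hi))
    if cols.size:
        sub = pm.values[:, cols]
        if mode == "gaussian":
            w = win.weights(pm.mz_axis[cols])
        elif mode == "uniform":
            w = np.ones(cols.size)
        else:
            raise ValueError(f"unknown weighting mode '{mode}'")
        vals = np.asarray(sub @ w).ravel()
    else:
        vals = np.zeros(pm.n_pixels)
    h = pm.coords[:, 1].max() + 1
    w_ = pm.coords[:, 0].max() + 1
    window = np.zeros((h, w_), bool)
    window[pm.coords[:, 1], pm.coords[:, 0]] = True
    keep = vals > 0
    if not np.any(keep):
        warnings.warn("MOI absent in every pixel; returning an empty SPP", stacklevel=2)
    return SpatialPointPattern(
        pm.coords[keep, 0].astype(float),
        pm.coords[keep, 1].astype(float),
        vals[keep],
        window,
    )


def spp_to_raster(spp: SpatialPointPattern, snap: bool = False) -> RasterImage:
    """Rasterize a grid-aligned SPP; co-located marks are summed.

    Pixels in the window without a point are NaN.  Off-grid points raise
    unless ``snap=True``, which assigns them to the nearest pixel.
    """
    if not spp.grid_aligned and not snap:
        raise ValueError("SPP has off-grid points; pass snap=True to rasterize")
    img = np.full(spp.window.shape, np.nan)
    ix = np.rint(spp.x).astype(int)
    iy = np.rint(spp.y).astype(int)
    # sum co-located marks onto an initially-NaN canvas
    occupied = np.zeros(spp.window.shape, bool)
    occupied[iy, ix] = True
    img[occupied] = 0.0
    np.add.at(img, (iy, ix), spp.marks)
    return RasterImage(img)


def raster_to_spp(img: RasterImage, window: np.ndarray) -> SpatialPointPattern:
    """Points at every finite pixel of the raster, marks = pixel values."""
    window = np.asarray(window, bool)
    finite = np.isfinite(img.values) & window
    iy, ix = np.nonzero(finite)
    return SpatialPointPattern(
        ix.astype(float),
        iy.astype(float),
        img.values[iy, ix],
        window,
        check_marks=False,
    )


@dataclass
class SpatialExpression:
    """Parsed pixel-wise arithmetic over named SPP operands.

    Supports +, -, *, / with scalar constants, e.g.
    ``"(atp + 0.5*adp) / (atp + adp + amp)"``.
    """

    source: str
    tree: _ast.expression = field(init=False, repr=False)

    _ALLOWED = (
        _ast.Expression, _ast.BinOp, _ast.UnaryOp, _ast.Name, _ast.Constant,
        _ast.Add, _ast.Sub, _ast.Mult, _ast.Div, _ast.USub, _ast.UAdd,
        _ast.Load,
    )

    def __post_init__(self):
        self.tree = _ast.parse(self.source, mode="eval")
        for node in _ast.walk(self.tree):
            if not isinstance(node, self._ALLOWED):
                raise ValueError(
                    f"unsupported syntax {type(node).__name__!r} in spatial expression"
                )
            if isinstance(node, _ast.Constant) and not isinstance(node.value, (int, float)):
                raise ValueError("only numeric constants allowed")

    @property
    def names(self) -> set:
        return {n.id for n in _ast.walk(self.tree) if isinstance(n, _ast.Name)}

    @property
    def uses_division(self) -> bool:
        return any(isinstance(n, _ast.Div) for n in _ast.walk(self.tree))


def eval_expression(expr: SpatialExpression | str, operands: dict) -> SpatialPointPattern:
    """Evaluate a spatial arithmetic expression pixel-by-pixel.

    All operand SPPs must share the same tissue window.  The result is
    defined only on pixels where every operand has a point; divisions by
    zero (peak absent) drop the pixel.  The resulting raster is converted
    back into an SPP carrying the computed per-pixel values.
    """
    if isinstance(expr, str):
        expr = SpatialExpression(expr)
    missing = expr.names - set(operands)
    if missing:
        raise ValueError(f"unbound operand name(s): {sorted(missing)}")
    if expr.uses_division:
        warnings.warn(
            "spatial expression contains division; ratios can amplify intensity "
            "uncertainty",
            stacklevel=2,
        )
    spps = {k: operands[k] for k in expr.names}
    windows = [s.window for s in spps.values()]
    ref = windows[0]
    for wdw in windows[1:]:
        if wdw.shape != ref.shape or not np.array_equal(wdw, ref):
            raise ValueError("operand windows differ")
    rasters = {k: spp_to_raster(s).values for k, s in spps.items()}

    def ev(node):
        if isinstance(node, _ast.Expression):
            return ev(node.body)
        if isinstance(node, _ast.Constant):
            return float(node.value)
        if isinstance(node, _ast.Name):
            return rasters[node.id]
        if isinstance(node, _ast.UnaryOp):
            v = ev(node.operand)
            return -v if isinstance(node.op, _ast.USub) else +v
        left, right = ev(node.left), ev(node.right)
        with np.errstate(divide="ignore", invalid="ignore"):
            if isinstance(node.op, _ast.Add):
                return left + right
            if isinstance(node.op, _ast.Sub):
                return left - right
            if isinstance(node.op, _ast.Mult):
                return left * right
            out = np.asarray(left / right, float)
            out[~np.isfinite(out)] = np.nan
            return out

    result = ev(expr.tree)
    result = np.asarray(result, float)
    result = np.where(np.isfinite(result), result, np.nan)
    return raster_to_spp(RasterImage(result), ref)
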