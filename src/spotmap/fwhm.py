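"""Peak-width (FWHM) modelling as a smooth function of m/z.

Mass resolving power varies nonlinearly with m/z; for FTICR it degrades
quadratically.  Rather than assuming an instrument model, the peak width used
for mass-window weighting is measured empirically: FWHM values of isolated
peaks (SNR >= 3) are extracted from one full-profile spectrum and smoothed by
locally weighted polynomial regression (LOESS) into a continuous FWHM(m/z)
curve.  The closed-form resolution formulas for the undamped / damped FTICR
and linear-TOF regimes are provided for qualitative comparison plots; the
measured curve is what drives the weighting pipeline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .io import ProfileSpectrum

__all__ = [
    "FWHMCurve",
    "ResolutionModelParams",
    "extract_fwhm_points",
    "fit_fwhm_curve",
    "theoretical_fwhm",
    "sigma_from_fwhm",
    "FWHM_TO_SIGMA",
]

#: FWHM = 2*sqrt(2 ln 2) * sigma for a Gaussian peak.
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class FWHMCurve:
    """Smooth positive FWHM(m/z) interpolant fitted by LOESS.

    ``evaluate`` clamps queries outside the trained m/z range to the boundary
    value (with a warning) instead of extrapolating the local polynomials.
    """

    train_mz: np.ndarray
    train_fwhm: np.ndarray
    span: float = 0.5
    degree: int = 2
    snr_min: float = 3.0

    def __post_init__(self):
        self.train_mz = np.asarray(self.train_mz, float)
        self.train_fwhm = np.asarray(self.train_fwhm, float)
        if self.train_mz.size != self.train_fwhm.size:
            raise ValueError("train arrays must have equal length")
        if self.train_mz.size < 10:
            raise ValueError("need at least 10 (m/z, FWHM) points to fit a curve")
        order = np.argsort(self.train_mz)
        self.train_mz = self.train_mz[order]
        self.train_fwhm = self.train_fwhm[order]

    @property
    def domain(self) -> tuple:
        return float(self.train_mz[0]), float(self.train_mz[-1])

    def evaluate(self, mz) -> np.ndarray | float:
        scalar = np.isscalar(mz)
        q = np.atleast_1d(np.asarray(mz, float))
        lo, hi = self.domain
        if np.any((q < lo) | (q > hi)):
            warnings.warn(
                "m/z outside the trained FWHM range; clamping to boundary",
                stacklevel=2,
            )
        q = np.clip(q, lo, hi)
        out = _loess_predict(self.train_mz, self.train_fwhm, q, self.span, self.degree)
        # local polynomials can dip; peak widths are physically positive
        floor = 1e-3 * float(np.min(self.train_fwhm))
        out = np.maximum(out, max(floor, np.finfo(float).tiny))
        return float(out[0]) if scalar else out

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "train_mz": self.train_mz.tolist(),
                "train_fwhm": self.train_fwhm.tolist(),
                "span": self.span,
                "degree": self.degree,
                "snr_min": self.snr_min,
            }
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "FWHMCurve":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        return cls(
            np.asarray(data["train_mz"]),
            np.asarray(data["train_fwhm"]),
            span=data.get("span", 0.5),
            degree=data.get("degree", 2),
            snr_min=data.get("snr_min", 3.0),
        )


@dataclass
class ResolutionModelParams:
    """Instrument parameters for the closed-form resolution formulas.

    All quantities must be supplied in one consistent unit system; outputs are
    in that same system (the constants' unit conventions are not normalised
    internally).
    """

    B: float | None = None  # magnetic field
    q: float = 1.0  # ion charge, multiples of e
    T_fid: float | None = None  # free-induction-decay time
    tau: float | None = None  # radial damping constant
    t: float | None = None  # time of flight
    dt: float | None = None  # TOF peak width

    @property
    def omega_c(self) -> float | None:
        return None  # derived as q*B/m per-ion; kept for API completeness


def extract_fwhm_points(sp: ProfileSpectrum, snr_min: float = 3.0):
    """Measure FWHM of isolated peaks in a profile spectrum.

    The noise level is the scaled median absolute deviation of the intensity
    trace (1.4826 * MAD); local maxima with apex/noise >= ``snr_min`` are
    accepted.  Each flank is walked from the apex until it crosses half
    maximum; the crossing m/z is found by linear interpolation.  Peaks whose
    flank turns upward (a neighbouring peak) before reaching half maximum are
    skipped.

    Returns ``(mz, fwhm)`` arrays for the accepted peaks.
    """
    inten = sp.intensity
    mz = sp.mz
    mad = np.median(np.abs(inten - np.median(inten)))
    noise = 1.4826 * mad
    if noise <= 0:
        noise = np.finfo(float).tiny
    peaks, _ = find_peaks(inten, height=snr_min * noise)
    out_mz, out_fwhm = [], []
    for p in peaks:
        half = inten[p] / 2.0
        left = _half_crossing(mz, inten, p, half, -1)
        right = _half_crossing(mz, inten, p, half, +1)
        if left is None or right is None:
            continue
        out_mz.append(mz[p])
        out_fwhm.append(right - left)
    if not out_mz:
        raise ValueError(
            "no qualifying peaks (SNR >= %g) with resolvable half-max flanks; "
            "choose a different profile spectrum" % snr_min
        )
    return np.asarray(out_mz), np.asarray(out_fwhm)


def _half_crossing(mz, inten, p, half, step):
    """m/z where the flank of peak ``p`` crosses ``half``, or None."""
    j = p
    while True:
        k = j + step
        if k < 0 or k >= inten.size:
            return None
        if inten[k] > inten[j]:  # flank rises again: neighbouring peak
            return None
        if inten[k] <= half:
            # crossing between j and k
            denom = inten[j] - inten[k]
            frac = (inten[j] - half) / denom if denom > 0 else 0.0
            return float(mz[j] + frac * (mz[k] - mz[j]))
        j = k


def fit_fwhm_curve(
    mz, fwhm, span: float = 0.5, degree: int = 2, snr_min: float = 3.0
) -> FWHMCurve:
    """Fit a LOESS curve through (m/z, FWHM) points.

    Local polynomial regression with tricube weights over the nearest
    ``span`` fraction of points; degree-2 local polynomials by default.
    """
    mz = np.asarray(mz, float)
    fwhm = np.asarray(fwhm, float)
    if mz.size < 10:
        raise ValueError("need at least 10 points to fit an FWHM curve")
    return FWHMCurve(mz, fwhm, span=span, degree=degree, snr_min=snr_min)


def _loess_predict(x, y, xq, span, degree):
    """Tricube-weighted local polynomial regression (x sorted ascending)."""
    n = x.size
    k = max(int(np.ceil(span * n)), degree + 1)
    k = min(k, n)
    out = np.empty(xq.size)
    for i, x0 in enumerate(xq):
        d = np.abs(x - x0)
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = y[idx][d[idx] == 0].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0, None)
        # guard against rank deficiency at the edges
        deg = min(degree, max(1, np.count_nonzero(w > 0) - 1))
        xs = x[idx] - x0
        coeffs = np.polyfit(xs, y[idx], deg, w=np.sqrt(w))
        out[i] = np.polyval(coeffs, 0.0)
    return out


def theoretical_fwhm(m, params: ResolutionModelParams, regime: str):
    """Closed-form peak width Delta-m for a given instrument regime.

    ``low_pressure``: undamped FTICR signal within the FID time,
    Delta-m = 7.589 m^2 / (q B T_fid).
    ``damped``: radially damped FTICR transient,
    Delta-m = 2 sqrt(3) m^2 / (q B tau).
    ``tof``: linear TOF, resolving power m/Delta-m = t/(2 dt), hence
    Delta-m = 2 m dt / t.

    Inputs and outputs are in whatever consistent unit system the caller
    supplies via ``params``.
    """
    m = np.asarray(m, float)
    if regime == "low_pressure":
        for name in ("B", "T_fid"):
            if getattr(params, name) is None:
                raise ValueError(f"regime 'low_pressure' requires parameter '{name}'")
        return 7.589 * m**2 / (params.q * params.B * params.T_fid)
    if regime == "damped":
        for name in ("B", "tau"):
            if getattr(params, name) is None:
                raise ValueError(f"regime 'damped' requires parameter '{name}'")
        return 2.0 * np.sqrt(3.0) * m**2 / (params.q * params.B * params.tau)
    if regime == "tof":
        for name in ("t", "dt"):
            if getattr(params, name) is None:
                raise ValueError(f"regime 'tof' requires parameter '{name}'")
        return 2.0 * m * params.dt / params.t
    raise ValueError(f"unknown regime '{regime}'")


def sigma_from_fwhm(fwhm):
    """Standard deviation of a Gaussian with the given FWHM.

    sigma_G = FWHM / (2 sqrt(2 ln 2)).
    """
    fwhm = np.asarray(fwhm, float)
    if np.any(fwhm <= 0):
        raise ValueError("FWHM must be positive")
    out = fwhm / FWHM_TO_SIGMA
    return float(out) if out.ndim == 0 else out
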