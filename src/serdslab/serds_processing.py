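"""Difference-spectrum computation for shifted-excitation pairs.

A SERDS pair is two co-registered spectra acquired at excitations a small
wavelength step apart.  Subtracting them cancels everything that does not
move with the excitation (fluorescence, ambient light), but only if the
two frames have the same background amplitude.  Laser-power variation and
photobleaching break that, so before subtraction the pair can be
normalised per-spectrum (area or z-score/SNV) or the subtrahend can be
rescaled by a factor x chosen to minimise the integrated magnitude of the
difference (subtraction optimisation):

    raw     D = S1 - S2
    area    D = S1/sum(S1) - S2/sum(S2)
    zscore  D = (S1 - mean)/sd - (S2 - mean)/sd
    subopt  D = S1 - x* S2,   x* = argmin_x AUC(|S1 - x S2|)

Residual smooth background left in D can be removed by a polynomial fitted
to the off-band pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import minimize_scalar

from .spectral_core import Spectrum

__all__ = [
    "SerdsMethod",
    "SerdsPair",
    "SerdsResult",
    "area_normalize",
    "zscore_normalize",
    "subtraction_optimize",
    "serds_difference",
    "residual_polynomial_correct",
]


class SerdsMethod(str, Enum):
    raw = "raw"
    area = "area"
    zscore = "zscore"
    subopt = "subopt"


@dataclass
class SerdsPair:
    """Co-registered pair; ``s1`` is the longer-excitation frame."""

    s1: Spectrum
    s2: Spectrum

    def __post_init__(self):
        if not np.array_equal(self.s1.axis, self.s2.axis):
            raise ValueError(
                "pair is not co-registered; resample both onto one grid first "
                "(spectral_core.resample_to_grid)")
        e1 = self.s1.meta.get("acquisition_excitation_nm")
        e2 = self.s2.meta.get("acquisition_excitation_nm")
        if e1 is not None and e2 is not None:
            if e1 == e2:
                raise ValueError("pair excitations are identical (shift 0)")
            if e1 < e2:  # normalise orientation: s1 at the longer wavelength
                self.s1, self.s2 = self.s2, self.s1

    @property
    def shift_nm(self) -> float | None:
        e1 = self.s1.meta.get("acquisition_excitation_nm")
        e2 = self.s2.meta.get("acquisition_excitation_nm")
        if e1 is None or e2 is None:
            return None
        return e1 - e2


@dataclass
class SerdsResult:
    difference: Spectrum
    method: SerdsMethod
    opt_factor: float = 1.0
    residual_baseline_removed: bool = False


def area_normalize(s: Spectrum) -> Spectrum:
    """Scale so the intensities sum to one."""
    total = s.intensity.sum()
    if total == 0:
        raise ValueError("cannot area-normalize a zero-sum spectrum")
    return s.with_intensity(s.intensity / total, normalization="area")


def zscore_normalize(s: Spectrum, *, ddof: int = 0) -> Spectrum:
    """Centre to mean 0 and scale to unit standard deviation (SNV).

    ``ddof=0`` uses the population standard deviation; ``ddof=1`` the sample
    convention.  The convention used is recorded in the output metadata.
    """
    sd = s.intensity.std(ddof=ddof)
    if sd == 0:
        raise ValueError("cannot z-score a constant spectrum")
    out = (s.intensity - s.intensity.mean()) / sd
    return s.with_intensity(out, normalization="zscore", zscore_ddof=ddof)


def _abs_auc(axis: np.ndarray, y: np.ndarray) -> float:
    return float(np.trapezoid(np.abs(y), axis))


def subtraction_optimize(pair: SerdsPair, *, bracket: tuple[float, float] = (0.2, 5.0),
                         grid_points: int = 200, xatol: float = 1e-6) -> float:
    """Factor x* minimising AUC(|S1 - x S2|) (trapezoid on the common axis).

    The objective is piecewise linear in x with many kinks, so a coarse grid
    pre-scan brackets the global minimum before bounded scalar refinement.
    """
    if not np.any(pair.s2.intensity):
        raise ValueError("s2 is identically zero; optimization is unbounded")
    axis = pair.s1.axis
    y1, y2 = pair.s1.intensity, pair.s2.intensity
    xs = np.linspace(bracket[0], bracket[1], grid_points)
    aucs = np.trapezoid(np.abs(y1[None, :] - xs[:, None] * y2[None, :]), axis, axis=1)
    k = int(np.argmin(aucs))
    lo = xs[max(k - 1, 0)]
    hi = xs[min(k + 1, grid_points - 1)]
    res = minimize_scalar(lambda x: _abs_auc(axis, y1 - x * y2), bounds=(lo, hi),
                          method="bounded", options={"xatol": xatol})
    return float(res.x)


def serds_difference(pair: SerdsPair, method: SerdsMethod | str = SerdsMethod.raw,
                     **opt_kwargs) -> SerdsResult:
    """Difference spectrum of a co-registered pair under the chosen method."""
    method = SerdsMethod(method)
    x = 1.0
    if method is SerdsMethod.raw:
        diff = pair.s1.intensity - pair.s2.intensity
    elif method is SerdsMethod.area:
        diff = area_normalize(pair.s1).intensity - area_normalize(pair.s2).intensity
    elif method is SerdsMethod.zscore:
        diff = zscore_normalize(pair.s1).intensity - zscore_normalize(pair.s2).intensity
    else:
        x = subtraction_optimize(pair, **opt_kwargs)
        diff = pair.s1.intensity - x * pair.s2.intensity
    meta = {"method": method.value}
    if pair.shift_nm is not None:
        meta["shift_nm"] = pair.shift_nm
    return SerdsResult(difference=pair.s1.with_intensity(diff, **meta),
                       method=method, opt_factor=x)


def residual_polynomial_correct(result: SerdsResult, degree: int = 3,
                                band_windows: list[tuple[float, float, float]] | None = None,
                                **detect_kwargs) -> SerdsResult:
    """Remove smooth background remaining in a difference spectrum.

    A degree-``degree`` polynomial is least-squares fitted to the pixels
    outside detected band windows (band detection runs on |difference|
    unless windows are supplied) and subtracted everywhere.
    """
    d = result.difference
    n = len(d)
    if degree > 7:
        raise ValueError("degree above 7 is not supported")
    if degree >= n / 10:
        raise ValueError("polynomial degree too high for the record length")
    if band_windows is None:
        from .snr_eval import detect_bands

        # generous windows: band tails biasing the background fit are worse
        # here than losing off-band pixels
        detect_kwargs.setdefault("window_halfwidth_pts", 40)
        detect_kwargs.setdefault("threshold_frac", 0.02)
        band_windows = detect_bands(d.with_intensity(np.abs(d.intensity)),
                                    **detect_kwargs)
    mask = np.ones(n, dtype=bool)
    for lo, hi, _c in band_windows:
        mask &= ~((d.axis >= lo) & (d.axis <= hi))
    if mask.sum() <= degree + 1:
        raise ValueError("too few off-band pixels to fit the polynomial")
    coeffs = np.polynomial.Polynomial.fit(d.axis[mask], d.intensity[mask], degree)
    corrected = d.intensity - coeffs(d.axis)
    return SerdsResult(difference=d.with_intensity(corrected, residual_poly=degree),
                       method=result.method, opt_factor=result.opt_factor,
                       residual_baseline_removed=True)
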