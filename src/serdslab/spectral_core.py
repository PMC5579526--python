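"""Axis conventions, unit conversions, resampling, baselines and filters.

All downstream stages share one canonical axis: Raman shift in cm^-1
relative to a 785 nm excitation, on a uniform grid from 400 to 3200 cm^-1
with a default step of 2 cm^-1.  Spectra may also live on an absolute
detector wavelength axis (nm); conversions between the two frames are the
closed forms

    nu = 1e7 * (1/lambda_exc - 1/lambda)        [cm^-1, lambda in nm]
    lambda = 1 / (1/lambda_exc - nu/1e7)

The asymmetry that makes shifted-excitation difference spectroscopy work is
expressed entirely through these maps: Raman features are fixed in the
shift frame of their own excitation, fluorescence is fixed in the
wavelength frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.signal import savgol_filter as _sp_savgol
from scipy.interpolate import CubicSpline
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "AxisKind",
    "Spectrum",
    "Baseline",
    "DEFAULT_EXCITATION_NM",
    "canonical_grid",
    "excitation_shift_to_raman_displacement",
    "wavelength_to_raman_shift",
    "raman_shift_to_wavelength",
    "to_raman_shift_axis",
    "resample_to_grid",
    "rubberband_baseline",
    "savgol",
]

DEFAULT_EXCITATION_NM = 785.0


class AxisKind(str, Enum):
    wavelength_nm = "wavelength_nm"
    raman_shift_cm1 = "raman_shift_cm1"


def canonical_grid(lo: float = 400.0, hi: float = 3200.0, step: float = 2.0) -> np.ndarray:
    """Uniform Raman-shift grid (cm^-1) shared by all processing stages."""
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


@dataclass
class Spectrum:
    """An intensity trace on an explicit axis.

    Parameters
    ----------
    axis : strictly increasing array, wavelength (nm) or Raman shift (cm^-1).
    intensity : counts, same length as ``axis``.
    axis_kind : which frame ``axis`` lives in.
    excitation_nm : reference excitation wavelength; required for the
        Raman-shift frame, optional metadata otherwise.
    meta : free-form acquisition metadata (sample label, seed, ...).
    """

    axis: np.ndarray
    intensity: np.ndarray
    axis_kind: AxisKind = AxisKind.raman_shift_cm1
    excitation_nm: float | None = DEFAULT_EXCITATION_NM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.axis_kind = AxisKind(self.axis_kind)
        if self.axis.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("axis and intensity must be 1-D")
        if self.axis.size != self.intensity.size:
            raise ValueError("axis and intensity lengths differ")
        if self.axis.size < 8:
            raise ValueError("spectrum needs at least 8 points")
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.axis_kind is AxisKind.raman_shift_cm1:
            if self.excitation_nm is None or self.excitation_nm <= 0:
                raise ValueError("raman_shift_cm1 axis requires excitation_nm > 0")

    def __len__(self) -> int:
        return self.axis.size

    @property
    def step(self) -> float:
        """Median axis spacing."""
        return float(np.median(np.diff(self.axis)))

    def with_intensity(self, intensity: np.ndarray, **meta) -> "Spectrum":
        return replace(self, intensity=np.asarray(intensity, dtype=float),
                       meta={**self.meta, **meta})


@dataclass
class Baseline:
    """Rubberband baseline: hull support points, baseline and corrected trace."""

    support_points: np.ndarray  # indices into the spectrum
    baseline: np.ndarray
    corrected: np.ndarray


def _require_positive(name: str, *values: float) -> None:
    for v in values:
        if not np.all(np.asarray(v) > 0):
            raise ValueError(f"{name} must be positive")


def excitation_shift_to_raman_displacement(lambda1_nm: float, lambda2_nm: float) -> float:
    """Displacement (cm^-1) of Raman bands on a common shift axis when the
    excitation moves from ``lambda1_nm`` to ``lambda2_nm``.

    Antisymmetric under argument swap; e.g. a 785 -> 792 nm shift displaces
    the bands by ~112.6 cm^-1.
    """
    _require_positive("wavelength", lambda1_nm, lambda2_nm)
    return 1e7 * (1.0 / lambda1_nm - 1.0 / lambda2_nm)


def wavelength_to_raman_shift(lambda_nm, excitation_nm: float):
    """Stokes Raman shift nu = 1e7 (1/lambda_exc - 1/lambda), cm^-1."""
    _require_positive("wavelength", lambda_nm, excitation_nm)
    return 1e7 * (1.0 / excitation_nm - 1.0 / np.asarray(lambda_nm, dtype=float))


def raman_shift_to_wavelength(shift_cm1, excitation_nm: float):
    """Inverse of :func:`wavelength_to_raman_shift`."""
    _require_positive("excitation", excitation_nm)
    denom = 1.0 / excitation_nm - np.asarray(shift_cm1, dtype=float) / 1e7
    if np.any(denom <= 0):
        raise ValueError("Raman shift beyond the optical range for this excitation")
    return 1.0 / denom


def to_raman_shift_axis(spectrum: Spectrum,
                        reference_excitation_nm: float = DEFAULT_EXCITATION_NM) -> Spectrum:
    """Re-express a wavelength-frame spectrum on a Raman-shift axis relative
    to ``reference_excitation_nm`` (the calibration every acquisition is
    brought to before co-registration).  Intensities are untouched; only the
    axis is relabelled."""
    if spectrum.axis_kind is AxisKind.raman_shift_cm1:
        if spectrum.excitation_nm == reference_excitation_nm:
            return spectrum
        wl = raman_shift_to_wavelength(spectrum.axis, spectrum.excitation_nm)
        shift = wavelength_to_raman_shift(wl, reference_excitation_nm)
    else:
        shift = wavelength_to_raman_shift(spectrum.axis, reference_excitation_nm)
    return Spectrum(axis=shift, intensity=spectrum.intensity.copy(),
                    axis_kind=AxisKind.raman_shift_cm1,
                    excitation_nm=reference_excitation_nm, meta=dict(spectrum.meta))


def resample_to_grid(spectrum: Spectrum, grid: np.ndarray, *,
                     kind: str = "linear", edge_policy: str = "error") -> Spectrum:
    """Interpolate a spectrum onto ``grid``.

    Linear by default (exact on affine profiles); ``kind="cubic"`` uses a
    natural cubic spline.  Grid points outside the axis span raise unless
    ``edge_policy="truncate"``, which drops them.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    lo, hi = spectrum.axis[0], spectrum.axis[-1]
    inside = (grid >= lo) & (grid <= hi)
    if not inside.all():
        if edge_policy == "truncate":
            grid = grid[inside]
            if grid.size < 8:
                raise ValueError("truncated grid too short")
        else:
            raise ValueError(
                "grid extends beyond the spectrum span; pass edge_policy='truncate'")
    if kind == "linear":
        vals = np.interp(grid, spectrum.axis, spectrum.intensity)
    elif kind == "cubic":
        vals = CubicSpline(spectrum.axis, spectrum.intensity)(grid)
    else:
        raise ValueError(f"unknown interpolation kind {kind!r}")
    return replace(spectrum, axis=grid, intensity=vals)


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull, left to right."""
    pts = np.column_stack([x, y])
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # collinear / constant spectrum: the hull is the segment itself
        return np.array([0, x.size - 1])
    verts = hull.vertices  # counter-clockwise
    start = int(np.where(verts == np.argmin(x))[0][0])
    verts = np.roll(verts, -start)
    # CCW from the leftmost point traverses the lower chain first
    end = int(np.where(verts == np.argmax(x))[0][0])
    lower = verts[: end + 1]
    return np.sort(lower)


def rubberband_baseline(spectrum: Spectrum, *, smooth: bool = True,
                        span_frac: float = 0.05, poly_degree: int = 2) -> Baseline:
    """Convex-hull ("rubberband") baseline with local-polynomial smoothing.

    Support points are the vertices of the lower convex hull of
    (axis, intensity); the piecewise-linear baseline through them is then
    smoothed by local polynomial regression (window = ``span_frac`` of the
    record, degree ``poly_degree``).  Before smoothing the corrected trace
    is exactly zero at every support point.
    """
    if len(spectrum) < 3:
        raise ValueError("need at least 3 points for a hull baseline")
    x, y = spectrum.axis, spectrum.intensity
    idx = _lower_hull_indices(x, y)
    base = np.interp(x, x[idx], y[idx])
    if smooth:
        n = x.size
        win = max(int(round(span_frac * n)), poly_degree + 2)
        if win % 2 == 0:
            win += 1
        win = min(win, n if n % 2 else n - 1)
        base = _sp_savgol(base, window_length=win, polyorder=poly_degree)
    return Baseline(support_points=idx, baseline=base, corrected=y - base)


def savgol(spectrum: Spectrum, window_pts: int, poly_order: int,
           deriv_order: int = 0) -> Spectrum:
    """Savitzky-Golay smoothing / differentiation on the spectrum's own axis.

    Derivatives are returned per axis unit (the uniform axis spacing is used
    as the sample interval)."""
    if window_pts % 2 == 0 or window_pts <= poly_order:
        raise ValueError("window_pts must be odd and exceed poly_order")
    if deriv_order < 0 or deriv_order > poly_order:
        raise ValueError("deriv_order must be in [0, poly_order]")
    if window_pts > len(spectrum):
        raise ValueError("window longer than spectrum")
    d = np.diff(spectrum.axis)
    if not np.allclose(d, d[0], rtol=1e-6):
        raise ValueError("Savitzky-Golay filtering requires a uniform axis")
    out = _sp_savgol(spectrum.intensity, window_length=window_pts,
                     polyorder=poly_order, deriv=deriv_order, delta=float(d[0]))
    return spectrum.with_intensity(out)
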