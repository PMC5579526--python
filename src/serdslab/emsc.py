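"""Extended multiplicative signal correction (EMSC) background removal.

A measured spectrum is modelled as a linear combination of *background*
components — a constant offset, a linear term, and several smooth
fluorescence shape functions — plus *pure component* reference spectra
(e.g. collagen-, protein-, lipid- and bone-like).  Ordinary least squares
fits all coefficients jointly; the fitted background part alone is then
subtracted, so the chemical signal content (whatever projects onto the
pure components and the residual) is retained:

    raw = X_bg b + X_pure c + r
    corrected = raw - X_bg b

The default design uses 7 background columns (constant, linear, plain
polynomials of order 2-6 on the min-max-scaled axis); measured or fitted
fluorescence shapes can be supplied instead.  Classic EMSC additionally
divides by the reference-component coefficient (multiplicative scatter
scaling); that rescaling is off by default and available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral_core import Spectrum, savgol

__all__ = ["EmscDesign", "EmscFit", "build_design", "emsc_fit",
           "first_derivative_view"]


@dataclass
class EmscDesign:
    axis: np.ndarray
    matrix: np.ndarray           # columns: background first, then pure
    labels: list[str]
    n_background: int

    @property
    def background(self) -> np.ndarray:
        return self.matrix[:, : self.n_background]

    @property
    def pure(self) -> np.ndarray:
        return self.matrix[:, self.n_background:]


@dataclass
class EmscFit:
    design: EmscDesign
    coefficients: np.ndarray
    residual_rms: float
    condition_number: float
    corrected: Spectrum

    def coefficient(self, label: str) -> float:
        return float(self.coefficients[self.design.labels.index(label)])


def build_design(axis: np.ndarray, pure: list[Spectrum], n_fluor: int = 5,
                 fluor_shapes: list[np.ndarray] | None = None,
                 orthogonalize: bool = False) -> EmscDesign:
    """Assemble the EMSC design matrix.

    Columns, in order: all-ones constant, axis min-max scaled to [0, 1],
    ``n_fluor`` fluorescence shapes (default: powers 2..n_fluor+1 of the
    scaled axis), then the pure-component spectra.  With the defaults the
    background block has 7 columns.  ``orthogonalize=True`` replaces the
    background block by its orthonormalised span (same column space).
    """
    axis = np.asarray(axis, dtype=float)
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    cols = [np.ones_like(t), t]
    labels = ["constant", "linear"]
    if fluor_shapes is not None:
        for j, shape in enumerate(fluor_shapes):
            shape = np.asarray(shape, dtype=float)
            if shape.size != axis.size:
                raise ValueError("fluorescence shape length mismatch")
            cols.append(shape)
            labels.append(f"fluor_{j + 1}")
    else:
        for k in range(2, 2 + n_fluor):
            cols.append(t**k)
            labels.append(f"fluor_poly{k}")
    n_bg = len(cols)
    if orthogonalize:
        q, _ = np.linalg.qr(np.column_stack(cols))
        cols = [q[:, j] for j in range(n_bg)]
    for p in pure:
        if not np.array_equal(p.axis, axis):
            raise ValueError("pure-component spectrum not on the design axis; "
                             "resample it first")
        cols.append(p.intensity)
        labels.append(p.meta.get("label", f"pure_{len(labels) - n_bg + 1}"))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        null = np.abs(vt[-1])
        guilty = [labels[j] for j in np.where(null > 0.3 * null.max())[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {guilty}")
    return EmscDesign(axis=axis, matrix=X, labels=labels, n_background=n_bg)


def emsc_fit(raw: Spectrum, design: EmscDesign, *,
             rescale_to: str | None = None, ridge: float = 0.0) -> EmscFit:
    """Fit the design to a raw spectrum and subtract the background part.

    ``rescale_to=<pure label>`` additionally divides the corrected spectrum
    by that component's coefficient (classic multiplicative correction).
    ``ridge`` adds Tikhonov damping for near-collinear designs (off by
    default).
    """
    if not np.array_equal(raw.axis, design.axis):
        raise ValueError("spectrum is not on the design axis")
    X = design.matrix
    y = raw.intensity
    if ridge > 0:
        n = X.shape[1]
        coef = np.linalg.solve(X.T @ X + ridge * np.eye(n), X.T @ y)
    else:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    background = design.background @ coef[: design.n_background]
    corrected = y - background
    if rescale_to is not None:
        scale = coef[design.labels.index(rescale_to)]
        if scale == 0:
            raise ValueError(f"cannot rescale: coefficient of {rescale_to!r} is zero")
        corrected = corrected / scale
    cond = float(np.linalg.cond(X))
    return EmscFit(design=design, coefficients=coef,
                   residual_rms=float(np.sqrt(np.mean(resid**2))),
                   condition_number=cond,
                   corrected=raw.with_intensity(corrected, emsc="background-subtracted"))


def first_derivative_view(fit: EmscFit, window_pts: int = 11,
                          sg_order: int = 3) -> Spectrum:
    """Savitzky-Golay first derivative of the corrected spectrum, for
    positional comparison with difference spectra (band maxima sit at the
    derivative's zero crossings, difference-spectrum extrema near its
    extrema)."""
    return savgol(fit.corrected, window_pts, sg_order, deriv_order=1)
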