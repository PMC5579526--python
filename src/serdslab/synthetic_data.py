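"""Synthetic shot-noise-limited Raman acquisitions with fluorescence backgrounds.

The generator emulates the structure of biochemical tissue spectra used to
study background-correction methods:

* parametric band sets (Gaussian/Lorentzian) standing in for measured
  lipid, protein, collagen and mineralised-bone component spectra, with
  deliberately heterogeneous bandwidths (a ~10 cm^-1 phenylalanine ring
  breathing line up to a ~85 cm^-1 CH-stretch envelope component), because
  the width spread is what breaks the classic "shift by one FWHM" rule;
* a smooth polynomial fluorescence background parameterised in the
  absolute wavelength frame — under an excitation shift the Raman bands
  move on the detector while the fluorescence profile stays put, which is
  the asymmetry difference spectroscopy exploits;
* Poisson shot noise (mean = expected counts, std = sqrt(counts)), with a
  Gaussian N(I, I) approximation available;
* multi-excitation series with optional per-frame laser-power factors and
  photobleaching decay.

Fixtures are versioned constants chosen from standard Raman band
assignments; they reproduce the qualitative structure of tissue component
spectra, not any particular measured sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from numpy.polynomial import polynomial as P

from .spectral_core import (
    AxisKind,
    Spectrum,
    DEFAULT_EXCITATION_NM,
    canonical_grid,
    wavelength_to_raman_shift,
)

__all__ = [
    "Band",
    "BandSet",
    "FluorescenceModel",
    "AcquisitionConfig",
    "default_detector_grid",
    "synth_pure_spectrum",
    "lipid_like_fixture",
    "protein_like_fixture",
    "collagen_like_fixture",
    "bone_like_fixture",
    "fixture_by_label",
    "default_fluorescence",
    "synth_fluorescence",
    "simulate_acquisition",
    "simulate_serds_series",
    "series_to_reference_axis",
]


class BandShape(str, Enum):
    gaussian = "gaussian"
    lorentzian = "lorentzian"


@dataclass(frozen=True)
class Band:
    """One Raman band: centre (cm^-1), FWHM (cm^-1), peak amplitude (counts)."""

    center_cm1: float
    fwhm_cm1: float
    amplitude: float
    shape: BandShape = BandShape.gaussian

    def __post_init__(self):
        if self.fwhm_cm1 <= 0 or self.amplitude <= 0:
            raise ValueError("band FWHM and amplitude must be positive")

    def profile(self, x: np.ndarray) -> np.ndarray:
        dx = np.asarray(x, dtype=float) - self.center_cm1
        if BandShape(self.shape) is BandShape.gaussian:
            return self.amplitude * np.exp(-4.0 * np.log(2.0) * dx**2 / self.fwhm_cm1**2)
        hw2 = (self.fwhm_cm1 / 2.0) ** 2
        return self.amplitude * hw2 / (dx**2 + hw2)


@dataclass(frozen=True)
class BandSet:
    bands: tuple[Band, ...]
    label: str = ""

    def __post_init__(self):
        if not self.bands:
            raise ValueError("band set must be non-empty")

    @property
    def max_amplitude(self) -> float:
        return max(b.amplitude for b in self.bands)


# ---------------------------------------------------------------------------
# Versioned component fixtures (centres from standard Raman assignments)
# ---------------------------------------------------------------------------

_PEAK = 1000.0  # counts of the strongest band in each fixture


def _bandset(label: str, rows: list[tuple[float, float, float]]) -> BandSet:
    return BandSet(tuple(Band(c, w, a * _PEAK) for c, w, a in rows), label=label)


def lipid_like_fixture() -> BandSet:
    """Triacylglyceride-like band set: sharp ester/acyl fingerprint bands
    plus the broad CH_n stretch envelope between 2800 and 3100 cm^-1."""
    return _bandset("lipid-like", [
        # (centre cm^-1, FWHM cm^-1, relative amplitude)
        (1078, 20, 0.35),   # C-C skeletal stretch
        (1266, 16, 0.30),   # =C-H in-plane
        (1301, 18, 0.55),   # CH2 twist
        (1440, 24, 0.80),   # CH2 scissoring
        (1655, 22, 0.35),   # C=C stretch
        (1746, 12, 0.30),   # ester C=O, narrow
        (2850, 30, 0.90),   # CH2 symmetric stretch
        (2885, 40, 0.85),   # CH2 asymmetric stretch
        (2935, 85, 0.60),   # broad CH_n envelope component
    ])


def protein_like_fixture() -> BandSet:
    """Globular-protein-like band set: narrow phenylalanine ring breathing,
    broad amide envelopes, CH3-dominated high-wavenumber region."""
    return _bandset("protein-like", [
        (1003, 10, 0.55),   # phenylalanine ring breathing, narrow
        (1250, 45, 0.45),   # amide III envelope
        (1340, 30, 0.35),   # CH deformation
        (1450, 30, 0.60),   # CH2/CH3 deformation
        (1660, 35, 0.85),   # amide I
        (2880, 60, 0.50),
        (2935, 70, 0.90),   # CH3 stretch envelope
    ])


def collagen_like_fixture() -> BandSet:
    """Fibrous-collagen-like band set (proline/hydroxyproline markers)."""
    return _bandset("collagen-like", [
        (855, 18, 0.50),    # proline ring
        (938, 20, 0.45),    # C-C backbone
        (1004, 10, 0.25),
        (1248, 40, 0.45),   # amide III
        (1454, 30, 0.55),
        (1668, 40, 0.80),   # amide I
        (2940, 80, 0.85),
    ])


def bone_like_fixture() -> BandSet:
    """Mineralised-tissue band set dominated by the narrow phosphate nu1 line."""
    return _bandset("bone-like", [
        (590, 30, 0.30),    # PO4 nu4
        (960, 14, 1.00),    # PO4 nu1, strong and narrow
        (1070, 25, 0.25),   # carbonate
        (1450, 30, 0.20),
        (1665, 40, 0.25),
        (2940, 70, 0.30),
    ])


_FIXTURES = {
    "lipid": lipid_like_fixture,
    "protein": protein_like_fixture,
    "collagen": collagen_like_fixture,
    "bone": bone_like_fixture,
}


def fixture_by_label(label: str) -> BandSet:
    key = label.split("-")[0].lower()
    try:
        return _FIXTURES[key]()
    except KeyError:
        raise KeyError(f"unknown fixture {label!r}; choose from {sorted(_FIXTURES)}")


def synth_pure_spectrum(bands: BandSet, grid_cm1: np.ndarray | None = None) -> Spectrum:
    """Render a noiseless pure-component spectrum (sum of band profiles) on a
    Raman-shift grid.  The grid must cover every band centre +/- 3 FWHM."""
    if grid_cm1 is None:
        grid_cm1 = canonical_grid()
    grid_cm1 = np.asarray(grid_cm1, dtype=float)
    lo, hi = grid_cm1[0], grid_cm1[-1]
    for b in bands.bands:
        if b.center_cm1 - 3 * b.fwhm_cm1 < lo or b.center_cm1 + 3 * b.fwhm_cm1 > hi:
            raise ValueError(
                f"grid [{lo}, {hi}] cm^-1 does not cover band at {b.center_cm1} "
                f"cm^-1 (+/- 3 FWHM)")
    intensity = np.sum([b.profile(grid_cm1) for b in bands.bands], axis=0)
    return Spectrum(axis=grid_cm1, intensity=intensity,
                    axis_kind=AxisKind.raman_shift_cm1,
                    excitation_nm=DEFAULT_EXCITATION_NM,
                    meta={"label": bands.label})


# ---------------------------------------------------------------------------
# Fluorescence background
# ---------------------------------------------------------------------------


class ScaleMode(str, Enum):
    absolute = "absolute"
    multiple_of_max_band = "multiple_of_max_band"


@dataclass(frozen=True)
class FluorescenceModel:
    """Smooth polynomial background in the absolute-wavelength frame.

    ``poly_coeffs`` are ascending coefficients of a polynomial in the
    detector wavelength (nm).  With ``scale_mode="multiple_of_max_band"``
    the evaluated shape is rescaled so its maximum over the grid equals
    ``scale`` times the maximal band of a Raman reference spectrum — e.g.
    scale 5/8/10 emulates backgrounds 5/8/10 times the strongest band.
    """

    poly_coeffs: tuple[float, ...]
    scale_mode: ScaleMode = ScaleMode.multiple_of_max_band
    scale: float = 5.0

    def evaluate_shape(self, wavelength_nm: np.ndarray) -> np.ndarray:
        vals = P.polyval(np.asarray(wavelength_nm, dtype=float),
                         np.asarray(self.poly_coeffs, dtype=float))
        if np.any(vals < -1e-9 * max(1.0, np.abs(vals).max())):
            raise ValueError("fluorescence polynomial is negative on the grid")
        return np.clip(vals, 0.0, None)


def default_fluorescence(scale: float = 5.0) -> FluorescenceModel:
    """Concave cubic background peaking near 950 nm, zero-ish at the span
    edges plus a 15% pedestal; unit maximum before scaling."""
    # 0.15 + (l-800)(1085-l)(1900-l)/norm, expanded to raw coefficients
    root_part = P.polyfromroots([800.0, 1085.0, 1900.0])  # (l-800)(l-1085)(l-1900)
    grid = np.linspace(806.0, 1075.0, 2001)
    shape = -P.polyval(grid, root_part)
    norm = shape.max()
    coeffs = -root_part / norm * 0.85
    coeffs[0] += 0.15
    return FluorescenceModel(poly_coeffs=tuple(coeffs), scale=scale)


def synth_fluorescence(model: FluorescenceModel, raman_reference: Spectrum | None,
                       grid_nm: np.ndarray) -> Spectrum:
    """Evaluate the fluorescence background on a wavelength grid.

    In ``multiple_of_max_band`` mode the returned trace has an exact maximum
    of ``model.scale * max(raman_reference.intensity)``.
    """
    grid_nm = np.asarray(grid_nm, dtype=float)
    shape = model.evaluate_shape(grid_nm)
    if ScaleMode(model.scale_mode) is ScaleMode.multiple_of_max_band:
        if raman_reference is None:
            raise ValueError("multiple_of_max_band scaling needs a Raman reference")
        if model.scale == 0 or shape.max() == 0:
            vals = np.zeros_like(shape)
        else:
            vals = shape * (model.scale * raman_reference.intensity.max() / shape.max())
    else:
        vals = model.scale * shape
    return Spectrum(axis=grid_nm, intensity=vals, axis_kind=AxisKind.wavelength_nm,
                    excitation_nm=None, meta={"label": "fluorescence"})


# ---------------------------------------------------------------------------
# Acquisition simulation
# ---------------------------------------------------------------------------


class NoiseModel(str, Enum):
    poisson = "poisson"
    gaussian = "gaussian"


def default_detector_grid(lo_nm: float = 806.0, hi_nm: float = 1075.0,
                          step_nm: float = 0.2) -> np.ndarray:
    """Uniform detector wavelength grid covering 400-3200 cm^-1 for
    excitations between ~784 and ~798 nm."""
    n = int(round((hi_nm - lo_nm) / step_nm)) + 1
    return lo_nm + step_nm * np.arange(n)


@dataclass(frozen=True)
class AcquisitionConfig:
    excitation_nm: float = DEFAULT_EXCITATION_NM
    detector_grid_nm: np.ndarray = field(default_factory=default_detector_grid)
    noise: bool = True
    seed: int = 0
    noise_model: NoiseModel = NoiseModel.poisson

    def __post_init__(self):
        if self.excitation_nm <= 0:
            raise ValueError("excitation must be positive")


def _child_seed(master: int, index: int) -> int:
    """Stable per-frame seed derived from (master, frame index)."""
    return int(np.random.SeedSequence((int(master), int(index))).generate_state(1)[0]
               % (2**31))


def simulate_acquisition(bands: BandSet, fluor: FluorescenceModel | None,
                         cfg: AcquisitionConfig) -> Spectrum:
    """Simulate one detector frame.

    The Raman term is the band model evaluated at the Raman shift each
    detector pixel corresponds to *for this excitation*; the fluorescence
    term is evaluated directly in the wavelength frame and therefore does
    not move when the excitation is tuned.  With ``noise=True`` each pixel
    is an independent Poisson draw with mean equal to the noiseless counts.
    """
    grid_nm = np.asarray(cfg.detector_grid_nm, dtype=float)
    shift_frame = wavelength_to_raman_shift(grid_nm, cfg.excitation_nm)
    raman = np.sum([b.profile(shift_frame) for b in bands.bands], axis=0)
    if fluor is not None:
        reference = synth_pure_spectrum(bands)
        background = synth_fluorescence(fluor, reference, grid_nm).intensity
    else:
        background = np.zeros_like(raman)
    noiseless = raman + background
    if np.any(noiseless < 0):
        raise ValueError("negative expected counts")
    intensity = noiseless
    if cfg.noise:
        rng = np.random.default_rng(cfg.seed)
        if NoiseModel(cfg.noise_model) is NoiseModel.poisson:
            intensity = rng.poisson(noiseless).astype(float)
        else:
            intensity = noiseless + rng.standard_normal(noiseless.size) * np.sqrt(noiseless)
    return Spectrum(axis=grid_nm, intensity=intensity,
                    axis_kind=AxisKind.wavelength_nm, excitation_nm=None,
                    meta={"label": bands.label,
                          "acquisition_excitation_nm": cfg.excitation_nm,
                          "seed": cfg.seed, "noise": cfg.noise})


def simulate_serds_series(bands: BandSet, fluor: FluorescenceModel | None,
                          excitations_nm: list[float],
                          base_cfg: AcquisitionConfig,
                          power_factors: list[float] | None = None,
                          bleach_factor: float = 1.0) -> list[Spectrum]:
    """Simulate consecutive acquisitions at several excitation wavelengths.

    All frames share the detector grid of ``base_cfg``; frame *i* gets an
    independent child seed derived from the base seed.  ``power_factors``
    scales each frame's expected counts (laser-power variation between
    excitation settings); ``bleach_factor`` applies a cumulative factor
    ``bleach_factor**i`` emulating photobleaching of the sample over the
    acquisition sequence.
    """
    if len(excitations_nm) < 2:
        raise ValueError("a shifted-excitation series needs >= 2 excitations")
    if len(set(excitations_nm)) != len(excitations_nm):
        raise ValueError("duplicate excitation wavelengths")
    if power_factors is None:
        power_factors = [1.0] * len(excitations_nm)
    if len(power_factors) != len(excitations_nm):
        raise ValueError("one power factor per excitation required")
    out = []
    for i, exc in enumerate(excitations_nm):
        cfg = AcquisitionConfig(excitation_nm=exc,
                                detector_grid_nm=base_cfg.detector_grid_nm,
                                noise=False, seed=base_cfg.seed,
                                noise_model=base_cfg.noise_model)
        frame = simulate_acquisition(bands, fluor, cfg)
        scale = power_factors[i] * bleach_factor**i
        noiseless = frame.intensity * scale
        intensity = noiseless
        if base_cfg.noise:
            rng = np.random.default_rng(_child_seed(base_cfg.seed, i))
            if NoiseModel(base_cfg.noise_model) is NoiseModel.poisson:
                intensity = rng.poisson(noiseless).astype(float)
            else:
                intensity = noiseless + rng.standard_normal(noiseless.size) \
                    * np.sqrt(noiseless)
        out.append(frame.with_intensity(intensity, power_factor=power_factors[i],
                                        bleach=bleach_factor**i,
                                        noise=base_cfg.noise))
    return out


def series_to_reference_axis(series: list[Spectrum],
                             grid_cm1: np.ndarray | None = None,
                             reference_excitation_nm: float = DEFAULT_EXCITATION_NM
                             ) -> list[Spectrum]:
    """Calibrate a wavelength-frame series onto one common Raman-shift grid
    relative to the reference excitation (the co-registration every
    difference computation requires)."""
    from .spectral_core import resample_to_grid, to_raman_shift_axis

    if grid_cm1 is None:
        grid_cm1 = canonical_grid()
    return [resample_to_grid(to_raman_shift_axis(s, reference_excitation_nm), grid_cm1)
            for s in series]
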