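# Methods

This note documents the models, conventions and numerical choices behind
`serdslab`, and what the synthetic studies can and cannot show about
measured tissue data.

## Frames and the canonical axis

Two frames coexist. The **detector frame** is absolute wavelength λ (nm);
the **Raman-shift frame** is ν̃ = 10⁷(1/λ_exc − 1/λ) cm⁻¹ relative to a
stated excitation. Raman features are fixed in the shift frame *of their
own excitation*; fluorescence is fixed in the wavelength frame. All
processing happens on one canonical axis: Raman shift relative to 785.0 nm,
uniform from 400 to 3200 cm⁻¹ in 2 cm⁻¹ steps. The 2 cm⁻¹ step is finer
than a typical dispersive instrument's ~9 cm⁻¹ resolution so that the
smallest experimental excitation step (0.5 nm ≈ 8 cm⁻¹) is not discretised
away; a 0.5 nm shift is 4 grid points. Wavelength-frame acquisitions are
relabelled to the 785-relative axis and linearly interpolated onto the
canonical grid (cubic available); linear interpolation is exact on affine
profiles and converges quadratically on smooth bands.

The displacement of Raman bands on a common reference axis under an
excitation change λ₁→λ₂ is 10⁷(1/λ₁ − 1/λ₂); at 785 nm, 1 nm ≈ 16 cm⁻¹.

## Synthetic data generator

The generator emulates shot-noise-limited biochemical Raman acquisitions:

* **Band sets.** Four versioned fixtures (lipid-, protein-, collagen-,
  bone-like) built from standard Raman assignments, each a sum of Gaussian
  profiles with amplitudes relative to a 1000-count strongest band.
  Bandwidths are deliberately heterogeneous (10–85 cm⁻¹, including a broad
  CH-stretch envelope at 2800–3100 cm⁻¹), because that spread is what
  invalidates the FWHM shift rule. The fixtures reproduce the qualitative
  structure of tissue component spectra, not any measured sample.
* **Fluorescence.** A smooth polynomial in the *wavelength* frame; the
  default is a concave cubic peaking near 950 nm with a 15% pedestal.
  Its height is set as a multiple (default 5; studies use 0/5/8/10) of the
  strongest Raman band, matched exactly on the evaluation grid. Because it
  is parameterised in wavelength, it is bitwise identical across excitation
  settings — the idealised SERDS asymmetry. Real fluorophores can respond
  to multi-nm excitation changes; that effect is not modelled.
* **Noise.** Each pixel draws independently from Poisson(mean = noiseless
  counts), so σ = √I; a Gaussian N(I, I) approximation is available.
  Detector read noise, etaloning, ambient light and cosmic rays are not
  simulated (a despiking utility handles injected spikes in tests).
* **Series.** One frame per excitation on a shared detector grid
  (806–1075 nm, 0.2 nm pixels), with per-frame seeds derived from the
  master seed via `SeedSequence((master, frame_index))`. Optional per-frame
  power factors and a cumulative bleach factor (frame *i* scaled by
  bleach^i) emulate laser-power variation and photobleaching; both scale
  the whole expected-count trace.

What passing tests on this generator show: the algebraic and statistical
behaviour of the methods under exactly the stated noise model. What they
do not show: robustness to wavelength-calibration error, detector
nonlinearity, fluorescence that tracks excitation, or band shapes outside
the Gaussian/Lorentzian family.

## Difference processing

Pairs are co-registered on the canonical axis, oriented so s1 is the
longer-excitation frame. Methods: raw S₁−S₂; area normalisation (each
spectrum scaled to unit sum); z-score/SNV (mean 0, SD 1; population SD by
default, sample SD behind `ddof=1`, the convention recorded in metadata);
and subtraction optimisation, x* = argmin AUC(|S₁ − x·S₂|). The AUC is a
trapezoid on the axis, making the objective grid-density invariant. The
objective is a nonnegative combination of |aᵢ − x·bᵢ| terms and hence
convex in x; a 200-point pre-scan over [0.2, 5] brackets the minimum and a
bounded scalar search refines it to 1e−6. Residual smooth background in a
difference spectrum is removed by a polynomial (degree ≤ 7) fitted to
off-band pixels; band windows for the exclusion are detected on
|difference| with deliberately generous half-widths (80 cm⁻¹), since band
tails leaking into the fit bias it more than lost off-band pixels.

## Shift selection

The autocorrelation is the biased (1/n) normalised sample acf of the
mean-centred intensities, so acf(0) = 1 exactly; an unbiased variant is
flagged. Candidate shifts in nm are converted to a displacement at the
reference excitation and rounded to the nearest integer lag of the uniform
grid (the wavenumber displacement varies slightly across the spectrum; the
single-number conversion matches how shifts are quoted in practice).
The optimal shift maximises 1 − acf over the scanned range, capped at
12.6 nm — beyond that, real fluorescence profiles cannot be assumed
stationary and tunable sources/filters become impractical. The retained
signal fraction AUC(|D|)/(2·AUC(|S|)) is 0 at zero shift and 1 at complete
band separation. On noisy differences the numerator includes a noise
pedestal, so the noisy estimate is upward-biased and can exceed 1; ordering
comparisons are made within matched noise conditions.

## SNR evaluation

SNR is computed from the *noiseless* signal/background decomposition, as
appropriate for simulations; estimating SNR from a single noisy trace is
out of scope. Band windows come from the Savitzky–Golay second derivative
of the noiseless spectrum: peaks of −d²/dν̃² above 5% of its global
maximum, expanded ±5 grid points and merged. Both defaults are package
choices; the curvature threshold suppresses shoulders below a few percent
of the strongest band. The band-averaged SNR is the mean per-pixel SNR
over the union of windows — off-band regions are excluded before
averaging.

For the matched-time comparison the conventional measurement doubles both
signal and background (2S/√(2S+2F)); only with fluorescence scaling with
time does the closed-form ratio ½|1 − S₂/S₁| follow algebraically. The
variant that doubles only the signal is available behind
`fluorescence_scales_with_time=False` and is documented as inconsistent
with the closed form. The total (region-summed) difference-spectrum SNR
uses that closed form over a region of interest with S₁ ≥ 1; the dominance
statement (total SERDS SNR < total Raman SNR at any positively
autocorrelated shift) is evaluated over detected band windows. Over an
unrestricted region containing near-empty pixels the closed form can
exceed the conventional total, because it divides by the conventional
measurement's noise rather than the difference measurement's own.

## EMSC

The design matrix holds 7 background columns — constant, min-max-scaled
linear term, and five fluorescence shapes (default: powers 2–6 of the
scaled axis, i.e. a full degree-6 polynomial basis together with the first
two columns; measured shapes can be substituted) — plus pure-component
spectra. Coefficients come from an SVD least-squares solve (condition
number reported; optional ridge damping); rank deficiency raises an error
naming the collinear columns. Only the fitted background part is
subtracted: the correction is additive, with the classic multiplicative
rescaling by a reference coefficient behind a flag, since plain background
subtraction is the variant under study. The polynomial background basis
absorbs the wavelength-frame fluorescence re-expressed on the wavenumber
axis (a smooth rational transform) to well below the shot-noise floor.

## Study runners

`run_simulation_study` (single location): band-averaged SNR at
fluorescence scales 0/5/8/10; the 1−acf scan to 12.6 nm; noiseless
difference spectra at 1/2/4 nm with retained fractions; EMSC on a noisy
scale-5 acquisition; and a matched-time SNR comparison of EMSC versus
optimised SERDS.

`run_experiment_study` (image emulation): a 400-point grid of four tissue
classes (100 points each, ±20% amplitude jitter), five excitations
784–786 nm in 0.5 nm steps with ±5% frame-to-frame power drift and 1%
photobleaching per frame, Poisson noise throughout. Per point: difference
spectra at 0.5/1/1.5/2 nm against the 786 nm frame under all four methods,
scored by off-band/on-band RMS ratio (scale-free across methods); EMSC on
the 785 nm frame; area normalisation and Ward/Euclidean hierarchical
clustering into 4 clusters. Tests run the study at 40 points, which is
ample for the ordering assertions it supports.

All randomness flows from a single master seed; reports are
JSON-serialisable and bit-reproducible for a fixed seed.

## Known limitations

* The fixtures are qualitative stand-ins; absolute quantities (mean band
  SNRs, retained percentages, the exact nm position of the information
  optimum) depend on the band table and are not claims about any measured
  sample — only orderings and closed-form identities are asserted.
* Reconstruction of a conventional spectrum from a difference spectrum
  (integration/deconvolution) is not implemented.
* EMSC with spatially varying, multi-fluorophore backgrounds is supported
  only to the extent of supplying multiple shape columns.
* Vendor binary formats are not read; the I/O dialect is plain CSV with a
  one-line header.
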