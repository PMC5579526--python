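# serdslab

Fluorescence backgrounds are the main obstacle to Raman spectroscopy of
biological tissue: auto-fluorescence can exceed the Raman bands by an order
of magnitude, and in a shot-noise-limited measurement its Poisson noise
(σ = √counts) buries them. `serdslab` is a toolbox for studying and
comparing the two standard remedies on equal footing:

* **SERDS** (shifted excitation Raman difference spectroscopy), an
  instrumental method: acquire two spectra at slightly different excitation
  wavelengths and subtract them. Raman bands move with the excitation,
  fluorescence does not, so the difference cancels the background.
* **EMSC** (extended multiplicative signal correction), a computational
  method: least-squares fit of background components (constant, linear,
  smooth fluorescence shapes) plus pure-component reference spectra, then
  subtraction of the fitted background part only.

The package provides a shot-noise-limited simulator of multi-excitation
tissue-like acquisitions, the four difference-processing variants (raw
subtraction, area normalisation, z-score/SNV normalisation, subtraction
optimisation), an autocorrelation-based criterion for choosing the
excitation shift, the SNR theory of difference spectra, EMSC correction,
and end-to-end study runners with despiking and hierarchical clustering.

## The core quantities

With Raman signal *S* and fluorescence *F* (counts), the per-pixel
shot-noise-limited SNRs are

    SNR_Raman(i) = S(i) / √(S(i) + F(i))
    SNR_SERDS(i) = |S₁(i) − S₂(i)| / √(S₁(i) + F₁(i) + S₂(i) + F₂(i))

— the difference subtracts signal but adds noise in quadrature. At matched
total acquisition time (one conventional spectrum integrated as long as
both shifted frames together) the ratio has the closed form

    SNR_SERDS / SNR_Raman = ½ · |1 − S₂/S₁|,

so wherever the shifted copy overlaps its original (S₂ ≤ S₁) the difference
spectrum loses at least half the SNR. Summed over the band regions, the
difference-spectrum SNR is strictly below the conventional one whenever the
spectrum is positively autocorrelated at the shift lag.

The excitation shift itself is chosen by the information criterion

    Δλ* = argmax [ 1 − acf(lag(Δλ)) ],

the shift minimising the spectrum's overlap with its shifted copy, rather
than the classic "one band FWHM" rule — biochemical spectra contain
bandwidths from ~10 cm⁻¹ (phenylalanine ring breathing) to ~90 cm⁻¹ (CH
stretch envelope), so no single FWHM exists. The companion diagnostic is
the retained signal fraction AUC(|D|) / (2·AUC(|S|)) of a difference
spectrum D.

## Worked example

```python
import numpy as np
import serdslab as sl

# noiseless lipid-like pure spectrum on the canonical 785 nm-relative grid
pure = sl.synth_pure_spectrum(sl.lipid_like_fixture())

# information scan over candidate excitation shifts
scan = sl.shift_scan(pure, np.arange(0.0, 12.61, 0.2), excitation_nm=785.0)
print(f"optimal shift: {scan.optimal_shift_nm:.1f} nm "
      f"({scan.optimal_shift_cm1:.0f} cm^-1)")

# shot-noise-limited series with a 5x fluorescence background and a 5%
# laser-power drop on the last frame
fl = sl.default_fluorescence(scale=5.0)
series = sl.simulate_serds_series(
    sl.lipid_like_fixture(), fl, [784.0, 785.0, 786.0],
    sl.AcquisitionConfig(noise=True, seed=7),
    power_factors=[1.0, 1.0, 0.95])
reg = sl.series_to_reference_axis(series)

pair = sl.SerdsPair(s1=reg[2], s2=reg[0])      # 786 minus 784 nm
res = sl.serds_difference(pair, "subopt")
print(f"subtraction factor x* = {res.opt_factor:.4f}")

# EMSC correction of the 785 nm frame
grid = reg[1].axis
pure_cols = [sl.synth_pure_spectrum(sl.fixture_by_label(lb), grid)
             for lb in ("collagen", "protein", "lipid", "bone")]
fit = sl.emsc_fit(reg[1], sl.build_design(grid, pure_cols))
print(f"EMSC lipid coefficient: {fit.coefficient('lipid-like'):.3f}")

report = sl.snr_report(pure)
print(f"mean band SNR without background: {report.mean_band_snr:.1f} "
      f"over {len(report.band_windows)} bands")
```

prints

```
optimal shift: 12.2 nm (195 cm^-1)
subtraction factor x* = 0.9508
EMSC lipid coefficient: 1.021
mean band SNR without background: 21.4 over 9 bands
```

The shift scan places the information optimum at 195 cm⁻¹ — an order of
magnitude above the narrowest band's FWHM. The subtraction optimiser
recovers the simulated 5% power drop (x* ≈ 0.95), restoring background
cancellation that plain subtraction loses. EMSC recovers the simulated
lipid amplitude (coefficient ≈ 1) under a background five times the
strongest band plus Poisson noise.

A command-line interface mirrors the library
(`serdslab simulate|serds|shiftscan|snr|emsc|run-sim|run-exp`); see
`serdslab --help`.

## Layout

| module | contents |
| --- | --- |
| `spectral_core` | axis conventions, nm↔cm⁻¹ conversions, resampling, rubberband (convex-hull) baseline, Savitzky–Golay filters |
| `synthetic_data` | band-set fixtures, fluorescence models, Poisson acquisition and series simulation |
| `serds_processing` | difference methods: raw, area, z-score/SNV, subtraction optimisation; residual polynomial cleanup |
| `shift_selection` | autocorrelation, 1−acf shift scan, retained signal fraction |
| `snr_eval` | per-pixel and band-averaged shot-noise SNR, difference-spectrum SNR theory, band detection |
| `emsc` | EMSC design matrix, least-squares fit, background subtraction, derivative view |
| `pipeline` | despiking, hierarchical clustering, simulation and image study runners |
| `io` | plain-text CSV spectrum dialect |
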