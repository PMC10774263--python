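"""Fit one cell-like point spectrum and compute its metabolic ratios.

Builds a synthetic power-normalized OPTIR spectrum (protein + total lipid +
azide-tagged lipid), masks the peak-free 1780-2030 cm^-1 gap, detects peaks by
smoothed second derivatives, fits the whole spectrum, and prints the fitted
band areas and the two per-cell metrics.
"""

from optirlipid import (
    cell_metrics,
    detect_peaks,
    fit_spectrum,
    make_spectrum,
    mask_silent_gap,
)

# weights: protein 1.0, total lipid 0.5, and 25% of that lipid azide-tagged
spectrum, truth = make_spectrum(
    {"protein": 1.0, "total_lipid": 0.5, "azide": 0.125},
    noise_sd=0.005,
    seed=1,
)
spectrum = mask_silent_gap(spectrum)

seeds = detect_peaks(spectrum)
fit = fit_spectrum(spectrum, seeds)
record = cell_metrics(fit, sample="demo", cell_id="001", n_spectra=1)

print(f"peak candidates (cm^-1): {[round(c) for c in seeds]}")
for band in ("amide_I", "lipid_carbonyl", "azide"):
    print(
        f"{band:>15}: fitted area {fit.areas[band]:8.3f}"
        f"   (true {truth['band_areas'][band]:8.3f})"
    )
print(f"normalized total lipid (1740/1650): {record.norm_total_lipid:.3f}")
print(f"new lipid fraction     (2096/1740): {record.new_lipid_fraction:.3f}")
print(
    "-> about half the dry mass signal is lipid, and a quarter of that lipid "
    "pool was synthesized after the azide-tagged fatty acid was supplied"
)
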