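# Methods

This note documents the models, conventions and numerical choices behind
`optirlipid`, and what the synthetic phantoms do and do not emulate.

## Data model and conventions

Spectra are wavenumber-indexed intensity traces on a strictly increasing axis
inside 900–2400 cm⁻¹ (the instrument's fingerprint plus cell-silent coverage);
channel images are single-wavenumber rasters with a pixel size in µm. Pixel
coordinates are 0-based `(row, col)` with pixel centres at
`(i + 0.5) · pixel_size` — needed for unambiguous distance and line-profile
math. Delimited text is sniffed among comma/tab/semicolon (comma canonical on
output); duplicate wavenumbers collapse by mean on read. Undefined metric
values are written as empty CSV fields, never sentinel numbers, so they cannot
silently propagate into ratios.

Band definitions live in one `BandLibrary`: amide-I 1654 ± 20, lipid carbonyl
1742 ± 22 (the ester C=O band is quoted at both 1740 and 1744 cm⁻¹ depending
on acquisition; one window covers both), azide 2096 ± 30, plus secondary bands
(amide-II 1550, C–H bend 1473, C–O–C 1170, free-acid carbonyl 1700). The three
quantification windows must not overlap — enforced at construction. The
1780–2030 cm⁻¹ range contains no observable bands and is excluded from fitting
and display (`mask_silent_gap`); the data are retained, not deleted.

## Preprocessing

The fixed order is: divide by the IR laser power spectrum (linearly
interpolated onto the spectrum's axis; non-positive power is an error, never a
silent divide), divide by the linearly interpolated intensity at exactly the
amide-I anchor (1654 cm⁻¹), then average ≥ 3 pinpoint spectra per cell.
Normalize-then-average is pinned by a regression test because the reverse
order weights cells by absolute signal. Linear interpolation is used for both
power and anchor lookup as the minimal assumption. The anchor uses the
interpolated value at 1654 cm⁻¹, not a local maximum: display normalization
and fitting-based quantification are deliberately separate, and the metric
ratios use fitted component areas only. Negative intensities after power
normalization are retained — the fitted baseline absorbs them; clamping would
bias areas. Images divide by the power at their wavenumber.

## Peak detection and whole-spectrum fitting

Candidate centres are local minima of a Savitzky–Golay second derivative
(default window 11 points, polynomial order 3) whose depth exceeds
`prominence_frac` (default 0.05) of the strongest minimum. A band appears as a
negative second-derivative dip regardless of a slowly varying baseline, which
is why detection runs on the second derivative rather than the raw trace.
Defaults are config-exposed and pinned in tests.

The whole spectrum is then fitted jointly — a global linear baseline plus one
component per seed — by bounded trust-region least squares
(`scipy.optimize.least_squares`, xtol = ftol = gtol = 1e-10, deterministic for
identical inputs). Centres are bounded to seed ± 10 cm⁻¹, which prevents the
azide component drifting into the masked gap; FWHMs to [2, 200] cm⁻¹;
amplitudes to ≥ 0. The default lineshape is Gaussian (closed-form area
`amplitude · fwhm · √(π/4 ln 2)`; condensed-phase mid-IR bands in this range
are close to Gaussian); Lorentzian and pseudo-Voigt (mixing η, area
`η·Lorentzian + (1−η)·Gaussian`) are available by configuration. Areas map to
band names when the fitted centre falls inside a band window; if two
components land in one window the larger area wins and a fit-quality warning
is recorded. A band with no component is *absent* (`None`), distinct from a
fitted zero amplitude — absent denominators make metrics undefined rather than
infinite. Duplicate seeds (< 1 cm⁻¹ apart) are deduplicated with a warning.

Spatial resolution is estimated by fitting Gaussian + constant offset to a
line profile across a sub-resolution droplet; FWHM = 2√(2 ln 2)·σ. The
estimate is invariant to additive offsets and axis reversal, requires ≥ 7
samples, and refuses profiles whose fitted width exceeds the sampled span.

## Metrics

`norm_total_lipid = A(carbonyl)/A(amide-I)` and
`new_lipid_fraction = A(azide)/A(carbonyl)`. An absent azide band is treated
as a measurable zero by default (`absent_as_zero`), because untagged controls
genuinely contain no azide; the flag is configurable and the absence is always
recorded. An absent or non-positive amide-I area refuses the record — there is
nothing to normalize by.

Photothermal estimates: modulation depth `m = V_AC/(gain · V_DC)` and
transient temperature rise `ΔT = m/κ` with κ the relative scattering-intensity
change per kelvin (default 10⁻³/K). Values are reported to 2 significant
figures (`round_sig`) while full precision is retained internally. The
direct-IR tuning penalty is the ratio of the extreme tuning wavelengths
(10.6/4.3 µm ≈ 2.5); OPTIR's resolution is set by the fixed visible probe.

Limit of detection: the calibration line is constrained through the blank
mean — `slope = Σ c·(a − ā_blank) / Σ c²` over non-zero concentrations — and
`LoD = k·σ_blank/slope` with the standard analytical k = 3 (3.3 selectable for
the ICH convention). A non-positive slope is a calibration error.

Depth profiles: each positioned spectrum gets the Euclidean
distance-transform depth of its pixel, `(EDT − 0.5)·pixel_size`, i.e. distance
from the pixel centre to the tissue/background interface taken midway between
pixel centres. This makes boundary pixels ~0 and the centre of a 1000 µm
square ~500 µm, exact to half a pixel — the inherent raster discretization.
The azide area per spectrum defaults to the fitted component area, with a
raw-trapezoid option (local linear baseline across the azide window) for
fit-free integration.

## Imaging

Ratio images divide two power-normalized channels where the denominator
exceeds `threshold_frac` (default 0.05) of its maximum — an explicit,
config-exposed stand-in for however vendor software guards near-zero
denominators. Per-cell means run over valid pixels only; cells with fewer than
`min_valid_pixels` (default 10) valid pixels are reported undefined.
Histogram subpopulation analysis bins valid pixels (Freedman–Diaconis by
default) and fits one or two Gaussians to the counts; the caller chooses the
component count — no automatic model selection. Two-component initial centres
come from a deterministic 1-D two-means split (percentile initialization,
Lloyd updates), so results are seed-free and repeatable. Line profiles use
bilinear interpolation (nearest-neighbour available for bit-exact sampling);
`droplet_line_profile` snaps to pixel centres and samples one value per pixel
so resolution estimates see the raw scan line without interpolation
smoothing. An Otsu + connected-components helper provides convenience masks
for phantoms; real analyses use externally drawn ROI masks, and no automatic
segmentation is claimed.

## Statistics

Group comparisons use the classical Student (pooled-variance) two-sided
two-sample t-test — Welch by flag, and the variant used is recorded in the
result metadata — or the two-sided paired t-test on differences. Identical
paired samples (zero-variance, zero-mean differences) report t = 0, p = 1
instead of an undefined statistic. α = 0.05 travels with every result and is
never applied silently. Box summaries use type-7 (linear-interpolation)
quartiles — stated because the outlier set depends on the convention —
whiskers at the min/max of non-outliers, outliers beyond 1.5×IQR. No
multiple-testing correction is applied; comparisons here are single per-figure
tests. Pearson colocalization resamples the finer grid onto the coarser by
nearest neighbour, then correlates ROI pixels; zero variance in a channel
returns NaN with a warning. Raw intensities are used, with no background
subtraction.

## Synthetic phantoms

The component library builds protein (amide-I 1654, amide-II 1550), total
lipid (1744, 1473, 1170), azide (2096) and free palmitic-acid (1700, 1473)
spectra as Gaussian bands of 25 cm⁻¹ FWHM, each normalized to unit maximum, on
the default 980–2300 cm⁻¹ axis at 2 cm⁻¹ spacing (661 points) matching the
instrument scan range. All non-probe components contribute < 10⁻⁶ of their
maximum inside 2000–2320 cm⁻¹, preserving the cell-silent property.

Cell-image phantoms lay anti-aliased disks (nucleus: protein-rich; cytoplasm:
protein plus low lipid background; droplets: lipid-rich with per-cell azide
fraction) on a supersampled grid (odd supersampling factor, so detector pixel
centres coincide with fine-grid centres), convolve with a Gaussian PSF
(default FWHM 0.5 µm, wavenumber-independent — the probe beam sets OPTIR
resolution; a direct-IR emulation can vary it), and *point-sample* at detector
pixel centres, matching raster-scan acquisition rather than integrating
detector pixels. Noise is additive Gaussian; `noise_snr` is each channel's
post-PSF peak amplitude over the noise σ, the definition under which a stated
SNR describes the imaged channel itself. Real OPTIR noise is likely mixed
multiplicative/additive; without a characterization, additive Gaussian is the
documented stand-in. Ground truth (PSF-free weight maps on the detector grid,
cell labels, droplet geometry, per-cell true ratios) is emitted alongside, and
the stored per-cell truths are recomputed from the emitted weight maps so they
can never drift apart. The resolution phantom uses an isolated, fully tagged
droplet with no cytoplasmic lipid: a PSF-width measurement needs the droplet
to be the only structure on the profile.

Organoid phantoms are 2-D disc sections (matching 10-µm cryosections) with
azide weight `exp(−depth/decay_length)` (default decay length 300 µm, which
keeps the signal detectable ~700 µm from the surface) and uniform
protein/lipid; point spectra are drawn at fixed depths along a radius with a
`location` grouping key. Dilution series are linear in concentration with
Gaussian noise; the defaults (slope 10⁻³ area/µM, σ chosen so 3σ/slope =
100 µM) sit at the scale of the solvent LoD measurement. Six blank replicates
are generated by default: with the minimum three, the sample SD of the blank
is biased ~11 % low (E[s] = c₄σ, c₄(3) = 0.886), which would consume most of a
recovery budget by construction rather than by estimation noise.

Everything is seed-deterministic: identical seed and configuration give
bit-identical outputs, and the pipeline splits all randomness from one root
seed.

## What passing tests do and do not show

The phantoms share the analysis' structural assumptions: Gaussian bands at
known centres, linear mixing, additive noise, a shift-invariant Gaussian PSF,
exponential penetration. Recovery on them validates the estimators'
correctness and calibration — not robustness to lineshape misspecification,
water-vapour residuals, scattering baselines, focus drift, or segmentation
errors, none of which the generator emulates. Problem sizes in the test suite
and acceptance script (tens of cells, 20-µm to 60-µm fields, 2000-replicate
null calibrations) are chosen as the smallest sizes at which the statistical
claims are meaningful.

## Known limitations

Per-pixel full-spectrum fitting of hyperspectral cubes is out of scope (point
spectra plus single-wavenumber images are the supported acquisition modes).
No image registration beyond same-grid resampling is performed. The exact
smoothing/prominence settings of the original interactive peak analysis are
not reconstructable; the defaults here are explicit, config-exposed choices.
Absolute intracellular concentrations are not calibrated — the metrics are
ratios, and the LoD applies to the solvent calibration geometry.
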