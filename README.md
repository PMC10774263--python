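# optirlipid

Single-cell lipid-metabolism quantification for optical photothermal infrared
(OPTIR) microscopy with a bioorthogonal azide probe.

## The problem

OPTIR microscopy reads out mid-IR absorption through the photothermal
modulation of a visible probe beam, giving vibrational contrast at
sub-micrometre resolution. When cells are fed an azide-tagged palmitic acid,
the azide stretch (~2096 cm⁻¹) falls in the *cell-silent* spectral region
(1800–2800 cm⁻¹) where endogenous biomolecules do not absorb, so every azide
photon marks lipid synthesized after the probe was supplied. Combining that
band with the ester-carbonyl band of total lipids (~1740–1744 cm⁻¹) and the
amide-I band of protein (~1654 cm⁻¹) turns single-point spectra and
single-wavenumber images into per-cell metabolic readouts — in cultured cells,
stem-cell-derived microglia, and brain-organoid sections.

`optirlipid` is the analysis side of such experiments: it converts raw OPTIR
exports (two-column spectra, single-wavenumber TIFFs, IR power curves, label
masks) into fitted band areas, per-cell metrics, ratio images, colocalization
and group statistics. A synthetic phantom generator with exported ground truth
makes every stage testable without an instrument.

## The quantities it computes

For each cell, point spectra are IR-power normalized, normalized to the
protein content at the amide-I anchor (1654 cm⁻¹), averaged (≥ 3 pinpoint
spectra), and decomposed by whole-spectrum fitting into baseline plus Gaussian
bands found with smoothed second derivatives. The fitted areas A give

- **normalized total lipid** = A(1740) / A(1650) — total lipid per unit
  protein, robust to focus and biomass variation;
- **newly synthesized lipid fraction** = A(2096) / A(1740) — the share of the
  lipid pool carrying the azide tag.

Both ratios are invariant to any positive rescaling of the raw spectrum.
Image analysis mirrors this per pixel: the 2096/1744 ratio image (masked where
the denominator is near zero) is averaged over cell ROIs or decomposed into
subpopulations by Gaussian histogram fits. The package also computes Pearson
colocalization between OPTIR and fluorescence channels, two-sided two-sample
and paired t-tests with 1.5×IQR box summaries, the 3σ limit of detection from
a dilution series (LoD = 3σ_blank / slope), probe-penetration depth profiles
via the Euclidean distance to the tissue surface, and the photothermal
estimates m = V_AC / (gain · V_DC) and ΔT = m / κ.

## Worked example

`examples/01_fit_point_spectrum.py` builds a noisy cell-like spectrum with
known composition (protein 1.0, total lipid 0.5, a quarter of it tagged),
fits it, and prints:

```
peak candidates (cm^-1): [1170, 1472, 1550, 1654, 1744, 2094]
        amide_I: fitted area   26.616   (true   26.612)
 lipid_carbonyl: fitted area   13.363   (true   13.306)
          azide: fitted area    3.398   (true    3.326)
normalized total lipid (1740/1650): 0.502
new lipid fraction     (2096/1740): 0.254
```

The detected candidates are the five component bands plus the azide band in
the cell-silent region; the fitted areas match the generating truth, and the
two ratios recover the built-in composition (0.5 lipid per protein, 25 % of
lipid newly synthesized). The other examples cover spatial-resolution
estimation from a sub-resolution droplet (`02`), ratio-image quantification
and histogram subpopulations (`03`), LoD calibration (`04`), organoid depth
profiles (`05`), and the end-to-end two-condition pipeline with statistics
(`06`). Each prints the numbers it computes and one line on what they mean.

A thin CLI wraps the same functions (`optirlipid simulate|preprocess|
fit-spectra|quantify|ratio-image|cell-quant|histogram|profile|coloc|compare|
lod|depth|run`), configured by `--config file.yaml` with
`--set section.key=value` overrides.

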