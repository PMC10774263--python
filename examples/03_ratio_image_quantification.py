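"""Ratio imaging and per-cell quantification on a two-population phantom.

Four phantom cells, two with a true newly-synthesized-lipid fraction of 0.3
and two with 0.6, are imaged at the azide (2096 cm^-1) and lipid-carbonyl
(1744 cm^-1) wavenumbers. The per-pixel ratio image recovers the fraction;
per-cell means and a two-Gaussian histogram fit separate the populations.
"""

from optirlipid import (
    CellPhantomSpec,
    cell_mean_ratio,
    histogram_subpopulations,
    make_cell_image,
    ratio_image,
)

spec = CellPhantomSpec(
    fov_um=60.0,
    n_cells=4,
    cell_radius_um=6.0,
    new_lipid_fraction=(0.3, 0.3, 0.6, 0.6),
)
images, truth = make_cell_image(spec, pixel_size_um=0.5, noise_snr=100.0, seed=11)

ratio = ratio_image(images["azide"], images["lipid_carbonyl"], threshold_frac=0.05)
means = cell_mean_ratio(ratio, truth.cell_mask)
hist = histogram_subpopulations(ratio, n_components=2)

print("per-cell mean 2096/1744 ratio (truth in parentheses):")
for cell_id, mean in sorted(means.items()):
    true = truth.cell_truths[cell_id]["new_lipid_fraction"]
    print(f"  cell {cell_id}: {mean:.3f}  ({true:.1f})")
print(
    "histogram subpopulation centers: "
    + ", ".join(f"{c:.3f}" for c in hist.centers)
)
print(
    "-> pixels pool into two populations whose centers match the two true "
    "fractions; cells of the high-fraction condition synthesize twice the "
    "share of new lipid"
)
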