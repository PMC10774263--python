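"""Estimate spatial resolution from a sub-resolution phantom droplet.

A 100-nm-radius fully tagged lipid droplet is far below the instrument's
~0.5 um point spread function, so a line profile across it measures the PSF
itself. A Gaussian + offset fit to the profile gives the FWHM that is quoted
as the imaging resolution.
"""

import numpy as np

from optirlipid import (
    droplet_line_profile,
    fwhm_line_profile,
    make_resolution_phantom,
)

fwhms = []
for seed in range(1, 11):
    image, center = make_resolution_phantom(
        seed=seed, droplet_radius_um=0.1, pixel_size_um=0.1, noise_snr=50.0
    )
    positions, values = droplet_line_profile(image, center, half_width_px=15)
    fwhms.append(fwhm_line_profile(positions, values))

print(f"per-replicate FWHM (nm): {[round(f * 1000) for f in fwhms]}")
print(f"mean FWHM: {np.mean(fwhms) * 1000:.0f} nm (PSF FWHM set to 500 nm)")
print(
    "-> the fitted width slightly exceeds the PSF because the droplet has a "
    "finite 200-nm diameter; both numbers say sub-micrometre resolution"
)
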