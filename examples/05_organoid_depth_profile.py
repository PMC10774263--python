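"""Probe-penetration depth profile in an organoid section phantom.

The azide-tagged fatty acid reaches a 3-D culture from its surface, so the
azide signal decays with depth. Point spectra taken at increasing distance
from the tissue edge are fitted and the azide band area is plotted against
the Euclidean distance to the surface; an exponential fit recovers the
penetration decay length.
"""

import numpy as np
from scipy.optimize import curve_fit

from optirlipid import depth_profile, make_organoid_phantom

phantom = make_organoid_phantom(
    radius_um=600.0,
    decay_length_um=300.0,
    seed=2,
    pixel_size_um=5.0,
    n_locations=5,
    spectra_per_location=3,
    noise_sd=0.003,
)
profile = depth_profile(phantom.spectra, phantom.tissue_mask)

popt, _ = curve_fit(
    lambda d, a, length: a * np.exp(-d / length),
    profile.distances_um,
    profile.mean_areas,
    p0=[profile.mean_areas[0], 200.0],
)

print("distance from surface (um) -> mean azide area +/- sd:")
for d, m, s in zip(profile.distances_um, profile.mean_areas, profile.sd_areas):
    print(f"  {d:7.1f} -> {m:6.3f} +/- {s:.3f}")
print(f"fitted decay length: {popt[1]:.0f} um (generated with 300 um)")
print(
    "-> newly synthesized lipid concentrates near the surface and decays "
    "exponentially toward the core, as expected for diffusion-limited uptake"
)
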