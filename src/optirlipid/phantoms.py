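"""Synthetic phantoms with exported ground truth.

Every analysis stage in this package can be exercised without instrument data
through the generators here: mixture point spectra built from a component
library (protein / total lipid / azide probe), cell-shaped channel images with
nuclei, cytoplasm and lipid droplets blurred by a Gaussian instrument PSF,
organoid sections with an exponential probe-penetration depth gradient, and
dilution series for limit-of-detection calibration.

Emulated features of real data: the 980-2300 cm^-1 scan axis, the cell-silent
region where only the azide probe absorbs, the ~0.5 um FWHM spatial
resolution, IR-power wavelength dependence, raster-scan point sampling and
additive detection noise. Not emulated: photothermal signal physics (heat
diffusion, scattering), water-vapour lines, and any multiplicative noise.

All generators are seed-deterministic: identical seed and configuration give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import FormatError, GeometryError
from .formats import (
    BandLibrary,
    ChannelImage,
    LabelMask,
    PowerSpectrum,
    Spectrum,
)
from .metrics import DilutionSeries, distance_to_surface
from .peakfit import GAUSS_AREA_FACTOR

#: default scan axis: 980-2300 cm^-1 at 2 cm^-1 spacing (661 points)
DEFAULT_AXIS = np.arange(980.0, 2300.0 + 1e-9, 2.0)

#: default per-component peak tables: (centre cm^-1, relative amplitude)
COMPONENT_PEAKS: dict[str, tuple[tuple[float, float], ...]] = {
    "protein": ((1654.0, 1.0), (1550.0, 0.65)),
    "total_lipid": ((1744.0, 1.0), (1473.0, 0.35), (1170.0, 0.45)),
    "azide": ((2096.0, 1.0),),
    "pa_powder": ((1700.0, 1.0), (1473.0, 0.5)),
}

#: channel wavenumbers at which phantom images are "acquired"
CHANNEL_WAVENUMBERS: dict[str, float] = {
    "amide_I": 1654.0,
    "lipid_carbonyl": 1744.0,
    "azide": 2096.0,
}


def _gauss(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    return np.exp(-4.0 * math.log(2.0) * ((x - center) / fwhm) ** 2)


@dataclass
class ComponentLibrary:
    """Reference spectra of the spectral components, unit maximum each.

    Components are sums of Gaussian bands (default FWHM 25 cm^-1) from
    :data:`COMPONENT_PEAKS`, normalized so each component's maximum on the
    axis is 1. Closed-form band areas of the normalized components are
    available through :meth:`true_band_area`.
    """

    axis: np.ndarray = field(default_factory=lambda: DEFAULT_AXIS.copy())
    fwhm: float = 25.0
    peaks: dict[str, tuple[tuple[float, float], ...]] = field(
        default_factory=lambda: dict(COMPONENT_PEAKS)
    )

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.components: dict[str, np.ndarray] = {}
        self._norm: dict[str, float] = {}
        for name, table in self.peaks.items():
            spec = np.zeros_like(self.axis)
            for center, rel in table:
                spec += rel * _gauss(self.axis, center, self.fwhm)
            peak = float(spec.max())
            if peak <= 0:
                raise FormatError(f"component {name!r} has no signal on the axis")
            self._norm[name] = peak
            self.components[name] = spec / peak

    def component_names(self) -> tuple[str, ...]:
        return tuple(self.peaks)

    def value_at(self, name: str, wavenumber: float) -> float:
        """Normalized component intensity at one wavenumber (closed form)."""
        total = sum(
            rel * math.exp(-4.0 * math.log(2.0) * ((wavenumber - c) / self.fwhm) ** 2)
            for c, rel in self.peaks[name]
        )
        return total / self._norm[name]

    def true_band_area(self, name: str, bands: BandLibrary, band: str) -> float:
        """Analytic area contributed by ``name`` inside ``band``'s window."""
        window = bands[band]
        area = 0.0
        for center, rel in self.peaks[name]:
            if window.contains(center):
                area += (rel / self._norm[name]) * self.fwhm * GAUSS_AREA_FACTOR
        return area


def make_power_spectrum(
    axis: np.ndarray | None = None,
    power_at_ref_mw: float = 6.0,
    ref_wavenumber: float = 2096.0,
) -> PowerSpectrum:
    """Smooth IR-laser power curve, pinned to a measured value at 2096 cm^-1.

    The shape is a broad bump over the fingerprint region falling off toward
    the cell-silent region, qualitatively like a quantum cascade laser tuning
    curve; absolute scale is set by ``power_at_ref_mw``.
    """
    axis = DEFAULT_AXIS.copy() if axis is None else np.asarray(axis, dtype=float)
    shape = 0.7 + 0.6 * np.exp(-(((axis - 1500.0) / 500.0) ** 2))
    ref = 0.7 + 0.6 * math.exp(-(((ref_wavenumber - 1500.0) / 500.0) ** 2))
    return PowerSpectrum(axis, power_at_ref_mw * shape / ref)


def make_spectrum(
    weights: dict[str, float],
    noise_sd: float = 0.0,
    seed: int | None = None,
    library: ComponentLibrary | None = None,
    bands: BandLibrary | None = None,
    apply_power: PowerSpectrum | None = None,
    meta: dict | None = None,
) -> tuple[Spectrum, dict]:
    """Weighted component mixture plus i.i.d. Gaussian noise, with truth.

    Returns ``(spectrum, truth)`` where the truth carries the exact per-band
    areas of the noiseless mixture. Without ``apply_power`` the spectrum
    represents a power-normalized trace; with it, intensities are multiplied
    by the power curve to emulate a raw instrument export (flags false).
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    lib = library or ComponentLibrary()
    bands = bands or BandLibrary()
    for name, w in weights.items():
        if name not in lib.components:
            raise KeyError(f"unknown component {name!r}")
        if w < 0:
            raise ValueError(f"component weight must be >= 0, got {name}={w}")
    intensity = np.zeros_like(lib.axis)
    for name, w in weights.items():
        intensity = intensity + w * lib.components[name]
    truth_areas: dict[str, float] = {}
    for band in bands.bands:
        area = sum(
            w * lib.true_band_area(name, bands, band) for name, w in weights.items()
        )
        if area > 0:
            truth_areas[band] = area
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.size)
    power_normalized = True
    if apply_power is not None:
        intensity = intensity * np.asarray(apply_power.at(lib.axis))
        power_normalized = False
    spectrum = Spectrum(
        lib.axis.copy(),
        intensity,
        power_normalized=power_normalized,
        meta=dict(meta or {}),
    )
    truth = {"weights": dict(weights), "band_areas": truth_areas, "noise_sd": noise_sd}
    return spectrum, truth


# ---------------------------------------------------------------------------
# Cell-image phantom
# ---------------------------------------------------------------------------


@dataclass
class CellPhantomSpec:
    """Geometry and composition of a cell-image phantom.

    ``new_lipid_fraction`` is the per-cell true azide/lipid weight ratio; a
    scalar applies to every cell, a sequence gives one value per cell.
    ``droplet_radius_um`` may be a scalar or a (lo, hi) range sampled
    uniformly per droplet.
    """

    fov_um: float = 40.0
    n_cells: int = 1
    cell_radius_um: float = 8.0
    nucleus_radius_um: float = 2.5
    droplets_per_cell: int = 4
    droplet_radius_um: float | tuple[float, float] = 0.6
    new_lipid_fraction: float | tuple[float, ...] = 0.5
    protein_cytoplasm: float = 1.0
    protein_nucleus: float = 1.3
    cytoplasm_lipid: float = 0.15
    droplet_lipid: float = 1.0
    max_placement_tries: int = 500

    def fraction_for(self, cell_index: int) -> float:
        if isinstance(self.new_lipid_fraction, (int, float)):
            return float(self.new_lipid_fraction)
        return float(self.new_lipid_fraction[cell_index])

    def droplet_radius(self, rng: np.random.Generator) -> float:
        if isinstance(self.droplet_radius_um, (int, float)):
            return float(self.droplet_radius_um)
        lo, hi = self.droplet_radius_um
        return float(rng.uniform(lo, hi))


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside phantom images.

    Weight maps are PSF-free component weights point-sampled on the detector
    grid, so every truth below is recomputable from them.
    """

    weight_maps: dict[str, np.ndarray]
    cell_mask: LabelMask
    droplets: list[tuple[float, float, float, int]]  # (x_um, y_um, r_um, cell)
    cell_truths: dict[int, dict[str, float]]
    psf_fwhm_um: float
    pixel_size_um: float
    seed: int | None

    def recompute_cell_truths(self) -> dict[int, dict[str, float]]:
        """Per-cell ratios recomputed from the emitted weight maps."""
        out: dict[int, dict[str, float]] = {}
        labels = self.cell_mask.labels
        for k in self.cell_mask.region_ids():
            sel = labels == k
            protein = float(self.weight_maps["protein"][sel].sum())
            lipid = float(self.weight_maps["total_lipid"][sel].sum())
            azide = float(self.weight_maps["azide"][sel].sum())
            out[int(k)] = {
                "norm_total_lipid": lipid / protein if protein > 0 else float("nan"),
                "new_lipid_fraction": azide / lipid if lipid > 0 else float("nan"),
            }
        return out


def _disk(
    grid_y: np.ndarray, grid_x: np.ndarray, cx: float, cy: float, r: float, px: float
) -> np.ndarray:
    """Anti-aliased disk indicator on a pixel-centre grid (values in [0,1])."""
    d = np.hypot(grid_x - cx, grid_y - cy)
    return np.clip(0.5 + (r - d) / px, 0.0, 1.0)


def make_cell_image(
    geometry: CellPhantomSpec | None = None,
    psf_fwhm_um: float = 0.5,
    pixel_size_um: float = 0.5,
    noise_snr: float | None = None,
    seed: int | None = None,
    channels: dict[str, float] | None = None,
    library: ComponentLibrary | None = None,
    apply_psf: bool = True,
) -> tuple[dict[str, ChannelImage], PhantomTruth]:
    """Render a cell phantom into per-band channel images plus ground truth.

    Cells are disks with a nucleus (protein-rich, lipid-poor), cytoplasm
    (protein plus a low lipid background) and lipid droplets (lipid-rich;
    azide weight = per-cell fraction x lipid weight). The component weight
    maps are built on a supersampled grid, multiplied by each channel's
    component response, convolved with a Gaussian PSF of ``psf_fwhm_um``,
    then point-sampled at the detector pixel centres -- the raster-scan
    geometry of the instrument. ``noise_snr`` is the peak amide-I channel
    amplitude over the additive noise sigma; ``None`` disables noise.

    Returns ``(channel images, truth)``. With ``apply_psf=False`` and no
    noise, per-pixel channel ratios equal the true weight ratios exactly.
    """
    spec = geometry or CellPhantomSpec()
    lib = library or ComponentLibrary()
    chans = dict(channels or CHANNEL_WAVENUMBERS)
    if spec.fov_um < 20:
        raise GeometryError("phantom field of view must be >= 20 um")
    rmin = (
        spec.droplet_radius_um
        if isinstance(spec.droplet_radius_um, (int, float))
        else spec.droplet_radius_um[0]
    )
    if rmin < 0.05:
        raise GeometryError("droplet radii must be >= 0.05 um")
    rng = np.random.default_rng(seed)

    n_det = int(round(spec.fov_um / pixel_size_um))
    ss = max(1, int(round(pixel_size_um / 0.05)))
    if ss % 2 == 0:
        ss += 1  # odd: detector pixel centres coincide with fine-grid centres
    fine_px = pixel_size_um / ss
    n_fine = n_det * ss
    coords = (np.arange(n_fine) + 0.5) * fine_px
    gx, gy = np.meshgrid(coords, coords)

    protein = np.zeros((n_fine, n_fine))
    lipid = np.zeros((n_fine, n_fine))
    azide = np.zeros((n_fine, n_fine))
    labels_fine = np.zeros((n_fine, n_fine), dtype=np.int64)
    droplets: list[tuple[float, float, float, int]] = []

    margin = spec.cell_radius_um + 1.0
    if 2 * margin >= spec.fov_um:
        raise GeometryError("cells do not fit in the field of view")
    # place cells without overlap
    centers: list[tuple[float, float]] = []
    for k in range(spec.n_cells):
        for _ in range(spec.max_placement_tries):
            cx = rng.uniform(margin, spec.fov_um - margin)
            cy = rng.uniform(margin, spec.fov_um - margin)
            if all(
                math.hypot(cx - ox, cy - oy) > 2.05 * spec.cell_radius_um
                for ox, oy in centers
            ):
                centers.append((cx, cy))
                break
        else:
            raise GeometryError(
                f"could not place cell {k + 1} after {spec.max_placement_tries} tries"
            )

    for k, (cx, cy) in enumerate(centers, start=1):
        frac = spec.fraction_for(k - 1)
        cell = _disk(gy, gx, cx, cy, spec.cell_radius_um, fine_px)
        nucleus = _disk(gy, gx, cx, cy, spec.nucleus_radius_um, fine_px)
        cytoplasm = np.clip(cell - nucleus, 0.0, 1.0)
        protein += spec.protein_cytoplasm * cytoplasm + spec.protein_nucleus * nucleus
        cell_lipid = spec.cytoplasm_lipid * cytoplasm
        # droplets inside the cytoplasm annulus
        for _ in range(spec.droplets_per_cell):
            r = spec.droplet_radius(rng)
            for _ in range(spec.max_placement_tries):
                rho = rng.uniform(spec.nucleus_radius_um + r, spec.cell_radius_um - r)
                phi = rng.uniform(0.0, 2.0 * math.pi)
                dx, dy = cx + rho * math.cos(phi), cy + rho * math.sin(phi)
                if all(
                    math.hypot(dx - ox, dy - oy) > r + orr
                    for ox, oy, orr, _ in droplets
                ):
                    break
            else:
                raise GeometryError("could not place a droplet without overlap")
            droplets.append((dx, dy, r, k))
            cell_lipid = np.maximum(
                cell_lipid, spec.droplet_lipid * _disk(gy, gx, dx, dy, r, fine_px)
            )
        lipid += cell_lipid
        azide += frac * cell_lipid
        labels_fine[cell > 0.5] = k

    weight_fine = {"protein": protein, "total_lipid": lipid, "azide": azide}

    # detector pixel centres on the fine grid
    det = (np.arange(n_det) + 0.5) * ss - 0.5
    dr, dc = np.meshgrid(det, det, indexing="ij")
    sample_coords = np.vstack([dr.ravel(), dc.ravel()])

    def point_sample(img: np.ndarray, order: int = 1) -> np.ndarray:
        out = ndimage.map_coordinates(img, sample_coords, order=order, mode="nearest")
        return out.reshape(n_det, n_det)

    sigma_fine = psf_fwhm_um / (2.0 * math.sqrt(2.0 * math.log(2.0))) / fine_px

    channel_fine: dict[str, np.ndarray] = {}
    for name, wn in chans.items():
        signal = np.zeros((n_fine, n_fine))
        for comp, wmap in weight_fine.items():
            resp = lib.value_at(comp, wn)
            if resp > 0:
                signal = signal + resp * wmap
        if apply_psf and sigma_fine > 0:
            signal = ndimage.gaussian_filter(signal, sigma_fine, mode="nearest")
        channel_fine[name] = signal

    images: dict[str, ChannelImage] = {}
    for name, wn in chans.items():
        pixels = point_sample(channel_fine[name])
        if noise_snr is not None:
            if noise_snr <= 0:
                raise ValueError("noise_snr must be positive")
            # SNR is each channel's peak (post-PSF) amplitude over noise sigma
            peak = float(channel_fine[name].max())
            if peak > 0:
                pixels = pixels + rng.normal(0.0, peak / noise_snr, pixels.shape)
        images[name] = ChannelImage(
            pixels, pixel_size_um, wn, power_normalized=True,
            meta={"phantom_seed": seed, "band": name},
        )

    weight_maps = {k: point_sample(v) for k, v in weight_fine.items()}
    label_det = point_sample(labels_fine.astype(float), order=0).astype(np.int64)
    cell_mask = LabelMask(label_det, pixel_size_um)
    truth = PhantomTruth(
        weight_maps=weight_maps,
        cell_mask=cell_mask,
        droplets=droplets,
        cell_truths={},
        psf_fwhm_um=psf_fwhm_um,
        pixel_size_um=pixel_size_um,
        seed=seed,
    )
    truth.cell_truths = truth.recompute_cell_truths()
    return images, truth


def make_resolution_phantom(
    seed: int | None = None,
    droplet_radius_um: float = 0.1,
    pixel_size_um: float = 0.1,
    psf_fwhm_um: float = 0.5,
    noise_snr: float | None = 50.0,
) -> tuple[ChannelImage, tuple[float, float]]:
    """Cell phantom for spatial-resolution estimation.

    One cell containing a single isolated, fully azide-tagged droplet with no
    cytoplasmic lipid background: the droplet is the only structure in the
    azide channel, so a line profile across it measures the instrument PSF
    (for a sub-resolution droplet, FWHM ~ psf_fwhm_um). Returns the azide
    channel image and the droplet centre (x, y) in um.
    """
    spec = CellPhantomSpec(
        fov_um=20.0,
        n_cells=1,
        cell_radius_um=6.0,
        nucleus_radius_um=2.0,
        droplets_per_cell=1,
        droplet_radius_um=droplet_radius_um,
        new_lipid_fraction=1.0,
        cytoplasm_lipid=0.0,
    )
    images, truth = make_cell_image(
        spec,
        psf_fwhm_um=psf_fwhm_um,
        pixel_size_um=pixel_size_um,
        noise_snr=noise_snr,
        seed=seed,
    )
    x, y, _, _ = truth.droplets[0]
    return images["azide"], (x, y)


# ---------------------------------------------------------------------------
# Colocalization phantom
# ---------------------------------------------------------------------------


def make_coloc_fov(
    seed: int | None = None,
    fov_um: float = 100.0,
    pixel_size_um: float = 1.0,
    noise_sd: float = 0.1,
) -> tuple[ChannelImage, dict[str, ChannelImage]]:
    """One field of view for colocalization tests.

    Two cell-type territories (astrocyte / neuron) split the field along a
    randomly oriented smooth boundary; the azide channel is built from the
    astrocyte territory plus additive noise, so its Pearson correlation with
    the astrocyte fluorescence channel exceeds that with the neuron channel.
    """
    rng = np.random.default_rng(seed)
    n = int(round(fov_um / pixel_size_um))
    coords = (np.arange(n) + 0.5) * pixel_size_um
    gx, gy = np.meshgrid(coords, coords)
    theta = rng.uniform(0.0, math.pi)
    offset = rng.uniform(0.4, 0.6) * fov_um
    axis_proj = math.cos(theta) * gx + math.sin(theta) * gy
    astro = (axis_proj < offset).astype(float)
    neuron = 1.0 - astro
    azide = ChannelImage(
        astro + rng.normal(0.0, noise_sd, astro.shape),
        pixel_size_um, 2096.0, power_normalized=True,
    )
    fluor = {
        "astrocyte": ChannelImage(
            astro + rng.normal(0.0, noise_sd, astro.shape), pixel_size_um, 1654.0,
            power_normalized=True,
        ),
        "neuron": ChannelImage(
            neuron + rng.normal(0.0, noise_sd, neuron.shape), pixel_size_um, 1654.0,
            power_normalized=True,
        ),
    }
    return azide, fluor


# ---------------------------------------------------------------------------
# Organoid phantom
# ---------------------------------------------------------------------------


@dataclass
class OrganoidPhantom:
    tissue_mask: LabelMask
    azide_image: ChannelImage
    spectra: list[Spectrum]
    truth: dict


def make_organoid_phantom(
    radius_um: float = 1500.0,
    decay_length_um: float = 300.0,
    seed: int | None = None,
    pixel_size_um: float = 10.0,
    n_locations: int = 5,
    spectra_per_location: int = 5,
    noise_sd: float = 0.005,
    azide_surface_weight: float = 1.0,
    library: ComponentLibrary | None = None,
) -> OrganoidPhantom:
    """Disc-shaped tissue section with exponential azide penetration decay.

    The azide weight at depth d from the surface is
    ``azide_surface_weight * exp(-d / decay_length_um)``; protein and lipid
    weights are uniform across the tissue. Point spectra are drawn at
    ``n_locations`` depths along a horizontal radius (grouped by a
    ``location`` meta key), emulating the probe-penetration measurement in
    cryosectioned organoids.
    """
    # an infinite decay length is the flat-profile limit and always valid
    if math.isfinite(decay_length_um) and radius_um <= decay_length_um / 10.0:
        raise GeometryError("radius must exceed decay_length / 10")
    lib = library or ComponentLibrary()
    rng = np.random.default_rng(seed)
    margin = 2.0 * pixel_size_um
    half = radius_um + margin
    n = int(round(2.0 * half / pixel_size_um))
    coords = (np.arange(n) + 0.5) * pixel_size_um
    gx, gy = np.meshgrid(coords, coords)
    cx = cy = half
    inside = np.hypot(gx - cx, gy - cy) <= radius_um
    mask = LabelMask(inside.astype(np.int64), pixel_size_um)
    depth = distance_to_surface(mask)
    azide_w = np.where(inside, azide_surface_weight * np.exp(-np.maximum(depth, 0.0) / decay_length_um), 0.0)
    azide_image = ChannelImage(
        azide_w * lib.value_at("azide", 2096.0),
        pixel_size_um, 2096.0, power_normalized=True,
    )

    # sampling depths along the horizontal radius, surface to core
    max_depth = 0.8 * radius_um
    depths = np.linspace(0.0, max_depth, n_locations)
    spectra: list[Spectrum] = []
    true_areas = []
    bands = BandLibrary()
    azide_unit_area = lib.true_band_area("azide", bands, "azide")
    for loc, d in enumerate(depths):
        x_um = cx - radius_um + d  # moving inward from the left surface
        y_um = cy
        w_az = azide_surface_weight * math.exp(-d / decay_length_um)
        true_areas.append(w_az * azide_unit_area)
        for j in range(spectra_per_location):
            s, _ = make_spectrum(
                {"protein": 1.0, "total_lipid": 0.5, "azide": w_az},
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                library=lib,
                meta={"x_um": x_um, "y_um": y_um, "location": loc, "id": f"loc{loc}_{j}"},
            )
            spectra.append(s)
    truth = {
        "decay_length_um": decay_length_um,
        "radius_um": radius_um,
        "depths_um": depths,
        "true_azide_areas": np.asarray(true_areas),
        "azide_surface_weight": azide_surface_weight,
        "seed": seed,
    }
    return OrganoidPhantom(mask, azide_image, spectra, truth)


# ---------------------------------------------------------------------------
# Dilution series
# ---------------------------------------------------------------------------


def make_dilution_series(
    concentrations_um: np.ndarray | None = None,
    slope: float = 1e-3,
    noise_sd: float = 1e-3 * 100.0 / 3.0,
    seed: int | None = None,
    n_blanks: int = 6,
) -> tuple[DilutionSeries, dict]:
    """Serial-dilution azide areas, linear in concentration, plus truth.

    Defaults give an analytic 3-sigma limit of detection of 100 uM, the
    scale measured for the azide bond in DMSO. Truth carries the analytic
    LoD ``3 * noise_sd / slope``.
    """
    if concentrations_um is None:
        concentrations_um = np.array([25.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1600.0])
    c = np.asarray(concentrations_um, dtype=float)
    rng = np.random.default_rng(seed)
    areas = slope * c + rng.normal(0.0, noise_sd, size=c.size)
    blanks = rng.normal(0.0, noise_sd, size=n_blanks)
    series = DilutionSeries(concentrations=c, areas=areas, blank_areas=blanks)
    truth = {
        "slope": slope,
        "noise_sd": noise_sd,
        "analytic_lod_um": 3.0 * noise_sd / slope,
        "seed": seed,
    }
    return series, truth
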