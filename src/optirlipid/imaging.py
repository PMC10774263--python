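"""Ratio images, per-cell image quantification, histogram subpopulations and
line profiles.

A ratio image divides two power-normalized single-wavenumber channels
pixelwise (canonically azide 2096 / carbonyl 1744, i.e. the per-pixel newly
synthesized lipid fraction) and masks pixels whose denominator is near zero.
Per-cell means over label masks give image-based single-cell quantification;
fitting one or two Gaussians to the pooled pixel histogram separates
subpopulations of cells with distinct metabolic levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage import filters, measure

from .exceptions import FitError, FormatError, GeometryError
from .formats import ChannelImage, LabelMask


@dataclass
class RatioImage:
    """Per-pixel quotient of two channel images with a validity mask.

    Values are defined only where ``valid_mask`` is true; outside they are
    NaN by construction and must never enter statistics.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    numerator_wavenumber: float
    denominator_wavenumber: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.values.shape != self.valid_mask.shape:
            raise GeometryError("values and valid_mask shapes differ")
        inside = self.values[self.valid_mask]
        if inside.size and not np.all(np.isfinite(inside)):
            raise FormatError("ratio values inside the valid mask must be finite")

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]


def ratio_image(
    num: ChannelImage, den: ChannelImage, threshold_frac: float = 0.05
) -> RatioImage:
    """num / den on pixels where den exceeds ``threshold_frac`` of its max.

    Both channels must be power-normalized, share shape and pixel size. The
    threshold guards against division by near-zero background; there are
    never infinities or NaNs inside the valid mask.
    """
    if num.pixels.shape != den.pixels.shape:
        raise GeometryError(
            f"channel shapes differ: {num.pixels.shape} vs {den.pixels.shape}"
        )
    if not math.isclose(num.pixel_size_um, den.pixel_size_um):
        raise GeometryError("channel pixel sizes differ")
    if not (num.power_normalized and den.power_normalized):
        raise FormatError("ratio_image requires power-normalized channels")
    dmax = float(np.max(den.pixels))
    valid = den.pixels > threshold_frac * dmax
    values = np.full(den.pixels.shape, np.nan)
    np.divide(num.pixels, den.pixels, out=values, where=valid)
    return RatioImage(
        values=values,
        valid_mask=valid,
        numerator_wavenumber=num.wavenumber,
        denominator_wavenumber=den.wavenumber,
        pixel_size_um=num.pixel_size_um,
    )


def cell_mean_ratio(
    r: RatioImage, cells: LabelMask, min_valid_pixels: int = 10
) -> dict[int, float | None]:
    """Mean ratio per labelled cell, over valid pixels only.

    Cells with fewer than ``min_valid_pixels`` valid pixels map to ``None``
    (undefined) rather than an unreliable mean.
    """
    if cells.labels.shape != r.values.shape:
        raise GeometryError("label mask shape differs from ratio image")
    ids = cells.region_ids()
    if ids.size == 0:
        raise ValueError("label mask contains no cells")
    out: dict[int, float | None] = {}
    for k in ids:
        sel = (cells.labels == k) & r.valid_mask
        n = int(np.count_nonzero(sel))
        out[int(k)] = float(np.mean(r.values[sel])) if n >= min_valid_pixels else None
    return out


@dataclass(frozen=True)
class GaussianComponent:
    center: float
    sigma: float
    amplitude: float


@dataclass
class HistogramFit:
    """One- or two-Gaussian fit to a pixel-value histogram."""

    bin_edges: np.ndarray
    counts: np.ndarray
    components: tuple[GaussianComponent, ...]  # sorted by center, ascending
    r_squared: float

    @property
    def centers(self) -> tuple[float, ...]:
        return tuple(c.center for c in self.components)


def _freedman_diaconis_bins(values: np.ndarray) -> np.ndarray:
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    lo, hi = float(values.min()), float(values.max())
    if iqr <= 0 or hi <= lo:
        return np.linspace(lo, hi if hi > lo else lo + 1.0, 11)
    width = 2.0 * iqr / values.size ** (1.0 / 3.0)
    n_bins = max(int(np.ceil((hi - lo) / width)), 4)
    return np.linspace(lo, hi, n_bins + 1)


def _kmeans_1d_2(values: np.ndarray, n_iter: int = 50) -> tuple[float, float]:
    """Deterministic 1-D two-means split (percentile init, Lloyd updates)."""
    c = np.percentile(values, [25.0, 75.0]).astype(float)
    for _ in range(n_iter):
        assign = np.abs(values[:, None] - c[None, :]).argmin(axis=1)
        new = np.array([
            values[assign == j].mean() if np.any(assign == j) else c[j]
            for j in range(2)
        ])
        if np.allclose(new, c):
            break
        c = new
    return float(min(c)), float(max(c))


def histogram_subpopulations(
    r: RatioImage, n_components: int = 1, bins: int | None = None
) -> HistogramFit:
    """Least-squares Gaussian fit(s) to the histogram of valid ratio pixels.

    ``n_components`` is 1 or 2 and chosen by the caller (no automatic model
    selection). Binning defaults to Freedman-Diaconis. For two components the
    initial centres come from a deterministic 1-D two-means split of the
    pixel values. Centres are returned sorted ascending.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    values = r.valid_values()
    if values.size < 100:
        raise FormatError(f"need >= 100 valid pixels, got {values.size}")
    edges = (
        np.linspace(values.min(), values.max(), bins + 1)
        if bins is not None
        else _freedman_diaconis_bins(values)
    )
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ymax = float(counts.max())
    spread = float(values.std())

    if n_components == 1:
        p0 = [ymax, float(values.mean()), max(spread, 1e-12)]
    else:
        c1, c2 = _kmeans_1d_2(values)
        s0 = max((c2 - c1) / 4.0, spread / 4.0, 1e-12)
        p0 = [ymax / 2.0, c1, s0, ymax / 2.0, c2, s0]

    def model(x, *p):
        y = np.zeros_like(x)
        for j in range(0, len(p), 3):
            amp, c, s = p[j], p[j + 1], p[j + 2]
            y = y + amp * np.exp(-((x - c) ** 2) / (2.0 * s**2))
        return y

    lo_b = [0.0, float(values.min()), 1e-12] * n_components
    hi_b = [np.inf, float(values.max()), float(values.max() - values.min()) or 1.0] * n_components
    try:
        popt, _ = optimize.curve_fit(
            model, centers, counts.astype(float), p0=p0, bounds=(lo_b, hi_b), maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(
            f"histogram fit did not converge (initial guesses {p0})"
        ) from exc
    comps = sorted(
        (
            GaussianComponent(center=float(popt[j + 1]), sigma=float(popt[j + 2]),
                              amplitude=float(popt[j]))
            for j in range(0, len(popt), 3)
        ),
        key=lambda c: c.center,
    )
    resid = counts - model(centers, *popt)
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return HistogramFit(bin_edges=edges, counts=counts, components=tuple(comps), r_squared=r2)


def extract_line_profile(
    img: ChannelImage,
    p0_um: tuple[float, float],
    p1_um: tuple[float, float],
    n_samples: int = 50,
    interpolation: str = "bilinear",
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the image along a segment between two points given in um.

    Points are ``(x, y)`` in micrometres with pixel centres at
    ``(j + 0.5, i + 0.5) * pixel_size``. Returns ``(positions_um, values)``
    where positions run from 0 at ``p0_um``. Bilinear interpolation by
    default; ``interpolation="nearest"`` for bit-exact sampling.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    h_um, w_um = img.fov_um
    for (x, y) in (p0_um, p1_um):
        if not (0.0 <= x <= w_um and 0.0 <= y <= h_um):
            raise GeometryError(f"endpoint ({x:g}, {y:g}) um outside the image")
    t = np.linspace(0.0, 1.0, n_samples)
    xs = p0_um[0] + t * (p1_um[0] - p0_um[0])
    ys = p0_um[1] + t * (p1_um[1] - p0_um[1])
    cols = xs / img.pixel_size_um - 0.5
    rows = ys / img.pixel_size_um - 0.5
    order = {"bilinear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    values = ndimage.map_coordinates(
        img.pixels, np.vstack([rows, cols]), order=order, mode="nearest"
    )
    length = math.hypot(p1_um[0] - p0_um[0], p1_um[1] - p0_um[1])
    return t * length, values


def droplet_line_profile(
    img: ChannelImage,
    center_um: tuple[float, float],
    half_width_px: int = 15,
    axis: str = "horizontal",
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-aligned line profile through a droplet centre.

    Snaps the requested ``(x, y)`` centre to the nearest pixel centre and
    samples exactly one value per pixel along the chosen axis, so the profile
    is the raw scan line with no interpolation smoothing -- the measurement
    used to estimate spatial resolution from a sub-resolution droplet.
    """
    px = img.pixel_size_um
    x, y = center_um
    j0 = int(round(x / px - 0.5))
    i0 = int(round(y / px - 0.5))
    xc, yc = (j0 + 0.5) * px, (i0 + 0.5) * px
    n = 2 * half_width_px + 1
    if axis == "horizontal":
        p0 = ((j0 - half_width_px + 0.5) * px, yc)
        p1 = ((j0 + half_width_px + 0.5) * px, yc)
    elif axis == "vertical":
        p0 = (xc, (i0 - half_width_px + 0.5) * px)
        p1 = (xc, (i0 + half_width_px + 0.5) * px)
    else:
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    return extract_line_profile(img, p0, p1, n_samples=n)


def segment_cells_otsu(
    img: ChannelImage, min_area_px: int = 20
) -> LabelMask:
    """Convenience Otsu-threshold + connected-components cell mask.

    Non-canonical helper: real analyses use hand-drawn or externally derived
    ROI masks; this gives a quick mask for phantoms and smoke tests.
    """
    thr = filters.threshold_otsu(img.pixels)
    binary = img.pixels > thr
    labels = measure.label(binary, connectivity=1)
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            labels[labels == region.label] = 0
    # re-densify label ids
    out = np.zeros_like(labels)
    for new_id, old_id in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old_id] = new_id
    return LabelMask(out.astype(np.int64), img.pixel_size_um)
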