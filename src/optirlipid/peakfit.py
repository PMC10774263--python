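"""Peak detection by smoothed second derivatives and whole-spectrum fitting.

Candidate peak centres are found as local minima of a Savitzky-Golay second
derivative (a band appears as a negative dip in the second derivative, robust
against a slowly varying baseline). The whole spectrum is then fitted jointly
as a linear baseline plus one lineshape per seed, by bounded nonlinear least
squares. Per-component areas follow in closed form:

* Gaussian:      A = amplitude * fwhm * sqrt(pi / (4 ln 2))
* Lorentzian:    A = amplitude * fwhm * pi / 2
* pseudo-Voigt:  A = eta * Lorentzian + (1 - eta) * Gaussian areas

Gaussian is the default lineshape: it has a closed-form area and condensed-
phase mid-IR bands over this range are well approximated by it; a pseudo-Voigt
(mixing eta) is available through :class:`FitConfig`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .exceptions import EstimationError, FitError, FormatError
from .formats import BandLibrary, Spectrum

GAUSS_AREA_FACTOR = math.sqrt(math.pi / (4.0 * math.log(2.0)))
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class PeakComponent:
    """One fitted band: centre and FWHM in cm^-1, amplitude in a.u. (>= 0)."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"  # "gaussian" | "lorentzian" | "pseudo_voigt"
    eta: float = 0.0  # Lorentzian fraction for pseudo_voigt

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise FitError(f"component fwhm must be > 0, got {self.fwhm}")
        if self.amplitude < 0:
            raise FitError(f"component amplitude must be >= 0, got {self.amplitude}")
        if self.shape not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise FitError(f"unknown lineshape {self.shape!r}")
        if not (0.0 <= self.eta <= 1.0):
            raise FitError("pseudo-Voigt eta must lie in [0, 1]")

    def profile(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the component on wavenumbers ``x``."""
        x = np.asarray(x, dtype=float)
        g = np.exp(-4.0 * math.log(2.0) * ((x - self.center) / self.fwhm) ** 2)
        if self.shape == "gaussian":
            return self.amplitude * g
        lor = 1.0 / (1.0 + (2.0 * (x - self.center) / self.fwhm) ** 2)
        if self.shape == "lorentzian":
            return self.amplitude * lor
        return self.amplitude * (self.eta * lor + (1.0 - self.eta) * g)

    @property
    def area(self) -> float:
        """Closed-form area under the component (a.u. * cm^-1)."""
        gauss = self.amplitude * self.fwhm * GAUSS_AREA_FACTOR
        lor = self.amplitude * self.fwhm * math.pi / 2.0
        if self.shape == "gaussian":
            return gauss
        if self.shape == "lorentzian":
            return lor
        return self.eta * lor + (1.0 - self.eta) * gauss


@dataclass
class SpectralFit:
    """Whole-spectrum fit: baseline + components, with per-band areas.

    ``areas`` maps band names to the closed-form area of the component
    assigned to that band; a band with no component inside its window is
    simply absent from the mapping (never stored as 0).
    """

    components: list[PeakComponent]
    baseline: tuple[float, float]  # (intercept at x_ref, slope)
    x_ref: float
    areas: dict[str, float]
    band_components: dict[str, PeakComponent]
    residual_rms: float
    converged: bool
    n_iter: int
    warnings: list[str] = field(default_factory=list)

    def baseline_at(self, x: np.ndarray) -> np.ndarray:
        b0, b1 = self.baseline
        return b0 + b1 * (np.asarray(x, dtype=float) - self.x_ref)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Model value (baseline + all components) at wavenumbers ``x``."""
        y = self.baseline_at(x)
        for c in self.components:
            y = y + c.profile(x)
        return y


@dataclass
class FitConfig:
    """Optimizer and model settings for whole-spectrum fitting."""

    shape: str = "gaussian"
    eta: float = 0.5  # used only for pseudo_voigt
    center_window: float = 10.0  # cm^-1, centre constrained to seed +/- this
    fwhm_init: float = 25.0
    fwhm_min: float = 2.0
    fwhm_max: float = 200.0
    max_nfev: int = 500 * 20
    tol: float = 1e-10
    smooth_window: int = 11
    smooth_poly: int = 3
    prominence_frac: float = 0.05


def detect_peaks(
    s: Spectrum,
    smooth_window: int = 11,
    smooth_poly: int = 3,
    prominence_frac: float = 0.05,
) -> list[float]:
    """Candidate peak centres from the Savitzky-Golay second derivative.

    Candidates are local minima of the smoothed second derivative whose depth
    (negative excursion) exceeds ``prominence_frac`` times the depth of the
    strongest minimum. Points in the masked gap are never reported. Returned
    centres are sorted by wavenumber.
    """
    if not (s.power_normalized or s.amide_normalized):
        raise FormatError("detect_peaks expects a normalized spectrum")
    if smooth_window % 2 == 0 or smooth_window < smooth_poly + 2:
        raise FormatError("smoothing window must be odd and >= poly + 2")
    n = s.wavenumbers.size
    if n < smooth_window:
        raise FormatError(
            f"spectrum has {n} points, shorter than smoothing window {smooth_window}"
        )
    dx = float(np.mean(np.diff(s.wavenumbers)))
    if not np.allclose(np.diff(s.wavenumbers), dx, rtol=1e-3, atol=1e-9 * abs(dx)):
        raise FormatError("detect_peaks requires a (near-)uniform wavenumber grid")
    d2 = signal.savgol_filter(s.intensity, smooth_window, smooth_poly, deriv=2, delta=dx)
    depth = -d2
    # local maxima of depth, i.e. minima of the second derivative
    idx, _ = signal.find_peaks(depth)
    idx = idx[depth[idx] > 0]
    if idx.size == 0:
        return []
    idx = idx[~s.excluded[idx]]
    if idx.size == 0:
        return []
    strongest = float(np.max(depth[idx]))
    keep = idx[depth[idx] >= prominence_frac * strongest]
    return [float(w) for w in np.sort(s.wavenumbers[keep])]


def _dedupe_seeds(seeds: list[float], min_sep: float = 1.0) -> tuple[list[float], bool]:
    seeds = sorted(float(c) for c in seeds)
    out: list[float] = []
    dropped = False
    for c in seeds:
        if out and abs(c - out[-1]) < min_sep:
            dropped = True
            continue
        out.append(c)
    return out, dropped


def fit_spectrum(
    s: Spectrum,
    seeds: list[float],
    bands: BandLibrary | None = None,
    config: FitConfig | None = None,
) -> SpectralFit:
    """Joint nonlinear least squares of baseline + one component per seed.

    Centres are bounded to ``seed +/- config.center_window`` (this keeps the
    azide component from drifting into the masked gap), FWHMs and amplitudes
    to positive ranges. Masked points do not enter the residual. Areas are
    assigned to band names when a fitted centre falls inside a band's window;
    if two components land in one window the larger-area one wins and the
    event is recorded as a fit-quality warning.
    """
    bands = bands or BandLibrary()
    cfg = config or FitConfig()
    if not seeds:
        raise FitError("fit_spectrum needs at least one seed centre")
    seeds, dropped = _dedupe_seeds(list(seeds))
    fit_warnings: list[str] = []
    if dropped:
        msg = "duplicate seed centres were deduplicated"
        warnings.warn(msg, stacklevel=2)
        fit_warnings.append(msg)

    use = ~s.excluded
    x = s.wavenumbers[use]
    y = s.intensity[use]
    if x.size < 2 * len(seeds) + 2:
        raise FitError("too few unmasked points for the requested model")
    x_ref = float(np.mean(x))
    k = len(seeds)

    def unpack(theta: np.ndarray):
        b0, b1 = theta[0], theta[1]
        amps = theta[2 : 2 + k]
        cents = theta[2 + k : 2 + 2 * k]
        fwhms = theta[2 + 2 * k : 2 + 3 * k]
        return b0, b1, amps, cents, fwhms

    ln2_4 = 4.0 * math.log(2.0)

    def model(theta: np.ndarray) -> np.ndarray:
        b0, b1, amps, cents, fwhms = unpack(theta)
        ym = b0 + b1 * (x - x_ref)
        for a, c, f in zip(amps, cents, fwhms):
            g = np.exp(-ln2_4 * ((x - c) / f) ** 2)
            if cfg.shape == "gaussian":
                ym = ym + a * g
            else:
                lor = 1.0 / (1.0 + (2.0 * (x - c) / f) ** 2)
                if cfg.shape == "lorentzian":
                    ym = ym + a * lor
                else:
                    ym = ym + a * (cfg.eta * lor + (1.0 - cfg.eta) * g)
        return ym

    def residuals(theta: np.ndarray) -> np.ndarray:
        return model(theta) - y

    base0 = float(np.percentile(y, 5))
    amps0 = [max(float(np.interp(c, x, y)) - base0, 1e-12) for c in seeds]
    theta0 = np.concatenate([[base0, 0.0], amps0, seeds, [cfg.fwhm_init] * k])
    lo = np.concatenate(
        [[-np.inf, -np.inf], [0.0] * k, [c - cfg.center_window for c in seeds], [cfg.fwhm_min] * k]
    )
    hi = np.concatenate(
        [[np.inf, np.inf], [np.inf] * k, [c + cfg.center_window for c in seeds], [cfg.fwhm_max] * k]
    )
    theta0 = np.clip(theta0, lo, hi)
    res = optimize.least_squares(
        residuals,
        theta0,
        bounds=(lo, hi),
        method="trf",
        xtol=cfg.tol,
        ftol=cfg.tol,
        gtol=cfg.tol,
        max_nfev=cfg.max_nfev,
    )
    converged = bool(res.success)
    if not converged:
        fit_warnings.append(f"fit did not converge: {res.message}")
        warnings.warn(fit_warnings[-1], stacklevel=2)
    b0, b1, amps, cents, fwhms = unpack(res.x)
    components = [
        PeakComponent(float(c), float(f), float(max(a, 0.0)), shape=cfg.shape,
                      eta=cfg.eta if cfg.shape == "pseudo_voigt" else 0.0)
        for a, c, f in zip(amps, cents, fwhms)
    ]
    areas: dict[str, float] = {}
    band_components: dict[str, PeakComponent] = {}
    for comp in components:
        name = bands.assign(comp.center)
        if name is None:
            continue
        if name in areas:
            msg = (
                f"two components fell in band {name!r}; "
                "keeping the larger-area one"
            )
            fit_warnings.append(msg)
            if comp.area <= areas[name]:
                continue
        areas[name] = comp.area
        band_components[name] = comp
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return SpectralFit(
        components=components,
        baseline=(float(b0), float(b1)),
        x_ref=x_ref,
        areas=areas,
        band_components=band_components,
        residual_rms=rms,
        converged=converged,
        n_iter=int(res.nfev),
        warnings=fit_warnings,
    )


#: sentinel distinguishing "no component in this band" from a zero area
ABSENT = None


def band_area(fit: SpectralFit, band: str, bands: BandLibrary | None = None) -> float | None:
    """Area of the component assigned to ``band``; None when absent.

    A band with an assigned component of zero amplitude yields 0.0; a band in
    which no fitted component landed yields ``None`` (explicitly "absent"),
    never 0. Unknown band names raise ``KeyError``.
    """
    bands = bands or BandLibrary()
    if band not in bands:
        raise KeyError(f"unknown band {band!r}")
    if not fit.converged:
        raise FitError("band_area requires a converged fit")
    return fit.areas.get(band, ABSENT)


def fwhm_line_profile(positions_um: np.ndarray, values: np.ndarray) -> float:
    """FWHM (um) of a Gaussian + constant offset fitted to a 1-D profile.

    Used to estimate spatial resolution from a line profile across a small
    (sub-resolution) lipid droplet: the profile is then essentially the
    instrument PSF. Invariant to additive offsets and to reversing the
    position axis. Requires >= 7 samples with a single dominant maximum.
    """
    pos = np.asarray(positions_um, dtype=float)
    val = np.asarray(values, dtype=float)
    if pos.size != val.size:
        raise FormatError("positions and values must have equal length")
    if pos.size < 7:
        raise EstimationError("need at least 7 samples for an FWHM estimate")
    span = float(pos.max() - pos.min())
    if span <= 0:
        raise EstimationError("degenerate position axis")
    offset0 = float(np.min(val))
    amp0 = float(np.max(val) - offset0)
    if amp0 <= 0:
        raise EstimationError("profile has no maximum above its baseline")
    c0 = float(pos[np.argmax(val)])
    sigma0 = span / 6.0

    def gauss_offset(xx, amp, c, sigma, off):
        return amp * np.exp(-((xx - c) ** 2) / (2.0 * sigma**2)) + off

    try:
        popt, _ = optimize.curve_fit(
            gauss_offset,
            pos,
            val,
            p0=[amp0, c0, sigma0, offset0],
            bounds=([0.0, pos.min() - span, 1e-6 * span, -np.inf],
                    [np.inf, pos.max() + span, 10.0 * span, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise EstimationError(f"profile fit did not converge: {exc}") from exc
    sigma = float(popt[2])
    if FWHM_PER_SIGMA * sigma > span:
        raise EstimationError(
            "fitted width spans more than half the profile; widen the profile"
        )
    return FWHM_PER_SIGMA * sigma
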