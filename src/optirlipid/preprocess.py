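"""Spectrum and image conditioning applied before any fitting.

Order matters and is fixed: raw point spectra are divided by the IR laser
power spectrum, then normalized to the protein (amide-I, 1654 cm^-1) anchor,
then averaged per cell (at least 3 pinpoint spectra per cell). Channel images
are divided by the IR power at their wavenumber. The 1780-2030 cm^-1 range,
where no peaks occur, is masked out of fitting but the data are retained.

Both quantification ratios (azide/carbonyl and carbonyl/amide-I) are invariant
to any positive global rescaling of the raw spectrum, because every stage here
is a pointwise positive scaling.
"""

from __future__ import annotations

import numpy as np

from .exceptions import (
    AxisMismatchError,
    CoverageError,
    FormatError,
    NormalizationError,
)
from .formats import (
    AMIDE_I_ANCHOR,
    BandLibrary,
    ChannelImage,
    PowerSpectrum,
    Spectrum,
)


def power_normalize_spectrum(s: Spectrum, p: PowerSpectrum) -> Spectrum:
    """Divide a raw spectrum by the IR laser power, interpolated on its axis.

    The power spectrum must cover the full axis of ``s``; power is linearly
    interpolated. Zero or negative power is an error, never a silent divide.
    """
    if s.power_normalized:
        raise NormalizationError("spectrum is already power-normalized")
    power = p.at(s.wavenumbers)  # raises CoverageError if not covered
    power = np.asarray(power, dtype=float)
    if np.any(power <= 0):
        raise NormalizationError("interpolated IR power is not strictly positive")
    return s.replace(intensity=s.intensity / power, power_normalized=True)


def amide_normalize(
    s: Spectrum, bands: BandLibrary | None = None, anchor: float | None = None
) -> Spectrum:
    """Normalize to total protein content at the amide-I anchor (1654 cm^-1).

    The divisor is the linearly interpolated intensity at exactly the anchor
    wavenumber (not a local maximum); after normalization the anchor value is
    1. Idempotent: normalizing an already-normalized spectrum returns it
    unchanged.
    """
    if not s.power_normalized:
        raise NormalizationError("power-normalize before amide normalization")
    if anchor is None:
        anchor = bands["amide_I"].center if bands is not None else AMIDE_I_ANCHOR
    if s.amide_normalized:
        return s.replace()
    value = s.value_at(anchor)  # raises AxisRangeError if anchor outside axis
    if value <= 0:
        raise NormalizationError(
            f"amide-I anchor intensity {value:g} at {anchor:g} cm^-1 is not positive"
        )
    return s.replace(intensity=s.intensity / value, amide_normalized=True)


def mask_silent_gap(s: Spectrum, bands: BandLibrary | None = None) -> Spectrum:
    """Exclude the peak-free 1780-2030 cm^-1 range from fitting and plotting.

    Points inside the closed interval are flagged in ``excluded``; intensities
    are retained, never deleted.
    """
    lo, hi = (bands.silent_gap if bands is not None else (1780.0, 2030.0))
    in_gap = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    return s.replace(excluded=s.excluded | in_gap)


def average_cell_spectrum(spectra: list[Spectrum], min_n: int = 3) -> Spectrum:
    """Pointwise mean of >= ``min_n`` normalized pinpoint spectra of one cell.

    All inputs must be amide-normalized and share an identical axis. The
    pipeline's canonical order is normalize-then-average; averaging first
    would weight cells by their absolute signal. The result records the
    number of inputs and their source ids in ``meta``.
    """
    if len(spectra) < min_n:
        raise FormatError(
            f"need at least {min_n} pinpoint spectra per cell, got {len(spectra)}"
        )
    first = spectra[0]
    for s in spectra[1:]:
        if s.wavenumbers.shape != first.wavenumbers.shape or not np.allclose(
            s.wavenumbers, first.wavenumbers
        ):
            raise AxisMismatchError("spectra to be averaged must share one axis")
    if not all(s.amide_normalized for s in spectra):
        raise NormalizationError("average requires amide-normalized spectra")
    mean = np.mean([s.intensity for s in spectra], axis=0)
    excluded = np.logical_or.reduce([s.excluded for s in spectra])
    meta = dict(first.meta)
    meta["n_averaged"] = len(spectra)
    meta["source_ids"] = [s.meta.get("id") for s in spectra]
    return Spectrum(
        first.wavenumbers.copy(),
        mean,
        power_normalized=True,
        amide_normalized=True,
        excluded=excluded,
        meta=meta,
    )


def power_normalize_image(img: ChannelImage, p: PowerSpectrum) -> ChannelImage:
    """Divide all pixels by the IR power at the image's wavenumber."""
    if img.power_normalized:
        raise NormalizationError("image is already power-normalized")
    try:
        power = p.at(img.wavenumber)
    except CoverageError:
        raise
    return ChannelImage(
        img.pixels / power,
        img.pixel_size_um,
        img.wavenumber,
        power_normalized=True,
        meta=dict(img.meta),
    )


def max_normalize_for_display(s: Spectrum) -> Spectrum:
    """Scale so the maximum over unmasked points is 1 (display only).

    This mirrors how reference spectra are commonly shown; quantification
    never uses it.
    """
    usable = s.intensity[~s.excluded]
    peak = float(np.max(usable))
    if peak <= 0:
        raise NormalizationError("maximum intensity is not positive")
    return s.replace(intensity=s.intensity / peak)
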