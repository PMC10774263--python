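"""Canonical data model and file I/O for OPTIR spectra, images and tables.

The data model mirrors what an OPTIR instrument exports: single-point spectra
(two-column delimited text, wavenumber in cm^-1 vs photothermal intensity),
single-wavenumber channel images (grayscale TIFF), IR laser power spectra,
integer label masks for ROIs/cells, and the per-cell metrics table produced by
the quantification stage.

Conventions
-----------
* Wavenumber axes are strictly increasing, in cm^-1, within [900, 2400].
* Pixel coordinates are 0-based ``(row, col)``; the centre of pixel ``(i, j)``
  sits at ``((i + 0.5) * pixel_size, (j + 0.5) * pixel_size)`` micrometres.
* Delimited text accepts comma, tab or semicolon; comma is canonical output.
* Missing metric values are written as empty fields, never sentinel numbers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .exceptions import (
    AxisRangeError,
    FormatError,
    GeometryError,
    ParseError,
)

WAVENUMBER_MIN = 900.0
WAVENUMBER_MAX = 2400.0

#: Anchor used for protein (amide-I) normalization, cm^-1.
AMIDE_I_ANCHOR = 1654.0


def _validate_axis(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise AxisRangeError("wavenumber axis must be 1-D with at least 2 points")
    if not np.all(np.isfinite(values)):
        raise AxisRangeError("wavenumber axis contains non-finite values")
    if np.any(np.diff(values) <= 0):
        raise AxisRangeError("wavenumber axis must be strictly increasing")
    if values[0] < WAVENUMBER_MIN or values[-1] > WAVENUMBER_MAX:
        raise AxisRangeError(
            f"axis [{values[0]:g}, {values[-1]:g}] cm^-1 outside supported "
            f"range [{WAVENUMBER_MIN:g}, {WAVENUMBER_MAX:g}]"
        )
    return values


@dataclass
class Spectrum:
    """One wavenumber-indexed intensity trace with normalization provenance.

    Parameters
    ----------
    wavenumbers
        Strictly increasing axis in cm^-1, within [900, 2400].
    intensity
        Photothermal intensity (a.u.), same length as the axis, finite.
    power_normalized
        True once divided by the IR laser power spectrum.
    amide_normalized
        True once divided by the interpolated intensity at the amide-I anchor
        (1654 cm^-1); in that state the anchor value is exactly 1.
    excluded
        Boolean mask of points excluded from fitting/plotting (e.g. the
        1780-2030 cm^-1 gap where no peaks occur). Data are kept, not deleted.
    meta
        Free-form provenance (sample id, cell id, stage position, ...).
    """

    wavenumbers: np.ndarray
    intensity: np.ndarray
    power_normalized: bool = False
    amide_normalized: bool = False
    excluded: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = _validate_axis(self.wavenumbers)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.wavenumbers.shape:
            raise FormatError(
                f"intensity length {self.intensity.size} != axis length "
                f"{self.wavenumbers.size}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise FormatError("spectrum intensities must be finite")
        if self.excluded is None:
            self.excluded = np.zeros(self.wavenumbers.size, dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
            if self.excluded.shape != self.wavenumbers.shape:
                raise FormatError("excluded mask length != axis length")
        if self.amide_normalized:
            anchor = self.value_at(AMIDE_I_ANCHOR)
            if abs(anchor - 1.0) > 1e-9:
                raise FormatError(
                    f"amide_normalized spectrum has anchor value {anchor!r}, "
                    "expected 1 within 1e-9"
                )

    def value_at(self, wavenumber: float) -> float:
        """Linearly interpolated intensity at ``wavenumber`` (cm^-1)."""
        if not (self.wavenumbers[0] <= wavenumber <= self.wavenumbers[-1]):
            raise AxisRangeError(
                f"{wavenumber:g} cm^-1 outside spectrum axis "
                f"[{self.wavenumbers[0]:g}, {self.wavenumbers[-1]:g}]"
            )
        return float(np.interp(wavenumber, self.wavenumbers, self.intensity))

    def replace(self, **kwargs) -> "Spectrum":
        """Return a copy with selected fields replaced (arrays are copied)."""
        fields = dict(
            wavenumbers=self.wavenumbers.copy(),
            intensity=self.intensity.copy(),
            power_normalized=self.power_normalized,
            amide_normalized=self.amide_normalized,
            excluded=self.excluded.copy(),
            meta=dict(self.meta),
        )
        fields.update(kwargs)
        return Spectrum(**fields)


@dataclass
class PowerSpectrum:
    """IR laser power (mW) versus wavenumber, used for power normalization."""

    wavenumbers: np.ndarray
    power_mw: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = _validate_axis(self.wavenumbers)
        self.power_mw = np.asarray(self.power_mw, dtype=float)
        if self.power_mw.shape != self.wavenumbers.shape:
            raise FormatError("power length != axis length")
        if not np.all(np.isfinite(self.power_mw)) or np.any(self.power_mw <= 0):
            raise FormatError("IR power must be finite and strictly positive")

    def at(self, wavenumber) -> np.ndarray | float:
        """Linear interpolation of power; raises if outside coverage."""
        wn = np.asarray(wavenumber, dtype=float)
        if np.any(wn < self.wavenumbers[0]) or np.any(wn > self.wavenumbers[-1]):
            from .exceptions import CoverageError

            raise CoverageError(
                "requested wavenumbers extend beyond the power spectrum axis "
                f"[{self.wavenumbers[0]:g}, {self.wavenumbers[-1]:g}] cm^-1"
            )
        out = np.interp(wn, self.wavenumbers, self.power_mw)
        return float(out) if np.ndim(wavenumber) == 0 else out


@dataclass
class ChannelImage:
    """Single-wavenumber OPTIR raster (photothermal signal, a.u.)."""

    pixels: np.ndarray
    pixel_size_um: float
    wavenumber: float
    power_normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise FormatError(f"channel image must be 2-D, got {self.pixels.ndim}-D")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("channel image pixels must be finite")
        if not (self.pixel_size_um > 0):
            raise GeometryError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not (WAVENUMBER_MIN <= self.wavenumber <= WAVENUMBER_MAX):
            raise AxisRangeError(
                f"wavenumber {self.wavenumber:g} outside "
                f"[{WAVENUMBER_MIN:g}, {WAVENUMBER_MAX:g}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def fov_um(self) -> tuple[float, float]:
        """Field of view (height, width) in micrometres."""
        return (
            self.pixels.shape[0] * self.pixel_size_um,
            self.pixels.shape[1] * self.pixel_size_um,
        )


@dataclass
class LabelMask:
    """Integer ROI/cell mask: 0 = background, k > 0 = region k."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise FormatError("label mask must be 2-D")
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(np.asarray(labels, dtype=float))
            if not np.allclose(labels, rounded):
                raise FormatError("label mask must hold integers")
            labels = rounded.astype(np.int64)
        if labels.min() < 0:
            raise FormatError("label mask must be non-negative")
        self.labels = labels.astype(np.int64)
        if not (self.pixel_size_um > 0):
            raise GeometryError("pixel_size_um must be > 0")

    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass(frozen=True)
class Band:
    """A named spectral band: nominal centre and half-width search window."""

    center: float
    halfwidth: float

    def contains(self, wavenumber: float) -> bool:
        return abs(wavenumber - self.center) <= self.halfwidth

    @property
    def lo(self) -> float:
        return self.center - self.halfwidth

    @property
    def hi(self) -> float:
        return self.center + self.halfwidth


#: The three bands used for quantification (areas enter the metric ratios).
QUANTIFICATION_BANDS = ("amide_I", "lipid_carbonyl", "azide")


@dataclass
class BandLibrary:
    """Named mid-IR bands of the azide-tagged palmitic-acid assay.

    amide_I (~1654 cm^-1) is the total-protein normalizer, lipid_carbonyl
    (~1740-1744 cm^-1, ester C=O stretch) the total-lipid proxy, and azide
    (~2096 cm^-1, -N3 stretch) marks newly synthesized lipids and sits in the
    cell-silent region where endogenous biomolecules do not absorb.
    """

    bands: dict[str, Band] = field(default_factory=lambda: dict(DEFAULT_BANDS))
    #: spectral range omitted from fits/plots: no observable peaks there
    silent_gap: tuple[float, float] = (1780.0, 2030.0)
    #: cell-silent region where only the probe absorbs
    silent_region: tuple[float, float] = (2000.0, 2320.0)

    def __post_init__(self) -> None:
        quant = [self.bands[name] for name in QUANTIFICATION_BANDS if name in self.bands]
        if len(quant) != len(QUANTIFICATION_BANDS):
            raise FormatError(
                f"band library must define all of {QUANTIFICATION_BANDS}"
            )
        for i, a in enumerate(quant):
            for b in quant[i + 1 :]:
                if a.lo < b.hi and b.lo < a.hi:
                    raise FormatError(
                        "quantification band windows must not overlap: "
                        f"[{a.lo:g},{a.hi:g}] vs [{b.lo:g},{b.hi:g}]"
                    )

    def __getitem__(self, name: str) -> Band:
        return self.bands[name]

    def __contains__(self, name: str) -> bool:
        return name in self.bands

    def assign(self, wavenumber: float) -> str | None:
        """Band name whose window contains ``wavenumber``, else None."""
        for name, band in self.bands.items():
            if band.contains(wavenumber):
                return name
        return None


DEFAULT_BANDS: dict[str, Band] = {
    "amide_I": Band(1654.0, 20.0),
    "amide_II": Band(1550.0, 20.0),
    "lipid_carbonyl": Band(1742.0, 22.0),  # reported at both 1740 and 1744
    "azide": Band(2096.0, 30.0),
    "ch_bend": Band(1473.0, 15.0),
    "coc_ester": Band(1170.0, 20.0),
    "pa_carbonyl": Band(1700.0, 15.0),
}


# ---------------------------------------------------------------------------
# Delimited-text spectra
# ---------------------------------------------------------------------------

_DELIMITERS = (",", "\t", ";")


def _sniff_delimiter(lines: Sequence[str]) -> str:
    counts = {d: sum(line.count(d) for line in lines) for d in _DELIMITERS}
    best = max(counts, key=counts.get)  # type: ignore[arg-type]
    if counts[best] == 0:
        # whitespace-separated fallback
        return ""
    return best


def read_spectrum(path: str | Path, meta: Mapping | None = None) -> Spectrum:
    """Read a two-column delimited-text spectrum (wavenumber, intensity).

    Accepts comma/tab/semicolon (or whitespace) separators and an optional
    single header line. Rows are sorted by wavenumber and duplicate
    wavenumbers are collapsed by averaging their intensities.
    """
    path = Path(path)
    raw_lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not raw_lines:
        raise ParseError(f"{path}: no data rows")
    delim = _sniff_delimiter(raw_lines[:20])
    rows: list[tuple[float, float]] = []
    for lineno, line in enumerate(raw_lines, start=1):
        parts = line.split(delim) if delim else line.split()
        parts = [p.strip() for p in parts if p.strip() != ""]
        if len(parts) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
        try:
            wn, it = float(parts[0]), float(parts[1])
        except ValueError:
            if lineno == 1:  # optional header
                continue
            raise ParseError(f"{path}: line {lineno}: non-numeric row {line!r}") from None
        rows.append((wn, it))
    if len(rows) < 2:
        raise ParseError(f"{path}: fewer than 2 numeric rows")
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    # collapse duplicate wavenumbers by mean
    wn_unique, inverse = np.unique(arr[:, 0], return_inverse=True)
    sums = np.zeros_like(wn_unique)
    counts = np.zeros_like(wn_unique)
    np.add.at(sums, inverse, arr[:, 1])
    np.add.at(counts, inverse, 1.0)
    intensity = sums / counts
    return Spectrum(wn_unique, intensity, meta=dict(meta or {}))


def write_spectrum(spectrum: Spectrum, path: str | Path, header: bool = True) -> None:
    """Write a spectrum as canonical comma-separated two-column text."""
    path = Path(path)
    lines = []
    if header:
        lines.append("wavenumber_cm-1,intensity")
    lines.extend(
        f"{wn:.6g},{it:.10g}" for wn, it in zip(spectrum.wavenumbers, spectrum.intensity)
    )
    path.write_text("\n".join(lines) + "\n")


def read_power_spectrum(path: str | Path) -> PowerSpectrum:
    """Read a two-column delimited power spectrum (wavenumber, power in mW)."""
    s = read_spectrum(path)
    return PowerSpectrum(s.wavenumbers, s.intensity)


def write_power_spectrum(p: PowerSpectrum, path: str | Path) -> None:
    path = Path(path)
    lines = ["wavenumber_cm-1,power_mw"]
    lines.extend(f"{wn:.6g},{pw:.10g}" for wn, pw in zip(p.wavenumbers, p.power_mw))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TIFF channel images and label masks
# ---------------------------------------------------------------------------


def read_channel_image(
    path: str | Path, pixel_size_um: float, wavenumber: float
) -> ChannelImage:
    """Read a single-plane grayscale TIFF as a :class:`ChannelImage`.

    Multi-plane or RGB inputs are rejected: OPTIR channel images are one
    grayscale raster per wavenumber.
    """
    if not (pixel_size_um > 0):
        raise GeometryError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected single-plane grayscale TIFF, got shape {arr.shape}"
        )
    return ChannelImage(arr.astype(float), pixel_size_um, wavenumber)


def write_channel_image(img: ChannelImage, path: str | Path) -> None:
    tifffile.imwrite(str(path), img.pixels.astype(np.float32))


def read_label_mask(path: str | Path, pixel_size_um: float) -> LabelMask:
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise FormatError(f"{path}: label mask must be single-plane, got {arr.shape}")
    return LabelMask(arr.astype(np.int64), pixel_size_um)


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    tifffile.imwrite(str(path), mask.labels.astype(np.int32))


# ---------------------------------------------------------------------------
# Metrics table
# ---------------------------------------------------------------------------

METRICS_COLUMNS = ("sample", "cell_id", "n_spectra", "norm_total_lipid", "new_lipid_fraction")


def write_metrics_table(records: Iterable, path: str | Path) -> None:
    """Write per-cell metric records as CSV.

    One row per cell with columns ``sample, cell_id, n_spectra,
    norm_total_lipid, new_lipid_fraction``. Undefined metrics (e.g. a missing
    azide fit without the absent-as-zero convention) are written as empty
    fields so they can never silently propagate into downstream ratios.
    """
    records = list(records)
    if not records:
        raise FormatError("cannot write an empty metrics table")
    rows = []
    for r in records:
        d = dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
        rows.append({k: d.get(k) for k in METRICS_COLUMNS})
    df = pd.DataFrame(rows, columns=list(METRICS_COLUMNS))
    df.to_csv(path, index=False, float_format="%.10g", na_rep="")


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    """Read a metrics CSV back; empty fields become NaN."""
    df = pd.read_csv(path)
    missing = set(METRICS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: metrics table missing columns {sorted(missing)}")
    return df
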