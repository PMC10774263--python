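"""End-to-end orchestration: dataset layout, run driver, reporting.

A dataset directory holds what an instrument session exports plus what the
phantom generator writes:

.. code-block:: text

    dataset/
      manifest.json          # pixel sizes, image wavenumbers, sample names
      power_spectrum.csv     # IR laser power vs wavenumber
      spectra/<sample>__<cell>__<i>.csv   # raw point spectra
      images/<sample>__<band>.tif         # raw single-wavenumber images
      masks/<sample>__cells.tif           # integer cell labels
      truth.json             # ground truth (phantom datasets only)

:func:`run_pipeline` executes preprocess -> peakfit -> metrics -> imaging ->
statistics over such a directory, writing a metrics CSV, per-cell fit records,
ratio TIFFs, a comparison JSON and a plain-text report whose header embeds the
resolved config hash and seed. Identical inputs and config give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import imaging as im
from . import metrics as met
from . import preprocess as pre
from . import stats as st
from .config import RunConfig
from .exceptions import OptirError, PipelineError
from .formats import (
    BandLibrary,
    ChannelImage,
    LabelMask,
    read_channel_image,
    read_label_mask,
    read_power_spectrum,
    read_spectrum,
    write_channel_image,
    write_label_mask,
    write_metrics_table,
    write_power_spectrum,
    write_spectrum,
)
from .peakfit import detect_peaks, fit_spectrum
from .phantoms import (
    CellPhantomSpec,
    make_cell_image,
    make_power_spectrum,
    make_spectrum,
)


# ---------------------------------------------------------------------------
# Phantom dataset writer
# ---------------------------------------------------------------------------


def write_phantom_dataset(
    outdir: str | Path,
    seed: int,
    conditions: dict[str, dict] | None = None,
    spectra_per_cell: int = 3,
    noise_sd: float = 0.01,
    pixel_size_um: float = 0.5,
    image_cells: int = 2,
    lipid_weight: float = 0.5,
    lipid_cv: float = 0.15,
    scale_cv: float = 0.15,
) -> Path:
    """Write a two-condition cell phantom dataset in the pipeline layout.

    Each condition has ``n_cells`` cells with a true newly-synthesized-lipid
    fraction ``fraction``; per-cell lipid weight and per-spectrum global scale
    are log-normally jittered so power and amide normalization do real work.
    Raw spectra and images carry the IR power curve; ``truth.json`` records
    the generating parameters.
    """
    conditions = conditions or {
        "control": {"n_cells": 8, "fraction": 0.3},
        "treated": {"n_cells": 8, "fraction": 0.6},
    }
    out = Path(outdir)
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    (out / "images").mkdir(exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)
    power = make_power_spectrum()
    write_power_spectrum(power, out / "power_spectrum.csv")

    manifest: dict = {
        "pixel_size_um": pixel_size_um,
        "samples": sorted(conditions),
        "images": {},
        "masks": {},
    }
    truth: dict = {"seed": seed, "conditions": {}, "cells": {}}
    for sample in sorted(conditions):
        params = conditions[sample]
        n_cells, fraction = int(params["n_cells"]), float(params["fraction"])
        truth["conditions"][sample] = {"n_cells": n_cells, "fraction": fraction}
        for cell in range(1, n_cells + 1):
            lipid = lipid_weight * float(rng.lognormal(0.0, lipid_cv))
            for i in range(spectra_per_cell):
                scale = float(rng.lognormal(0.0, scale_cv))
                s, _ = make_spectrum(
                    {
                        "protein": scale,
                        "total_lipid": scale * lipid,
                        "azide": scale * lipid * fraction,
                    },
                    noise_sd=noise_sd * scale,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    apply_power=power,
                )
                write_spectrum(s, out / "spectra" / f"{sample}__{cell:03d}__{i}.csv")
            truth["cells"][f"{sample}__{cell:03d}"] = {
                "lipid_weight": lipid,
                "new_lipid_fraction": fraction,
                "norm_total_lipid": lipid,
            }
        # one small image field per condition
        spec = CellPhantomSpec(
            fov_um=40.0,
            n_cells=image_cells,
            new_lipid_fraction=fraction,
        )
        images, img_truth = make_cell_image(
            spec,
            pixel_size_um=pixel_size_um,
            noise_snr=100.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        manifest["images"][sample] = {}
        for band, img in images.items():
            raw = ChannelImage(
                img.pixels * power.at(img.wavenumber),
                img.pixel_size_um,
                img.wavenumber,
                power_normalized=False,
            )
            fname = f"{sample}__{band}.tif"
            write_channel_image(raw, out / "images" / fname)
            manifest["images"][sample][band] = {
                "file": f"images/{fname}",
                "wavenumber": img.wavenumber,
            }
        mask_file = f"{sample}__cells.tif"
        write_label_mask(img_truth.cell_mask, out / "masks" / mask_file)
        manifest["masks"][sample] = f"masks/{mask_file}"
        truth["conditions"][sample]["image_cell_truths"] = {
            str(k): v for k, v in img_truth.cell_truths.items()
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    output_dir: Path
    metrics_csv: Path
    report_txt: Path
    records: list
    comparison: dict | None
    warnings: list[str]


def _load_dataset(input_dir: Path):
    manifest_path = input_dir / "manifest.json"
    if not manifest_path.exists():
        raise OptirError(f"no manifest.json in {input_dir}")
    manifest = json.loads(manifest_path.read_text())
    power = read_power_spectrum(input_dir / "power_spectrum.csv")
    spectra_dir = input_dir / "spectra"
    files = sorted(spectra_dir.glob("*.csv")) if spectra_dir.is_dir() else []
    if not files:
        raise OptirError(f"no point spectra found under {spectra_dir}")
    spectra = []
    for f in files:
        parts = f.stem.split("__")
        if len(parts) != 3:
            raise OptirError(
                f"{f.name}: expected <sample>__<cell>__<index>.csv"
            )
        s = read_spectrum(f, meta={"sample": parts[0], "cell": parts[1], "id": f.stem})
        spectra.append(s)
    px = float(manifest.get("pixel_size_um", 0.5))
    images: dict[str, dict[str, ChannelImage]] = {}
    for sample, bands_ in manifest.get("images", {}).items():
        images[sample] = {
            band: read_channel_image(
                input_dir / entry["file"], px, float(entry["wavenumber"])
            )
            for band, entry in bands_.items()
        }
    masks: dict[str, LabelMask] = {
        sample: read_label_mask(input_dir / rel, px)
        for sample, rel in manifest.get("masks", {}).items()
    }
    return manifest, power, spectra, images, masks


def run_pipeline(
    config: RunConfig, input_dir: str | Path, output_dir: str | Path
) -> PipelineResult:
    """Execute the full analysis over a dataset directory.

    Raises :class:`PipelineError` naming the failing stage; on success every
    fit converged and the report, metrics CSV, ratio TIFFs, per-cell ratio
    CSVs and (for two-sample datasets) the comparison JSON are in
    ``output_dir`` together with the resolved configuration.
    """
    input_dir = Path(input_dir)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bands = BandLibrary()
    all_warnings: list[str] = []

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except OptirError as exc:
                raise PipelineError(name, str(exc)) from exc

        return wrap

    # -- io -------------------------------------------------------------
    manifest, power, spectra, images, masks = stage("io")(_load_dataset, input_dir)

    # -- preprocess -------------------------------------------------------
    def _preprocess():
        by_cell: dict[tuple[str, str], list] = {}
        for s in spectra:
            s1 = pre.power_normalize_spectrum(s, power)
            s2 = pre.amide_normalize(s1, bands, anchor=config.preprocess.amide_anchor)
            s3 = pre.mask_silent_gap(s2, bands)
            key = (s.meta["sample"], s.meta["cell"])
            by_cell.setdefault(key, []).append(s3)
        return {
            key: pre.average_cell_spectrum(group, config.preprocess.min_spectra_per_cell)
            for key, group in sorted(by_cell.items())
        }

    cell_spectra = stage("preprocess")(_preprocess)

    # -- peakfit ----------------------------------------------------------
    def _fit_all():
        fits = {}
        for key, s in cell_spectra.items():
            seeds = detect_peaks(
                s,
                config.fit.smooth_window,
                config.fit.smooth_poly,
                config.fit.prominence_frac,
            )
            fit = fit_spectrum(s, seeds, bands, config.fit)
            all_warnings.extend(f"{key}: {w}" for w in fit.warnings)
            if not fit.converged:
                raise PipelineError("peakfit", f"fit for cell {key} did not converge")
            fits[key] = fit
        return fits

    fits = stage("peakfit")(_fit_all)
    fits_json = {
        f"{sample}__{cell}": {
            "areas": fit.areas,
            "residual_rms": fit.residual_rms,
            "converged": fit.converged,
            "components": [dataclasses.asdict(c) for c in fit.components],
        }
        for (sample, cell), fit in fits.items()
    }
    (outdir / "fits.json").write_text(json.dumps(fits_json, indent=1, sort_keys=True))

    # -- metrics ----------------------------------------------------------
    def _metrics():
        records = []
        for (sample, cell), fit in sorted(fits.items()):
            records.append(
                met.cell_metrics(
                    fit,
                    sample=sample,
                    cell_id=cell,
                    n_spectra=cell_spectra[(sample, cell)].meta["n_averaged"],
                    bands=bands,
                    absent_as_zero=config.metrics.absent_as_zero,
                )
            )
        return records

    records = stage("metrics")(_metrics)
    metrics_csv = outdir / "metrics.csv"
    write_metrics_table(records, metrics_csv)

    # -- imaging ----------------------------------------------------------
    def _imaging():
        rows = []
        for sample, chans in sorted(images.items()):
            if "azide" not in chans or "lipid_carbonyl" not in chans:
                continue
            num = pre.power_normalize_image(chans["azide"], power)
            den = pre.power_normalize_image(chans["lipid_carbonyl"], power)
            ratio = im.ratio_image(num, den, config.imaging.ratio_threshold_frac)
            out_tif = outdir / f"ratio__{sample}.tif"
            write_channel_image(
                ChannelImage(
                    np.where(ratio.valid_mask, ratio.values, 0.0),
                    ratio.pixel_size_um,
                    ratio.numerator_wavenumber,
                    power_normalized=True,
                ),
                out_tif,
            )
            if sample in masks:
                means = im.cell_mean_ratio(
                    ratio, masks[sample], config.imaging.min_valid_pixels
                )
                rows.extend(
                    {"sample": sample, "cell_id": k, "mean_ratio": v}
                    for k, v in sorted(means.items())
                )
        return rows

    ratio_rows = stage("imaging")(_imaging)
    if ratio_rows:
        import pandas as pd

        pd.DataFrame(ratio_rows).to_csv(
            outdir / "cell_ratios.csv", index=False, float_format="%.10g"
        )

    # -- statistics -------------------------------------------------------
    def _statistics():
        samples = sorted({r.sample for r in records})
        if len(samples) != 2:
            return None
        groups = []
        for sample in samples:
            vals = [
                r.new_lipid_fraction
                for r in records
                if r.sample == sample and r.new_lipid_fraction is not None
            ]
            groups.append(np.asarray(vals))
        if any(g.size < 2 for g in groups):
            return None
        cmp_ = st.two_sample_test(
            groups[0],
            groups[1],
            welch=config.stats.welch,
            alpha=config.stats.alpha,
            labels=(samples[0], samples[1]),
        )
        return {
            "metric": "new_lipid_fraction",
            "groups": list(cmp_.group_labels),
            "n": [int(g.size) for g in cmp_.values],
            "means": [float(g.mean()) for g in cmp_.values],
            "test": cmp_.test_name,
            "statistic": cmp_.statistic,
            "p_value": cmp_.p_value,
            "alpha": cmp_.alpha,
            "df": cmp_.degrees_of_freedom,
        }

    comparison = stage("statistics")(_statistics)
    if comparison is not None:
        (outdir / "comparison.json").write_text(
            json.dumps(comparison, indent=1, sort_keys=True)
        )

    # -- report -----------------------------------------------------------
    config.to_yaml(outdir / "config_resolved.yaml")
    lines = [
        "optirlipid pipeline report",
        f"config_hash: {config.digest()}",
        f"seed: {config.seed}",
        f"input: {input_dir}",
        f"cells_fitted: {len(fits)}",
        f"fit_warnings: {len(all_warnings)}",
    ]
    lines.extend(f"  warning: {w}" for w in all_warnings)
    if comparison is not None:
        lines.append(
            "comparison: {groups[0]} vs {groups[1]} p={p_value:.3g} ({test})".format(
                **comparison
            )
        )
    report = outdir / "report.txt"
    report.write_text("\n".join(lines) + "\n")
    return PipelineResult(
        output_dir=outdir,
        metrics_csv=metrics_csv,
        report_txt=report,
        records=records,
        comparison=comparison,
        warnings=all_warnings,
    )
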