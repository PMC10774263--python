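"""End-to-end pipeline on a two-condition phantom dataset.

Writes a phantom dataset (raw point spectra and channel images for a control
and a treated condition with true new-lipid fractions 0.3 vs 0.6), then runs
the full analysis: power/amide normalization, per-cell averaging, whole-
spectrum fitting, metric extraction, ratio imaging, and the two-sided
two-sample t-test between conditions.
"""

import tempfile
from pathlib import Path

from optirlipid import RunConfig, run_pipeline, write_phantom_dataset

with tempfile.TemporaryDirectory() as tmp:
    dataset = write_phantom_dataset(
        Path(tmp) / "dataset",
        seed=21,
        conditions={
            "control": {"n_cells": 6, "fraction": 0.3},
            "treated": {"n_cells": 6, "fraction": 0.6},
        },
    )
    result = run_pipeline(RunConfig(seed=21), dataset, Path(tmp) / "out")

    print("per-cell metrics (sample, cell, norm_total_lipid, new_lipid_fraction):")
    for rec in result.records:
        print(
            f"  {rec.sample:8s} {rec.cell_id}  "
            f"{rec.norm_total_lipid:.3f}  {rec.new_lipid_fraction:.3f}"
        )
    cmp_ = result.comparison
    print(
        f"{cmp_['test']}: groups {cmp_['groups']}, "
        f"means {[round(m, 3) for m in cmp_['means']]}, p = {cmp_['p_value']:.2e}"
    )
    print(
        "-> the treated condition's newly synthesized lipid fraction is about "
        "twice the control's, and the difference is statistically significant"
    )
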