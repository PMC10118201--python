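#!/usr/bin/env python
"""Simulate the default synthetic cohort and write its tables.

Generates a GDM-screening pregnancy cohort (48 controls, 41 cases) with
three raw-area glycan panels and the clinical marker table, and writes
everything under results/cohort/ for the downstream analysis scripts.
"""
from pathlib import Path

import glycassoc as ga
from glycassoc.tables_io import write_peak_table

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 1000

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    peaks, clinical, _ = ga.generate_cohort(ga.SynthConfig(seed=SEED))
    for panel_id, pt in peaks.items():
        write_peak_table(pt, OUT / f"peaks_{panel_id}.csv")
        print(f"{panel_id}: {pt.n_samples} samples x {pt.schema.n_peaks} peaks")
    clinical.data.rename_axis("sample_id").to_csv(OUT / "clinical.csv")
    sizes = clinical.group_sizes
    print(f"clinical table: {sizes['control']} control / {sizes['case']} case, "
          f"{len(clinical.markers)} markers -> {OUT}")
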