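#!/usr/bin/env python
"""Firing rate, burstiness and ISI CV per unit and pharmacological epoch.

Writes the per-unit table (results/firing_metrics.tsv) and prints the
group summary (mean ± SEM and median [Q1-Q3] per condition) in the style
used for condition-wise activity tables.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from epicortex import core
from epicortex.firing import burstiness_index, firing_rate, isi_cv

ROOT = Path(__file__).resolve().parent.parent / "results"
SYN = ROOT / "synthetic"


def main() -> None:
    units = core.load_units(SYN / "spikes.tsv", SYN / "waveforms.tsv")
    epochs = core.segment_epochs(core.load_epoch_annotations(SYN / "epochs.yaml"),
                                 guard_s=30.0)
    rows = []
    for u in units.units:
        for epoch in epochs:
            rows.append({
                "unit_id": u.unit_id, "condition": epoch.label,
                "rate_hz": firing_rate(u.spike_times, epoch),
                "burstiness": burstiness_index(u.spike_times, epoch),
                "isi_cv": isi_cv(u.spike_times, epoch),
            })
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "firing_metrics.tsv", sep="\t", index=False,
              float_format="%.4f")

    print("condition summary (all units):")
    for cond, g in df.groupby("condition", sort=False):
        r = g["rate_hz"]
        b = g["burstiness"]
        print(f"  {cond:9s} rate {r.mean():.2f} ± {r.sem():.2f} Hz, "
              f"median {r.median():.2f} [{r.quantile(.25):.2f}-"
              f"{r.quantile(.75):.2f}]; burstiness {b.mean():.3f} ± {b.sem():.3f}")
    drop = (df.pivot(index="unit_id", columns="condition", values="rate_hz"))
    lower = (drop["NBQX+APV"] < drop["control"]) & (drop["control"] > 0)
    active = drop["control"] > 0
    print(f"\nunits firing less under NBQX+APV than in control: "
          f"{int(lower.sum())}/{int(active.sum())} "
          f"({100 * lower.sum() / active.sum():.1f}%)")


if __name__ == "__main__":
    main()
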