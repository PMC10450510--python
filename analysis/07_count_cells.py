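#!/usr/bin/env python
"""Automated stained-cell counting and volumetric density per group.

Runs the channel-selection + adaptive-threshold + morphology + contour
pipeline on the synthetic micrographs, converts counts to densities with
the recorded tissue areas and the 60-μm section thickness, and compares
group densities with an unpaired test.

Writes results/cell_counts.tsv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import stats

from epicortex.cells import count_cells, density, select_channel

ROOT = Path(__file__).resolve().parent.parent / "results"
SYN = ROOT / "synthetic"


def main() -> None:
    truth = json.loads((SYN / "truth.json").read_text())["images"]
    rows = []
    for name, info in truth.items():
        img = np.asarray(Image.open(SYN / "images" / name))
        gray = select_channel(img)
        res = count_cells(gray, image_id=name)
        dens = density(res.n_cells, info["tissue_area_um2"])
        rows.append({"image": name, "group": info["group"],
                     "n_counted": res.n_cells, "n_true": info["n_cells"],
                     "density_per_1e6um3": round(dens, 2)})
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "cell_counts.tsv", sep="\t", index=False)
    print(df.to_string(index=False))

    err = (df.n_counted - df.n_true).abs() / df.n_true
    print(f"\nmean absolute count error: {100 * err.mean():.1f}%")
    g = {k: v["density_per_1e6um3"].to_numpy() for k, v in df.groupby("group")}
    t, p = stats.ttest_ind(*g.values())
    print("group densities (cells per 10^6 um^3): "
          + ", ".join(f"{k} {v.mean():.1f} ± {v.std(ddof=1)/np.sqrt(len(v)):.1f}"
                      for k, v in g.items()))
    print(f"Welch/Student t-test p = {p:.3f}")


if __name__ == "__main__":
    main()
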