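#!/usr/bin/env python
"""Classify every clustered unit and tabulate class proportions.

Applies the width/autocorrelogram decision tree to the synthetic
recording and compares the assigned labels against the generator's
ground truth.  Writes results/unit_classes.tsv and prints a class
proportion table of the style used for clustered-neuron counts.
"""

import json
from pathlib import Path

import pandas as pd

from epicortex import core
from epicortex.classify import classify_units

ROOT = Path(__file__).resolve().parent.parent / "results"
SYN = ROOT / "synthetic"


def main() -> None:
    units = core.load_units(SYN / "spikes.tsv", SYN / "waveforms.tsv")
    truth = json.loads((SYN / "truth.json").read_text())["unit_class"]
    df = classify_units(units)
    df["true_class"] = df["unit_id"].map(truth)
    df.to_csv(ROOT / "unit_classes.tsv", sep="\t", index=False)

    n = len(df)
    print(f"{n} units classified")
    counts = df["label"].value_counts()
    for label in ("RS-PC", "IB-PC", "UF-PC", "IN", "UC"):
        c = int(counts.get(label, 0))
        print(f"  {label:6s} {c:3d} ({100 * c / n:.1f}%)")
    pc = int(counts.get("RS-PC", 0) + counts.get("IB-PC", 0)
             + counts.get("UF-PC", 0))
    print(f"  all PCs {pc} ({100 * pc / n:.1f}%)")
    recovery = (df["label"] == df["true_class"]).mean()
    print(f"ground-truth recovery: {100 * recovery:.1f}%")
    print(pd.crosstab(df["true_class"], df["label"]).to_string())


if __name__ == "__main__":
    main()
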