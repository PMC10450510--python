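#!/usr/bin/env python
"""EM synapse morphometry statistics over the active-zone table.

Reproduces the structure of the study's synapse tables on the synthetic
records: length summaries by group/region/perforation, perforation and
target contingencies, group comparisons with a normality gate, and the
age-vs-epilepsy regression on per-patient perforation fractions.

Writes results/synapse_{lengths,targets}.tsv and synapse_tests.json.
"""

import json
from pathlib import Path

import pandas as pd

from epicortex.synapse import (age_epilepsy_regression, contingency_test,
                               group_compare, length_summary, load_records,
                               per_patient_perforation, perforated_ratio)

ROOT = Path(__file__).resolve().parent.parent / "results"
SYN = ROOT / "synthetic"


def main() -> None:
    df = load_records(SYN / "synapses.tsv")
    lengths = length_summary(df, ["group", "region", "perforated"])
    lengths.to_csv(ROOT / "synapse_lengths.tsv", sep="\t", index=False,
                   float_format="%.4f")
    print(lengths.round(3).to_string(index=False))

    ratios = perforated_ratio(df, "group")
    print("\nperforated active-zone ratios: " + ", ".join(
        f"{k} {v.count}/{v.total} ({v.percent}%)" for k, v in ratios.items()))
    perf_tab = pd.crosstab(df["group"], df["perforated"]).to_numpy()
    perf_chi = contingency_test(perf_tab)
    print(f"perforation x group chi-square p = {perf_chi.p:.4f}")

    target_tab = pd.crosstab(df["group"], df["target"])
    target_tab.to_csv(ROOT / "synapse_targets.tsv", sep="\t")
    target_chi = contingency_test(target_tab.to_numpy())
    print(f"target x group chi-square p = {target_chi.p:.4f}")

    by_perf = group_compare({
        "non-perforated": df.loc[~df.perforated, "active_zone_length_um"],
        "perforated": df.loc[df.perforated, "active_zone_length_um"]})
    print(f"\nperforated vs non-perforated length: {by_perf['test']}, "
          f"p = {by_perf['p']:.2e}")

    pats = per_patient_perforation(df)
    reg = age_epilepsy_regression(pats)
    print(f"age/epilepsy regression on perforation fraction "
          f"({reg['n']} patients): age p = {reg['p']['age']:.3f}, "
          f"epilepsy p = {reg['p']['epilepsy']:.3f}")

    tests = {
        "perforation_chi2_p": perf_chi.p,
        "target_chi2_p": target_chi.p,
        "length_by_perforation": by_perf,
        "age_epilepsy_regression": reg,
    }
    (ROOT / "synapse_tests.json").write_text(json.dumps(tests, indent=2))


if __name__ == "__main__":
    main()
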