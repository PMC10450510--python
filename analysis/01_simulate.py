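#!/usr/bin/env python
"""Generate the synthetic study bundle every later stage analyses.

One simulated slice recording: four 300-s pharmacological epochs
(control, APV, NBQX+APV, washout) cut from 360-s annotated blocks with a
30-s transition guard; 60 units across the four ground-truth classes
with condition-dependent rates (most units fire less once AMPA/kainate
receptors are blocked); SPA events near 1 Hz in every condition except
NBQX+APV, where population activity is abolished; two planted synaptic
connections (monosynaptic at 2 ms, polysynaptic at 6 ms); an EM
active-zone table at the two patient groups' printed regimes; and four
stained-section micrographs per group.

Writes results/synthetic/{spikes.tsv, waveforms.tsv, epochs.yaml,
spa_events_<condition>.tsv, traces_<condition>.npz, synapses.tsv,
images/*.png, truth.json}.
"""

import json
from pathlib import Path

import numpy as np

from epicortex import core, synth

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"

CONDITION_BLOCKS = [("control", 0.0, 360.0), ("APV", 360.0, 720.0),
                    ("NBQX+APV", 720.0, 1080.0), ("washout", 1080.0, 1440.0)]
# per-condition rate multipliers applied to each unit's base rate
RATE_MULT = {"control": 1.0, "APV": 0.9, "NBQX+APV": 0.5, "washout": 0.4}
SPA_RATE = {"control": 1.0, "APV": 0.8, "washout": 0.7}  # none in NBQX+APV


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "images").mkdir(exist_ok=True)
    cfg = synth.SimConfig(seed=SEED)
    rng = np.random.default_rng(SEED)

    epochs = core.segment_epochs(CONDITION_BLOCKS, guard_s=30.0)
    core.write_epoch_annotations(CONDITION_BLOCKS, OUT / "epochs.yaml")

    templates, gt = synth.make_units(
        cfg, rng, epoch_labels=tuple(l for l, _, _ in CONDITION_BLOCKS))
    for uid in gt.base_rate:
        base = gt.base_rate[uid]["control"]
        for cond, mult in RATE_MULT.items():
            gt.base_rate[uid][cond] = base * mult
    # a third of the units fire more tightly locked to the population events
    for uid in list(gt.spa_multiplier)[::3]:
        gt.spa_multiplier[uid] = 3.0

    all_events = []
    for epoch in epochs:
        if epoch.label not in SPA_RATE:
            continue
        scfg = synth.SimConfig(seed=SEED, spa_rate_hz=SPA_RATE[epoch.label])
        ev = synth.simulate_spa(scfg, epoch.duration, rng, start=epoch.start)
        all_events.append((epoch.label, ev))
        core.write_spa_events(ev, OUT / f"spa_events_{epoch.label.replace('+','_')}.tsv")
        np.savez_compressed(
            OUT / f"traces_{epoch.label.replace('+','_')}.npz",
            time_ms=ev.trace_time_ms, lfpg=ev.lfpg_traces, mua=ev.mua_traces)

    merged = core.SPAEventSet(np.sort(np.concatenate(
        [ev.event_times for _, ev in all_events])))
    trains = synth.simulate_trains(gt, epochs, cfg, rng,
                                   templates=templates, spa_events=merged)

    # plant one monosynaptic and one polysynaptic connection between PCs
    pcs = [u for u in gt.unit_class if gt.unit_class[u] in ("RS-PC", "IB-PC")]
    (pre1, post1), (pre2, post2) = (pcs[0], pcs[1]), (pcs[2], pcs[3])
    for pre, post, lat in ((pre1, post1, 2.0), (pre2, post2, 6.0)):
        t = synth.inject_connection(trains[pre].spike_times,
                                    trains[post].spike_times, lat, 0.3, 0.3, rng)
        trains[post].spike_times = t
        gt.connections.append((pre, post, lat, 0.3))
    core.write_units(trains, OUT / "spikes.tsv", OUT / "waveforms.tsv")

    synapses = synth.simulate_synapse_table(cfg, rng)
    from epicortex.synapse import write_records
    write_records(synapses, OUT / "synapses.tsv")

    from PIL import Image
    image_truth = {}
    for group, n_imgs in (("non-epileptic", 4), ("epileptic", 4)):
        for k in range(n_imgs):
            n_cells = int(rng.integers(40, 120))
            img, cents = synth.render_cells_image(n_cells, cfg, rng)
            name = f"{group[:3]}_{k}.png"
            Image.fromarray(img).save(OUT / "images" / name)
            image_truth[name] = {"group": group, "n_cells": n_cells,
                                 "tissue_area_um2": 1.2e6}

    truth = {
        "unit_class": gt.unit_class,
        "base_rate": gt.base_rate,
        "spa_multiplier": gt.spa_multiplier,
        "connections": gt.connections,
        "images": image_truth,
    }
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2))

    n_spk = sum(u.n_spikes for u in trains.units)
    print(f"wrote {OUT}")
    print(f"  {len(trains)} units, {n_spk} spikes across {len(epochs)} epochs")
    print(f"  SPA events: " + ", ".join(
        f"{lab}={ev.n_events}" for lab, ev in all_events))
    print(f"  planted connections: {gt.connections}")
    print(f"  {len(synapses)} active-zone records, {len(image_truth)} images")


if __name__ == "__main__":
    main()
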