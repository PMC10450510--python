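# epicortex

Analysis stack for *in-vitro* human neocortical slice physiology and the
accompanying anatomy: spontaneous population activity (SPA) under
pharmacological receptor blockade, rule-based single-unit classification,
firing/burst metrics, SPA-locked modulation with Granger screening,
crosscorrelogram connectivity inference, automated stained-cell counting,
and electron-microscopy (EM) synapse morphometry statistics.

It is written for electrophysiologists and neuroanatomists who have
*sorted* spike trains (unit id, spike time, laminar channel), SPA event
times, pharmacological epoch annotations, EM active-zone tables and
brightfield micrographs — and want the downstream analyses as tested,
reusable code. Raw-signal processing (spike sorting, SPA detection from
wideband data) is out of scope; those outputs are this package's inputs.
Because the original recordings are not public, a ground-truthed
synthetic-data generator (`epicortex.synth`) reproduces the statistical
structure every stage assumes, so the whole pipeline is testable end to
end.

## The core rules and statistics

* **Epochs** — 300-s analysis windows per bathing condition (control,
  APV, NBQX+APV, washout), cut from annotated blocks with a configurable
  transition guard.
* **SPA metrics** — recurrence frequency `n_events / T`;
  baseline-corrected (−150 to −50 ms) event-triggered LFPg and MUA
  averages; amplitude = max |average| within ±50 ms of the LFPg peak
  (time zero).
* **Unit classes** — halfmax AP width `w`: `w > 0.4 ms` → principal cell
  (PC), `w < 0.2 ms` → interneuron (IN), else unclassified (UC). The
  autocorrelogram splits PCs: a high peak at 3–10 ms lag with fast
  exponential decay → intrinsically bursting (IB-PC); a late peak
  (>10 ms) or sustained firing without a peak → regular spiking (RS-PC);
  otherwise unclear firing (UF-PC).
* **Bursts** — ≥3 spikes within a 20-ms window (greedy maximal-window
  scan, brute-force oracle shipped); burstiness = spikes-in-bursts /
  all spikes; ISI CV = SD/mean of inter-spike intervals.
* **SPA modulation** — per-event spike counts in [−150,−50) vs
  [−50,+50) ms; Wilcoxon signed-rank + a 50% relative-change gate →
  increased / decreased / unchanged; unit→SPA Granger F-test on 10-ms
  binned counts at the AIC-selected order.
* **Connections** — crosscorrelogram over ±40 ms in 1-ms bins; a causal
  peak above baseline mean + 2 SD carrying ≥20 counts is monosynaptic at
  1–3 ms lag, polysynaptic beyond 3 ms.
* **Cell counting** — highest-contrast RGB channel → denoise → adaptive
  threshold → blur → opening/dilation → edge and contour extraction →
  size filter at mean ± 2 SD; density = count / (tissue area × 60 µm).
* **Synapse statistics** — one record per EM active zone (a perforated
  synapse contributes two records sharing a synapse id); mean ± SEM and
  median [Q1–Q3] summaries, χ²/Yates/Fisher contingencies,
  normality-gated group tests with Dunn's follow-up, and OLS of
  per-patient perforation fraction on age + epilepsy status.

## Worked example

```python
import numpy as np
from epicortex import synth
from epicortex.connectivity import crosscorrelogram, detect_connection

rng = np.random.default_rng(3)
pre = np.sort(rng.uniform(0, 600, rng.poisson(5.0 * 600)))
post = np.sort(rng.uniform(0, 600, rng.poisson(2.0 * 600)))
post = synth.inject_connection(pre, post, latency_ms=2.0, p=0.3,
                               jitter_ms=0.3, rng=rng)
cand = detect_connection(crosscorrelogram(pre, post, "pre", "post"))
print(cand.verdict, cand.peak_lag_ms, cand.peak_count, round(cand.threshold, 1))
```

prints

```
monosynaptic 2.0 796 16.4
```

— a synapse planted at 2 ms with 30% transmission is recovered: the 2-ms
crosscorrelogram bin holds 796 coincidences against a detection
threshold (baseline mean + 2 SD) of 16.4, and the 1–3 ms lag rule calls
it monosynaptic.

The full narrative pipeline lives in `analysis/`: run
`python analysis/01_simulate.py` through `08_synapse_stats.py` in order;
each script prints what it found and writes its tables under `results/`.

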