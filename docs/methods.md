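# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the underlying procedure was open to
interpretation.

## Recording model and epochs

A recording is a set of sorted single units (spike times in seconds,
mean waveform in µV at a known sampling rate, laminar channel 1–23),
SPA events whose LFPg peak defines time zero, and pharmacological
condition annotations. Channels map to cortical compartments as
supragranular 1–8, granular 9–13, infragranular 14–23, with a
per-recording override table for cortices whose thickness required
correction.

Epoch segmentation trims each annotated block by a **guard** (default
30 s, configurable) at both ends and caps the result at **300 s** from
the trimmed start. The guard length is a package choice: transitions
between bathing solutions are gradual and no canonical transition
duration exists. Time not covered by an epoch is retained as an explicit
transition gap so that annotated time is conserved
(epochs + gaps = blocks). SPA events falling inside gaps are excluded
from epoch-scoped analyses by construction (event membership is tested
against the trimmed epoch interval).

## SPA metrics

Recurrence frequency is the event count in an epoch over the epoch
duration. Event-triggered LFPg/MUA averages are corrected by
subtracting the mean of the averaged trace over the −150 to −50 ms
baseline; because averaging and the correction are both linear the
order does not matter (tested). Amplitude is the maximum *absolute*
deviation of the corrected average within ±50 ms of time zero. The
measurement window is a package choice — the peri-event window is
reused because no separate measurement window is defined — and
peak-to-trough is a documented alternative not taken. Paired epoch
comparisons use a paired t-test when the D'Agostino–Pearson test does
not reject normality of the differences; Wilcoxon signed-rank
otherwise. The normality test is undefined below n = 8; there the
parametric branch is used, which matches the practice of applying
paired t-tests to small per-slice SPA samples.

## Unit classification

Evidence per unit: halfmax width of the mean waveform (width of the
dominant phase at half its absolute peak, linear interpolation between
samples, measured on the sign of the larger extremum — hence invariant
to scaling and polarity), the autocorrelogram (1-ms bins, 50-ms window,
positive lags, zero-lag self-pairs excluded), and the mean firing rate.

The decision tree applies the width thresholds as printed (PC > 0.4 ms,
IN < 0.2 ms, boundaries inclusive to UC) and then quantifies the
qualitative ACG anchors with `RuleSet` parameters:

* "high peak": global ACG peak ≥ 2× the 30–50-ms tail mean **and**
  ≥ 5 pair counts. The absolute floor keeps a sparse ACG (one or two
  chance coincidences over a near-empty tail) from faking a burst peak.
* "fast exponential decay": least-squares fit of `a·exp(−lag/τ)` to the
  post-peak flank, τ ≤ 20 ms.
* "sustained firing": mean rate ≥ 0.5 Hz.

All three are defaults, not constants. Width is the primary IN
criterion; an ACG that looks fast despite a narrow waveform is flagged,
not reclassified. A PC-width unit with no usable ACG is reported UF-PC
with a `no-acg-evidence` flag; a mid-width unit without an ACG is UC
with an `insufficient evidence` flag.

## Bursts and firing metrics

A burst is ≥3 spikes within 20 ms. The window anchoring is genuinely
ambiguous (sliding triplet vs ISI chain), so the default is a greedy
left-to-right maximal-window scan — at spike *i* take the largest *j*
with `t(j) − t(i) ≤ 20 ms`, emit `[i, j]` if it holds ≥3 spikes, resume
at `j+1` — and a naive O(n²) reference implementation ships alongside
as an equivalence oracle. A spike exactly at the window edge is inside.
A burst belongs to the epoch containing its first spike; only its
spikes inside that epoch enter the numerator, so burstiness stays in
[0, 1]. ISI CV uses the sample SD (n−1) and needs ≥3 spikes in the
epoch.

## SPA-locked modulation and Granger screening

Windows are half-open, [−150, −50) baseline and [−50, +50) peri-event,
equal 100-ms lengths so raw counts compare directly; events whose
windows would cross a recording edge are dropped, and <10 usable events
yields `unchanged` with an `insufficient` flag. The per-event pairs are
compared with Wilcoxon signed-rank (the unnamed "non-parametric test" —
the pairing is by construction, making the signed-rank test the natural
choice; configurable). A unit is increased iff p < α and peri ≥ 1.5×
baseline, decreased iff p < α and peri ≤ baseline/1.5, else unchanged.
A silent baseline with peri activity reports an infinite percent change
and is kept out of group means.

Granger screening bins unit spikes and SPA events at 10 ms, selects the
autoregression order by AIC up to 10 lags, and F-tests the unit-lag
block of the unrestricted model against the SPA-only restriction.
Bin width, order cap, criterion and α (0.05, uncorrected) are
configuration; only the concept is fixed. The implementation is plain
OLS; it is cross-checked in the tests against the reference ssr-based
Granger F-test at fixed order.

## Connectivity

CCGs count target−reference lags within ±40 ms at 1-ms bins centered on
integer lags. Positive lag means the target fires after the reference,
and the reference of a detected pair is the putative presynaptic
member; both orderings of every pair are scanned (the reverse ordering
is the mirrored histogram, never recomputed). The sign convention in
display-oriented descriptions of such histograms is ambiguous; this
package fixes causal = positive and documents it rather than guessing a
display axis. Baseline = bins with |lag| in [20, 40] ms on both flanks
(no canonical definition exists; configurable). The zero-lag bin is
excluded from the peak search as a common-input artifact. Gates: peak >
baseline mean + 2 SD and peak ≥ 20 counts; monosynaptic at 1–3 ms,
polysynaptic beyond. CCGs pool the whole recording by default; no
multiple-comparison correction is applied, as none is part of the rule.
At sparse-firing regimes (1–2 Hz, 300 s) the 20-count floor dominates
and the measured false-positive rate over 500 independent Poisson pairs
is far below 10% (computed in the tests and the acceptance script, not
assumed).

## Cell counting

Pipeline order: highest-SD RGB channel → 0.5× resize → Gaussian
denoise → local-mean adaptive threshold (block 51 px, offset 0.1 — a
pixel must sit 0.1 intensity units below its neighbourhood mean, which
keeps background texture out of the mask) → Gaussian blur →
morphological opening then dilation (disk radius 1, one iteration
each) → Canny edges merged into the mask → closed contour extraction →
keep contours with shoelace area within mean ± 2 SD of the per-image
contour-area distribution. All parameters live in `CountingConfig`; the
operations are fixed, their parameters were never published. Tissue
area is an input in physical units (measured externally), so density
`n / (area × 60 µm)` is invariant to image rescaling; the reporting
unit defaults to cells per 10⁶ µm³ and is configurable, since the
dimensionality of printed density units in this literature is
inconsistent and no attempt is made to reproduce printed density
values numerically.

## Synapse statistics

The record unit is the **active zone**: a perforated synapse (one
terminal, split active zone, same postsynaptic element) contributes two
records sharing a synapse id, and the validator enforces that shared
ids are perforated. Perforation ratios are computed over active zones —
the arithmetic that reproduces the printed group percentages — while
synapse-level counts remain derivable by de-duplicating the id.
Summaries report mean ± SEM (n−1 SD) and median [Q1–Q3] with
linear-interpolation quantiles. Contingency tests: Pearson χ² without
correction by default, Yates or Fisher (2×2) on request; expected cells
below 1 trigger a warning suggesting Fisher. Group comparisons gate on
D'Agostino–Pearson normality per group (groups too small for the test
route to the rank branch, the conservative default for unpaired data);
the nonparametric path is Kruskal–Wallis with a hand-implemented Dunn
follow-up (rank-based z with tie correction, no additional correction
unless configured — none is prescribed). The age/epilepsy analysis is
OLS of per-patient perforated fraction on age and an epilepsy
indicator; it requires ≥4 patients and both groups (otherwise the
indicator is collinear with the intercept).

## Synthetic-data generator

The generator emulates the study conditions, not the biophysics:

* **Trains** are piecewise-homogeneous Poisson processes sampled
  exactly (Poisson total count, inverse-CDF placement), with per-unit
  base rates log-uniform in 0.2–3 Hz and per-condition multipliers.
  RS-PC units draw from 0.8–3 Hz so sustained firing — part of their
  defining rule — holds by construction. SPA modulation is a
  piecewise-constant rate multiplier within ±50 ms of each event.
* **Bursts**: for IB-PC units a configured fraction (default 0.6) of
  the spike budget is grouped into bursts of 3–5 spikes at 3–5-ms
  intra-burst ISIs (placing the ACG peak inside the 3–10 ms rule
  window); burst onsets are kept ≥30 ms apart so a burst tail cannot
  strand spikes of the next outside a detection window, and the total
  budget is preserved so empirical rates converge to the truth.
* **Waveforms** are biphasic Gaussian-trough templates whose halfmax
  widths are drawn inside margin-separated class bands (PC 0.5–0.7 ms,
  IN 0.12–0.17 ms, UC 0.25–0.35 ms) so classes are unambiguous by
  construction.
* **SPA** events follow a Gamma renewal process (shape 4 by default, so
  recurrence estimators are exercised under non-Poisson regularity) at
  1 Hz; per-event traces are a 10-ms-σ Gaussian transient of
  configured amplitude (22 µV LFPg, 1.4 µV MUA — the reported
  population-level scale) plus Gaussian noise, the MUA rectified.
  Traces are synthesized directly at event-window resolution; no
  continuous recording is modelled.
* **Connections** add, per presynaptic spike with probability p, one
  postsynaptic spike at latency + Gaussian jitter.
* **Synapse tables** draw active-zone lengths log-normal with
  perforation-specific medians (0.22 / 0.16 µm, log-σ 0.33, bracketing
  the printed summaries); the configured perforation probabilities are
  the printed *zone-level* ratios (20.4% / 28.8%) and are converted
  internally to per-synapse Bernoulli rates p/(2−p). Target classes
  are categorical at the printed shares; ages are drawn per group
  (61.5 ± 17 vs 34.6 ± 13 years).
* **Micrographs** are dark ellipses (radius 7 ± 1.2 px, clipped at
  ±2 SD) on a bright textured background with enforced minimum centroid
  separation.

Every generator is a pure function of (config, seed). What passing
tests therefore show is that each rule recovers *its own* planted
structure under realistic rates, noise and sample sizes — not that the
rules are optimal for real tissue, where overlapping spikes, drift,
non-stationarity, correlated background synchrony and stain variability
all exist and are not modelled.

## Problem sizes in the test and acceptance suites

The suites use 300-s epochs at study-regime rates: 60-unit class
recovery; 1,000 random trains for the burst oracle; 50 planted and 500
null pairs for connectivity; 500 seeds for Granger null calibration and
rate-estimator convergence; 200 seeds for modulation null calibration;
a 10–150-blob × 3-noise × 3-seed image sweep; 1,000 random tables for
the χ² oracle. The acceptance script uses the same regimes at somewhat
smaller replicate counts, all derived from its `--seed`.

## Known limitations

* The Granger screen is linear on binned counts; spectral or nonlinear
  causality and the SPA→unit direction are out of scope.
* CCG significance uses the simple 2-SD rule; no jitter-corrected or
  convolution-baseline variants, and no inhibitory-trough detection.
* Cell counting applies no stereological correction and no stain
  deconvolution; validation is against generator ground truth.
* The exact per-class firing-rate distributions of the source material
  are unknown; the generator's bands bracket the reported group means
  and are exposed in `SimConfig`, not asserted as faithful.
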