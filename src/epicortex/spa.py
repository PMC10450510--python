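"""Network-level SPA characterization.

Recurrence frequency of the population events, baseline-corrected
event-triggered averages of the LFPg and MUA traces, peak amplitudes, and
paired per-SPA comparisons between pharmacological epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import Epoch, SPAEventSet

BASELINE_MS = (-150.0, -50.0)
AMPLITUDE_WINDOW_MS = (-50.0, 50.0)


@dataclass
class SPAStats:
    n_events: int
    recurrence_frequency: float  # Hz
    lfpg_amplitude: float  # microvolts
    mua_amplitude: float  # microvolts
    epoch_label: str = ""


@dataclass
class EpochComparison:
    test: str
    statistic: float
    p: float
    direction: str  # "increase" / "decrease" / "none"
    n: int

    @property
    def insufficient(self) -> bool:
        return self.test == "insufficient"


def recurrence_frequency(events: SPAEventSet, epoch: Epoch) -> float:
    """Events inside the epoch divided by the epoch duration (Hz)."""
    if epoch.duration <= 0:
        raise ValueError("zero-length epoch")
    n = int(np.count_nonzero(epoch.contains(events.event_times)))
    return n / epoch.duration


def event_triggered_average(traces: np.ndarray, time_ms: np.ndarray,
                            baseline_ms: tuple[float, float] = BASELINE_MS,
                            ) -> np.ndarray:
    """Pointwise mean across events, baseline-corrected.

    The mean of the averaged trace over the baseline window (default -150
    to -50 ms) is subtracted, so the baseline segment of the output has
    zero mean.  Averaging commutes with the correction (both are linear).
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 1:
        raise ValueError("need a (n_events, n_samples) trace array")
    time_ms = np.asarray(time_ms, dtype=float)
    if traces.shape[1] != time_ms.size:
        raise ValueError("traces and time base disagree in length")
    avg = traces.mean(axis=0)
    b = (time_ms >= baseline_ms[0]) & (time_ms < baseline_ms[1])
    if not b.any():
        raise ValueError("baseline window contains no samples")
    return avg - avg[b].mean()


def spa_amplitudes(avg_lfpg: np.ndarray, avg_mua: np.ndarray,
                   time_ms: np.ndarray,
                   window_ms: tuple[float, float] = AMPLITUDE_WINDOW_MS,
                   ) -> tuple[float, float]:
    """Peak absolute deviation of the corrected averages within +-50 ms."""
    time_ms = np.asarray(time_ms, dtype=float)
    m = (time_ms >= window_ms[0]) & (time_ms <= window_ms[1])
    lf = float(np.max(np.abs(np.asarray(avg_lfpg)[m]))) if m.any() else 0.0
    mu = float(np.max(np.abs(np.asarray(avg_mua)[m]))) if m.any() else 0.0
    return lf, mu


def _normality_gate(x: np.ndarray, alpha: float = 0.05) -> bool:
    """True when the D'Agostino-Pearson test does not reject normality.

    The test needs n >= 8; below that it cannot run and the parametric
    branch is used (matching the practice of applying paired t-tests to
    small per-SPA samples).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8 or np.allclose(x, x[0]):
        return True
    _, p = stats.normaltest(x)
    return p >= alpha


def compare_spa_across_epochs(control: np.ndarray, treated: np.ndarray,
                              paired: bool = True, alpha: float = 0.05,
                              ) -> EpochComparison:
    """Per-SPA comparison of one metric between two pharmacological epochs.

    Paired t-test when the differences pass the normality gate, Wilcoxon
    signed-rank otherwise; unpaired mode uses t / Mann-Whitney.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if paired and control.size != treated.size:
        raise ValueError("paired comparison needs equal-length samples")
    n = min(control.size, treated.size)
    if n < 3:
        return EpochComparison("insufficient", float("nan"), float("nan"), "none", n)

    if paired:
        diff = treated - control
        if np.allclose(diff, 0):
            return EpochComparison("wilcoxon", 0.0, 1.0, "none", n)
        if _normality_gate(diff, alpha):
            stat, p = stats.ttest_rel(treated, control)
            test = "paired-t"
        else:
            stat, p = stats.wilcoxon(treated, control)
            test = "wilcoxon"
        delta = float(np.mean(diff))
    else:
        if _normality_gate(control, alpha) and _normality_gate(treated, alpha):
            stat, p = stats.ttest_ind(treated, control)
            test = "t"
        else:
            stat, p = stats.mannwhitneyu(treated, control, alternative="two-sided")
            test = "mann-whitney"
        delta = float(np.mean(treated) - np.mean(control))

    direction = "none"
    if p < alpha:
        direction = "increase" if delta > 0 else "decrease"
    return EpochComparison(test, float(stat), float(p), direction, n)


def spa_stats(events: SPAEventSet, epoch: Epoch) -> SPAStats:
    """Recurrence frequency plus averaged-trace amplitudes for one epoch."""
    freq = recurrence_frequency(events, epoch)
    lf = mu = 0.0
    n = int(np.count_nonzero(epoch.contains(events.event_times)))
    if events.lfpg_traces is not None and n > 0:
        sel = epoch.contains(events.event_times)
        avg_lf = event_triggered_average(events.lfpg_traces[sel], events.trace_time_ms)
        avg_mu = event_triggered_average(events.mua_traces[sel], events.trace_time_ms)
        lf, mu = spa_amplitudes(avg_lf, avg_mu, events.trace_time_ms)
    return SPAStats(n, freq, lf, mu, epoch.label)
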