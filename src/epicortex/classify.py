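"""Rule-based single-unit classification.

Units are assigned to one of five classes from two pieces of evidence:
the action-potential width at half of its maximal amplitude (halfmax) on
the mean waveform, and the shape of the spike-train autocorrelogram (ACG).

* halfmax > 0.4 ms  -> principal cell (PC); the ACG splits the PC branch:
  a high peak at 3-10 ms lag followed by a fast exponential decay marks an
  intrinsically bursting PC (IB-PC); a lacking peak with sustained firing,
  or a peak beyond 10 ms, marks a regular-spiking PC (RS-PC); the rest are
  PCs with unclear firing (UF-PC).
* halfmax < 0.2 ms  -> putative inhibitory interneuron (IN); width is the
  primary criterion, the ACG (slow rise, slow decay) is corroborating.
* 0.2 <= halfmax <= 0.4 ms with a non-characteristic ACG -> unclassified
  (UC).

The qualitative anchors ("high peak", "fast decay", "sustained firing")
are quantified by the tunable :class:`RuleSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import UnitSet

CLASS_LABELS = ("RS-PC", "IB-PC", "UF-PC", "IN", "UC")


@dataclass
class RuleSet:
    """Thresholds for the classification decision tree.

    ``peak_prominence_factor``, ``decay_tau_max_ms`` and
    ``sustained_rate_min_hz`` quantify the qualitative ACG anchors; they
    are parameters, not fixed constants.
    """

    pc_width_ms: float = 0.4
    in_width_ms: float = 0.2
    ib_peak_lo_ms: float = 3.0
    ib_peak_hi_ms: float = 10.0
    acg_bin_ms: float = 1.0
    acg_window_ms: float = 50.0
    peak_prominence_factor: float = 2.0
    peak_min_count: int = 5  # a "high peak" needs this many pairs at least
    decay_tau_max_ms: float = 20.0
    sustained_rate_min_hz: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.in_width_ms < self.pc_width_ms:
            raise ValueError("need 0 < in_width < pc_width")
        if not self.ib_peak_lo_ms < self.ib_peak_hi_ms:
            raise ValueError("need ib_peak_lo < ib_peak_hi")


@dataclass
class UnitClass:
    label: str
    halfmax_ms: float
    acg_peak_ms: float = float("nan")
    decay_tau_ms: float = float("nan")
    mean_rate_hz: float = float("nan")
    flags: list[str] = field(default_factory=list)


def halfmax_width(waveform: np.ndarray, sampling_rate: float) -> float:
    """AP width (ms) at half of the dominant phase's peak amplitude.

    Measured on the sign of the larger \\|extremum\\|, with linear
    interpolation between samples; invariant under amplitude scaling and
    sign flip.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 2 or np.ptp(w) == 0:
        raise ValueError("flat waveform has no halfmax width")
    w = w - np.median(w)  # robust baseline
    peak_idx = int(np.argmax(np.abs(w)))
    sign = 1.0 if w[peak_idx] >= 0 else -1.0
    v = sign * w
    half = v[peak_idx] / 2.0
    if half <= 0:
        raise ValueError("flat waveform has no halfmax width")

    # walk outward from the peak to the half-amplitude crossings
    left = 0.0
    for i in range(peak_idx, 0, -1):
        if v[i - 1] < half:
            left = (i - 1) + (half - v[i - 1]) / (v[i] - v[i - 1])
            break
    right = float(v.size - 1)
    for i in range(peak_idx, v.size - 1):
        if v[i + 1] < half:
            right = i + (v[i] - half) / (v[i] - v[i + 1])
            break
    return (right - left) / sampling_rate * 1e3


@dataclass
class Autocorrelogram:
    lags_ms: np.ndarray  # bin centers, positive lags only
    counts: np.ndarray

    @property
    def is_empty(self) -> bool:
        return self.counts.sum() == 0


def autocorrelogram(spike_times: np.ndarray, bin_ms: float = 1.0,
                    window_ms: float = 50.0) -> Autocorrelogram:
    """Histogram of positive spike-pair lags in (0, window] ms.

    Zero-lag self pairs are excluded; the ACG is symmetric by
    construction, so only positive lags are stored.
    """
    t = np.asarray(spike_times, dtype=float)
    edges = np.arange(0.0, window_ms + bin_ms, bin_ms)
    centers = edges[:-1] + bin_ms / 2.0
    if t.size < 2:
        return Autocorrelogram(centers, np.zeros(centers.size, dtype=int))
    w = window_ms * 1e-3
    diffs = []
    k = 1
    while k < t.size:
        d = t[k:] - t[:-k]
        m = d <= w
        if not m.any():
            break
        diffs.append(d[m])
        k += 1
    if not diffs:
        return Autocorrelogram(centers, np.zeros(centers.size, dtype=int))
    d_ms = np.concatenate(diffs) * 1e3
    counts, _ = np.histogram(d_ms[d_ms > 0], bins=edges)
    return Autocorrelogram(centers, counts)


def _acg_features(acg: Autocorrelogram, rules: RuleSet) -> tuple[float, bool, float]:
    """(peak lag ms, prominent?, decay tau ms) from an ACG."""
    counts = acg.counts.astype(float)
    peak_i = int(np.argmax(counts))
    peak_lag = float(acg.lags_ms[peak_i])
    peak = counts[peak_i]
    tail = counts[(acg.lags_ms >= 30.0) & (acg.lags_ms <= 50.0)]
    tail_mean = float(tail.mean()) if tail.size else 0.0
    if peak <= 0:
        return peak_lag, False, float("inf")
    prominent = (peak >= rules.peak_min_count
                 and peak >= rules.peak_prominence_factor * max(tail_mean, 1.0))
    # exponential decay fit to the post-peak flank
    post = slice(peak_i, min(peak_i + 30, counts.size))
    x = acg.lags_ms[post] - peak_lag
    y = counts[post]
    tau = float("inf")
    if np.count_nonzero(y) >= 3:
        try:
            popt, _ = curve_fit(
                lambda t, a, tau_: a * np.exp(-t / tau_), x, y,
                p0=(peak, 5.0), bounds=([0, 0.1], [np.inf, 1e3]), maxfev=2000)
            tau = float(popt[1])
        except RuntimeError:
            tau = float("inf")
    return peak_lag, bool(prominent), tau


def classify_unit(width_ms: float, acg: Autocorrelogram | None,
                  mean_rate_hz: float, rules: RuleSet | None = None) -> UnitClass:
    """Deterministic decision tree over (halfmax width, ACG, mean rate)."""
    rules = rules or RuleSet()
    flags: list[str] = []

    if width_ms > rules.pc_width_ms:
        if acg is None or acg.is_empty:
            return UnitClass("UF-PC", width_ms, mean_rate_hz=mean_rate_hz,
                             flags=["no-acg-evidence"])
        peak_lag, prominent, tau = _acg_features(acg, rules)
        if (prominent and rules.ib_peak_lo_ms <= peak_lag <= rules.ib_peak_hi_ms
                and tau <= rules.decay_tau_max_ms):
            label = "IB-PC"
        elif (prominent and peak_lag > rules.ib_peak_hi_ms) or (
                not prominent and mean_rate_hz >= rules.sustained_rate_min_hz):
            label = "RS-PC"
        else:
            label = "UF-PC"
        return UnitClass(label, width_ms, peak_lag, tau, mean_rate_hz, flags)

    if width_ms < rules.in_width_ms:
        # width is the primary IN criterion; ACG shape only corroborates
        if acg is not None and not acg.is_empty:
            peak_lag, prominent, tau = _acg_features(acg, rules)
            if peak_lag <= rules.ib_peak_hi_ms and prominent:
                flags.append("fast-acg-despite-narrow-width")
            return UnitClass("IN", width_ms, peak_lag, tau, mean_rate_hz, flags)
        return UnitClass("IN", width_ms, mean_rate_hz=mean_rate_hz, flags=flags)

    if acg is None or acg.is_empty:
        flags.append("insufficient evidence")
        return UnitClass("UC", width_ms, mean_rate_hz=mean_rate_hz, flags=flags)
    peak_lag, _, tau = _acg_features(acg, rules)
    return UnitClass("UC", width_ms, peak_lag, tau, mean_rate_hz, flags)


def classify_units(unitset: UnitSet, rules: RuleSet | None = None) -> pd.DataFrame:
    """Classify every unit of a recording; one row per unit."""
    rules = rules or RuleSet()
    rows = []
    dur = max(unitset.recording_duration, 1e-9)
    for u in unitset.units:
        if u.mean_waveform is None or u.waveform_fs is None:
            raise ValueError(f"unit {u.unit_id}: no waveform, cannot classify")
        width = halfmax_width(u.mean_waveform, u.waveform_fs)
        acg = autocorrelogram(u.spike_times, rules.acg_bin_ms, rules.acg_window_ms)
        res = classify_unit(width, acg, u.n_spikes / dur, rules)
        rows.append({
            "unit_id": u.unit_id, "label": res.label, "width_ms": res.halfmax_ms,
            "acg_peak_ms": res.acg_peak_ms, "tau_ms": res.decay_tau_ms,
            "mean_rate_hz": res.mean_rate_hz, "flags": ";".join(res.flags),
        })
    return pd.DataFrame(rows)
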