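"""Firing rate, burst detection, burstiness index and ISI variability.

A burst is a group of at least ``min_spikes`` (default 3) spikes that
occur within a ``window_ms`` (default 20 ms) time window; the burstiness
index is the fraction of a unit's spikes that fall inside bursts.  The
window anchoring is ambiguous in principle (per-triplet vs ISI chain), so
the default greedy maximal-window scan is shipped alongside a brute-force
reference used as an equivalence oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Epoch


@dataclass
class Burst:
    start_index: int
    end_index: int  # inclusive
    start_s: float
    end_s: float
    n_spikes: int


@dataclass
class BurstSet:
    bursts: list[Burst]
    unit_id: str = ""

    def __len__(self) -> int:
        return len(self.bursts)

    @property
    def n_burst_spikes(self) -> int:
        return sum(b.n_spikes for b in self.bursts)


def firing_rate(spike_times: np.ndarray, epoch: Epoch) -> float:
    """Spike count in the epoch divided by the epoch duration (Hz)."""
    if epoch.duration <= 0:
        raise ValueError("zero-length epoch")
    t = np.asarray(spike_times, dtype=float)
    return float(np.count_nonzero(epoch.contains(t))) / epoch.duration


def detect_bursts(spike_times: np.ndarray, window_ms: float = 20.0,
                  min_spikes: int = 3, unit_id: str = "") -> BurstSet:
    """Greedy left-to-right maximal-window burst scan.

    At spike i, take the largest j with t(j) - t(i) <= window; if the
    group has >= min_spikes members emit the burst [i, j] and continue at
    j + 1, else advance by one spike.  A spike exactly at the window edge
    is inside (<=).  Emitted bursts are disjoint and ordered.
    """
    t = np.asarray(spike_times, dtype=float)
    w = window_ms * 1e-3
    bursts: list[Burst] = []
    i = 0
    n = t.size
    while i < n:
        j = int(np.searchsorted(t, t[i] + w, side="right")) - 1
        if j - i + 1 >= min_spikes:
            bursts.append(Burst(i, j, float(t[i]), float(t[j]), j - i + 1))
            i = j + 1
        else:
            i += 1
    return BurstSet(bursts, unit_id)


def detect_bursts_bruteforce(spike_times: np.ndarray, window_ms: float = 20.0,
                             min_spikes: int = 3, unit_id: str = "") -> BurstSet:
    """Naive O(n^2) reference implementation of the same burst semantics."""
    t = np.asarray(spike_times, dtype=float)
    w = window_ms * 1e-3
    bursts: list[Burst] = []
    i = 0
    while i < t.size:
        j = i
        for k in range(i, t.size):
            if t[k] - t[i] <= w + 0.0:
                j = k
            else:
                break
        if j - i + 1 >= min_spikes:
            bursts.append(Burst(i, j, float(t[i]), float(t[j]), j - i + 1))
            i = j + 1
        else:
            i += 1
    return BurstSet(bursts, unit_id)


def burstiness_index(spike_times: np.ndarray, epoch: Epoch | None = None,
                     window_ms: float = 20.0, min_spikes: int = 3) -> float:
    """Fraction of spikes found within bursts (0 when there are no spikes).

    A burst belongs to the epoch containing its first spike; only its
    spikes inside the epoch enter the numerator, so the index stays in
    [0, 1].
    """
    t = np.asarray(spike_times, dtype=float)
    bursts = detect_bursts(t, window_ms, min_spikes)
    if epoch is None:
        total = t.size
        in_burst = bursts.n_burst_spikes
    else:
        total = int(np.count_nonzero(epoch.contains(t)))
        in_burst = 0
        for b in bursts.bursts:
            if epoch.contains(np.array([b.start_s]))[0]:
                member = t[b.start_index:b.end_index + 1]
                in_burst += int(np.count_nonzero(epoch.contains(member)))
    return in_burst / total if total else 0.0


def isi_cv(spike_times: np.ndarray, epoch: Epoch | None = None) -> float:
    """Coefficient of variation of the inter-spike intervals.

    Sample SD (n-1 denominator) over mean; NaN with fewer than 3 spikes
    in the epoch.
    """
    t = np.asarray(spike_times, dtype=float)
    if epoch is not None:
        t = t[epoch.contains(t)]
    if t.size < 3:
        return float("nan")
    isis = np.diff(t)
    m = isis.mean()
    return float(isis.std(ddof=1) / m) if m > 0 else float("nan")
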