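"""Crosscorrelogram connectivity inference between unit pairs.

CCGs count target-minus-reference spike lags in 1-ms bins over -40..+40
ms.  A connection is declared when the causal-side peak (positive lag =
target fires after reference; the reference is the putative presynaptic
member) exceeds the baseline mean + 2 SD AND carries at least 20 counts:
monosynaptic at 1-3 ms peak lag, polysynaptic beyond 3 ms.  The zero-lag
bin is excluded as a common-input artifact; baseline bins are the
|lag| in [20, 40] ms flanks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import UnitSet


@dataclass
class CCG:
    ref_id: str
    target_id: str
    lags_ms: np.ndarray  # integer bin centers, -40..+40
    counts: np.ndarray
    baseline_mean: float
    baseline_sd: float
    n_ref: int

    def mirrored(self) -> "CCG":
        """CCG with the roles of the two units swapped (counts reversed)."""
        return CCG(self.target_id, self.ref_id, self.lags_ms,
                   self.counts[::-1].copy(), self.baseline_mean,
                   self.baseline_sd, self.n_ref)


@dataclass
class ConnectionCandidate:
    ref_id: str  # putative presynaptic
    target_id: str  # putative postsynaptic
    verdict: str  # none / monosynaptic / polysynaptic
    peak_lag_ms: float
    peak_count: int
    threshold: float


def crosscorrelogram(ref_times: np.ndarray, target_times: np.ndarray,
                     ref_id: str = "ref", target_id: str = "target",
                     window_ms: float = 40.0, bin_ms: float = 1.0,
                     baseline_ms: tuple[float, float] = (20.0, 40.0)) -> CCG:
    """Histogram of target-ref lags within +-window, 1-ms bins.

    Bin centers sit on integer lags (bin ℓ covers [ℓ-0.5, ℓ+0.5) ms);
    CCG(A,B) at lag ℓ equals CCG(B,A) at -ℓ.
    """
    if ref_id == target_id:
        raise ValueError("self-CCG is not a pair")
    ref = np.asarray(ref_times, dtype=float)
    tgt = np.asarray(target_times, dtype=float)
    if ref.size == 0 or tgt.size == 0:
        raise ValueError("both trains must be non-empty")
    nbins = int(round(2 * window_ms / bin_ms)) + 1
    edges = (np.arange(nbins + 1) - 0.5) * bin_ms - window_ms
    centers = (edges[:-1] + edges[1:]) / 2.0

    w = edges[-1] * 1e-3
    lo = np.searchsorted(tgt, ref + edges[0] * 1e-3, side="left")
    hi = np.searchsorted(tgt, ref + w, side="left")
    diffs = [tgt[a:b] - r for r, a, b in zip(ref, lo, hi) if b > a]
    if diffs:
        d_ms = np.concatenate(diffs) * 1e3
        counts, _ = np.histogram(d_ms, bins=edges)
    else:
        counts = np.zeros(nbins, dtype=int)

    base = counts[(np.abs(centers) >= baseline_ms[0])
                  & (np.abs(centers) <= baseline_ms[1])]
    bmean = float(base.mean())
    bsd = float(base.std(ddof=1)) if base.size > 1 else 0.0
    return CCG(ref_id, target_id, centers, counts, bmean, bsd, ref.size)


def detect_connection(ccg: CCG, sd_factor: float = 2.0,
                      min_peak_count: int = 20,
                      mono_ms: tuple[float, float] = (1.0, 3.0)) -> ConnectionCandidate:
    """Apply the mean + 2 SD / >= 20-count gates to the causal side."""
    causal = ccg.lags_ms >= 1.0  # zero lag excluded (common input)
    counts = ccg.counts[causal]
    lags = ccg.lags_ms[causal]
    i = int(np.argmax(counts))
    peak, lag = int(counts[i]), float(lags[i])
    threshold = ccg.baseline_mean + sd_factor * ccg.baseline_sd
    verdict = "none"
    if peak > threshold and peak >= min_peak_count:
        if mono_ms[0] <= lag <= mono_ms[1]:
            verdict = "monosynaptic"
        elif lag > mono_ms[1]:
            verdict = "polysynaptic"
    return ConnectionCandidate(ccg.ref_id, ccg.target_id, verdict, lag, peak,
                               threshold)


def scan_pairs(unitset: UnitSet, min_spikes: int = 2,
               **detect_kwargs) -> list[ConnectionCandidate]:
    """Test every ordered pair of simultaneously recorded units.

    Each unordered pair's CCG is computed once and mirrored for the
    reverse ordering; because the peak search is restricted to the causal
    side, a connection detected A->B at lag ℓ is never also reported
    B->A at the same lag.
    """
    out: list[ConnectionCandidate] = []
    units = [u for u in unitset.units if u.n_spikes >= min_spikes]
    for a in range(len(units)):
        for b in range(a + 1, len(units)):
            ua, ub = units[a], units[b]
            ccg = crosscorrelogram(ua.spike_times, ub.spike_times,
                                   ua.unit_id, ub.unit_id)
            out.append(detect_connection(ccg, **detect_kwargs))
            out.append(detect_connection(ccg.mirrored(), **detect_kwargs))
    return out


def pre_post_contrast(candidates: list[ConnectionCandidate],
                      metrics: dict[str, tuple[float, float]]) -> dict:
    """Compare firing rate and burstiness of pre vs post pair members.

    ``metrics`` maps unit_id -> (firing_rate_hz, burstiness).  Detected
    pairs only; Mann-Whitney U, medians and quartiles reported.
    """
    detected = [c for c in candidates if c.verdict != "none"]
    if len(detected) < 3:
        return {"status": "insufficient", "n_pairs": len(detected)}
    pre_ids = [c.ref_id for c in detected]
    post_ids = [c.target_id for c in detected]
    report: dict = {"status": "ok", "n_pairs": len(detected)}
    for k, name in ((0, "firing_rate"), (1, "burstiness")):
        pre = np.array([metrics[i][k] for i in pre_ids])
        post = np.array([metrics[i][k] for i in post_ids])
        if np.ptp(np.concatenate([pre, post])) == 0:
            u, p = float("nan"), 1.0
        else:
            u, p = stats.mannwhitneyu(pre, post, alternative="two-sided")
        report[name] = {
            "pre_median": float(np.median(pre)),
            "pre_q1": float(np.percentile(pre, 25)),
            "pre_q3": float(np.percentile(pre, 75)),
            "post_median": float(np.median(post)),
            "post_q1": float(np.percentile(post, 25)),
            "post_q3": float(np.percentile(post, 75)),
            "u": float(u), "p": float(p),
        }
    return report
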